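"""Sliding-window RIP (repeat-induced point mutation) index scanning.

RIP is a fungal genome-defense process that converts C to T preferentially
at CpA dinucleotides within repeated sequence.  Its footprint is read from
two dinucleotide ratios: the product index TpA/ApT rises as RIP creates TpA,
and the substrate index (CpA+TpG)/(ApC+GpT) falls as targets are consumed.
A window is called RIP-mutated when the product index exceeds 1.61 AND the
substrate index falls below 0.53.  Both indices are strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _product
from typing import Optional

from .core import GenomeSet, Interval

DINUCLEOTIDES = ["".join(p) for p in _product("ACGT", repeat=2)]


@dataclass
class DinucCounts:
    counts: dict[str, int] = field(default_factory=lambda: {d: 0 for d in DINUCLEOTIDES})

    @property
    def n_valid(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, dinuc: str) -> int:
        return self.counts[dinuc]


@dataclass(frozen=True)
class RipThresholds:
    product_min: float = 1.61
    substrate_max: float = 0.53

    def __post_init__(self) -> None:
        if self.product_min <= 0 or self.substrate_max <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class RipWindow:
    interval: Interval
    product_index: Optional[float]  # TpA/ApT; None when ApT = 0
    substrate_index: Optional[float]  # (CpA+TpG)/(ApC+GpT); None when denom = 0
    is_rip: bool


def dinucleotide_counts(seq: str) -> DinucCounts:
    """Count overlapping dinucleotides left to right; pairs touching N skip."""
    out = DinucCounts()
    c = out.counts
    s = seq.upper()
    for i in range(len(s) - 1):
        pair = s[i : i + 2]
        if pair in c:
            c[pair] += 1
    return out


def rip_indices(counts: DinucCounts) -> tuple[Optional[float], Optional[float]]:
    """(product, substrate) indices; None marks an undefined (0-denominator)
    index, which never satisfies a threshold."""
    product = counts["TA"] / counts["AT"] if counts["AT"] else None
    denom = counts["AC"] + counts["GT"]
    substrate = (counts["CA"] + counts["TG"]) / denom if denom else None
    return product, substrate


def composite_index(counts: DinucCounts) -> Optional[float]:
    """product - substrate, for reporting only (no threshold is applied)."""
    product, substrate = rip_indices(counts)
    if product is None or substrate is None:
        return None
    return product - substrate


def _call(product, substrate, thresholds: RipThresholds) -> bool:
    return (
        product is not None
        and substrate is not None
        and product > thresholds.product_min
        and substrate < thresholds.substrate_max
    )


def scan_rip(
    genome: GenomeSet,
    window: int = 1000,
    step: int = 500,
    thresholds: RipThresholds = RipThresholds(),
) -> tuple[list[RipWindow], list[Interval]]:
    """Tile each contig and call RIP windows; merge calls into regions.

    Windows start every `step` bases; the final partial window is kept when
    it is at least half a window long.  Overlapping or abutting RIP windows
    merge into regions (0-based half-open intervals).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 1 <= step <= window:
        raise ValueError("step must satisfy 1 <= step <= window")
    windows: list[RipWindow] = []
    regions: list[Interval] = []
    for contig, seq in genome.contigs.items():
        L = len(seq)
        open_region: Optional[list[int]] = None
        for start in range(0, L, step):
            end = min(start + window, L)
            if end - start < window and end - start < window / 2:
                break
            counts = dinucleotide_counts(seq[start:end])
            product, substrate = rip_indices(counts)
            hit = _call(product, substrate, thresholds)
            windows.append(RipWindow(Interval(contig, start, end), product, substrate, hit))
            if hit:
                if open_region is not None and start <= open_region[1]:
                    open_region[1] = max(open_region[1], end)
                else:
                    if open_region is not None:
                        regions.append(Interval(contig, *open_region))
                    open_region = [start, end]
            if end == L:
                break
        if open_region is not None:
            regions.append(Interval(contig, *open_region))
    return windows, regions


def write_window_table(windows: list[RipWindow], path: str) -> None:
    def fmt(x: Optional[float]) -> str:
        return "NA" if x is None else f"{x:.4f}"

    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tproduct_index\tsubstrate_index\tis_rip\n")
        for w in windows:
            iv = w.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{fmt(w.product_index)}"
                f"\t{fmt(w.substrate_index)}\t{int(w.is_rip)}\n"
            )


def write_regions_bed(regions: list[Interval], path: str) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(regions, 1):
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\trip_region_{i}\n")


def write_regions_gff3(regions: list[Interval], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, iv in enumerate(regions, 1):
            fh.write(
                f"{iv.contig}\tltrscape\tregion\t{iv.start + 1}\t{iv.end}\t.\t.\t.\t"
                f"ID=rip_region_{i}\n"
            )
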