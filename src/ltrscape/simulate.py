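"""Synthetic genomes with planted genes and LTR elements of known age.

The generator emulates the structure of a repeat-inflated fungal assembly:
i.i.d. background at a configurable GC, multi-exon genes with a higher
coding GC, and full-length LTR retrotransposons whose twin terminal repeats
start identical and are mutated independently under a Jukes-Cantor clock at
rate r substitutions/site/year for the element's age.  Expected pairwise
divergence between the twins is therefore 2*r*age, the quantity the dating
stage inverts.  Optional RIP-like C->T hypermutation can be applied to a
fraction of elements.  Everything is deterministic under the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .core import (
    GenomeSet,
    GeneModel,
    Interval,
    LtrElement,
    RepeatAnnotation,
    write_fasta,
    write_gff3,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")

DEFAULT_CLOCK_RATE = 1.02e-9  # substitutions / site / year, per lineage


class PlacementError(RuntimeError):
    """Planted features do not fit: genome too small."""


@dataclass
class ElementSpec:
    """One cohort of identical-structure LTR elements planted at a known age."""

    superfamily: str = "Gypsy"
    ltr_length: int = 1000
    internal_length: int = 3900
    age_years: float = 30e6
    copies: int = 10

    def __post_init__(self) -> None:
        # tolerate YAML 1.1 scalars ("2.0e7" arrives as a string)
        self.ltr_length = int(self.ltr_length)
        self.internal_length = int(self.internal_length)
        self.age_years = float(self.age_years)
        self.copies = int(self.copies)
        if self.ltr_length < 100:
            raise ValueError("ltr_length must be >= 100")
        if self.age_years < 0 or self.copies < 0 or self.internal_length < 1:
            raise ValueError("invalid ElementSpec")

    @property
    def span_length(self) -> int:
        return 2 * self.ltr_length + self.internal_length


@dataclass
class SimConfig:
    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 500_000
    gc_fraction: float = 0.447
    n_genes: int = 120
    exons_per_gene: int = 3
    mean_exon_len: int = 539
    mean_intron_len: int = 112
    coding_gc: float = 0.61
    elements: list[ElementSpec] = field(
        default_factory=lambda: [
            ElementSpec("Gypsy", 1000, 3900, 30e6, 24),
            ElementSpec("Copia", 1000, 3900, 30e6, 22),
        ]
    )
    clock_rate: float = DEFAULT_CLOCK_RATE
    rip_fraction: float = 0.0
    rip_intensity: float = 0.0
    tsd_length_range: tuple[int, int] = (4, 6)

    def __post_init__(self) -> None:
        self.gc_fraction = float(self.gc_fraction)
        self.clock_rate = float(self.clock_rate)
        self.rip_fraction = float(self.rip_fraction)
        self.rip_intensity = float(self.rip_intensity)
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0,1)")
        if not 0 <= self.rip_fraction <= 1 or not 0 <= self.rip_intensity <= 1:
            raise ValueError("rip_fraction/rip_intensity must be in [0,1]")
        if min(self.n_contigs, self.contig_length, self.n_genes, self.exons_per_gene) < 0:
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "elements" in data:
            data["elements"] = [
                e if isinstance(e, ElementSpec) else ElementSpec(**e)
                for e in data["elements"]
            ]
        if "tsd_length_range" in data:
            data["tsd_length_range"] = tuple(data["tsd_length_range"])
        return cls(**data)


@dataclass
class TruthRecord:
    """Ground truth for one planted element (the acceptance surface)."""

    element_id: str
    superfamily: str
    true_age_years: float
    p_distance: float  # realized twin-LTR p-distance at emission
    rip_applied: bool


@dataclass
class SimResult:
    genome: GenomeSet
    genes: list[GeneModel]
    repeats: list[RepeatAnnotation]
    elements: list[LtrElement]
    truth: list[TruthRecord]
    config: SimConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "annotations.gff3",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.genome, paths["fasta"])
        write_gff3(paths["gff3"], self.genome, self.genes, self.repeats, self.elements)
        with open(paths["truth"], "w") as fh:
            fh.write(f"# seed={self.config.seed}\n")
            fh.write("element_id\tsuperfamily\ttrue_age_years\tp_distance\trip_applied\n")
            for t in self.truth:
                fh.write(
                    f"{t.element_id}\t{t.superfamily}\t{t.true_age_years:g}"
                    f"\t{t.p_distance:.6f}\t{int(t.rip_applied)}\n"
                )
        return paths


# ---------------------------------------------------------------------------
# sequence-level primitives


def random_seq(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    arr = rng.choice(_BASES, size=length, p=p)
    return arr.tobytes().decode()


def jc_expected_p(expected_subs_per_site: float) -> float:
    """Probability a site shows a different base after mu expected substitutions."""
    return 0.75 * (1.0 - math.exp(-4.0 * expected_subs_per_site / 3.0))


def mutate_clock(seq: str, expected_subs_per_site: float, rng: np.random.Generator) -> str:
    """Evolve a sequence under the Jukes-Cantor process.

    Each non-N site is replaced, with the exact JC transition probability
    (3/4)(1 - exp(-4*mu/3)), by one of the three other bases chosen
    uniformly; multiple hits are thereby accounted for and the output is a
    draw from the true finite-time JC transition.  N sites are untouched.
    """
    if expected_subs_per_site < 0:
        raise ValueError("expected_subs_per_site must be >= 0")
    if expected_subs_per_site == 0 or not seq:
        return seq
    p_diff = jc_expected_p(expected_subs_per_site)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    eligible = arr != _N
    hit = (rng.random(arr.size) < p_diff) & eligible
    idx = np.nonzero(hit)[0]
    if idx.size:
        # uniformly one of the 3 other bases: offset current base index by 1..3
        cur = np.searchsorted(_BASES, arr[idx])
        offset = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(cur + offset) % 4]
    return arr.tobytes().decode()


def apply_rip(seq: str, intensity: float, rng: np.random.Generator) -> str:
    """RIP-like hypermutation: C->T at CpA and G->A at TpG.

    The TpG event is the CpA event seen on the opposite strand.  Contexts
    are read from the input in one left-to-right pass (mutations do not
    create new targets), each target firing independently with probability
    `intensity`.
    """
    if not 0 <= intensity <= 1:
        raise ValueError("intensity must be in [0,1]")
    if intensity == 0 or len(seq) < 2:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    c, a, g, t = (ord(x) for x in "CAGT")
    cpa = np.nonzero((arr[:-1] == c) & (arr[1:] == a))[0]
    tpg = np.nonzero((arr[:-1] == t) & (arr[1:] == g))[0] + 1
    fire_c = cpa[rng.random(cpa.size) < intensity]
    fire_g = tpg[rng.random(tpg.size) < intensity]
    arr[fire_c] = t
    arr[fire_g] = a
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# placement and assembly


def _positive_len(mean: int, rng: np.random.Generator) -> int:
    # Poisson(mean-1)+1: strictly positive with the requested mean
    return int(rng.poisson(max(mean - 1, 0))) + 1


def _plan_positions(
    feature_lengths: list[int], contig_length: int, rng: np.random.Generator
) -> list[int]:
    """Stick-breaking placement: non-overlapping starts for features in
    random order along one contig.  Raises PlacementError if they cannot fit.
    """
    total = sum(feature_lengths)
    slack = contig_length - total
    if slack < 0:
        raise PlacementError(
            f"planted features ({total} bp) exceed contig length {contig_length}: "
            "genome too small"
        )
    n = len(feature_lengths)
    if n == 0:
        return []
    # split slack into n+1 non-negative gaps, uniformly at random
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
    starts, pos = [], 0
    for length, gap in zip(feature_lengths, gaps[:-1]):
        pos += int(gap)
        starts.append(pos)
        pos += length
    return starts


def _build_element(
    spec: ElementSpec, config: SimConfig, rng: np.random.Generator
) -> tuple[str, int, int, float, bool]:
    """Return (insert_seq, tsd_len, ltr_len, realized_p, rip_applied).

    Layout of the insert: TSD + LTR5 + internal + LTR3 + TSD.
    """
    mu = config.clock_rate * spec.age_years  # per-lineage expected subs/site
    ancestral = "TG" + random_seq(spec.ltr_length - 4, config.gc_fraction, rng) + "CA"
    ltr5 = mutate_clock(ancestral, mu, rng)
    ltr3 = mutate_clock(ancestral, mu, rng)
    # re-impose the canonical termini (4 sites; negligible for dating)
    ltr5 = "TG" + ltr5[2:-2] + "CA"
    ltr3 = "TG" + ltr3[2:-2] + "CA"
    internal = random_seq(spec.internal_length, config.gc_fraction, rng)
    ripped = bool(rng.random() < config.rip_fraction)
    if ripped:
        body = apply_rip(ltr5 + internal + ltr3, config.rip_intensity, rng)
        L = spec.ltr_length
        ltr5, internal, ltr3 = body[:L], body[L:-L], body[-L:]
    p = sum(a != b for a, b in zip(ltr5, ltr3)) / spec.ltr_length
    tsd_len = int(rng.integers(config.tsd_length_range[0], config.tsd_length_range[1] + 1))
    tsd = random_seq(tsd_len, config.gc_fraction, rng)
    return tsd + ltr5 + internal + ltr3 + tsd, tsd_len, spec.ltr_length, p, ripped


def simulate_genome(config: SimConfig) -> SimResult:
    """Generate a genome with planted genes and dated LTR elements.

    Draw order (all from one seeded generator): per element cohort the
    element sequences, then gene structures, then placements contig by
    contig, then background fill.
    """
    rng = np.random.default_rng(config.seed)

    # 1. element inserts
    inserts: list[tuple[str, dict]] = []
    eid = 0
    for spec in config.elements:
        for _ in range(spec.copies):
            seq, tsd_len, ltr_len, p, ripped = _build_element(spec, config, rng)
            eid += 1
            inserts.append(
                (
                    seq,
                    dict(
                        element_id=f"ltr{eid:05d}",
                        superfamily=spec.superfamily,
                        tsd_len=tsd_len,
                        ltr_len=ltr_len,
                        age=spec.age_years,
                        p=p,
                        ripped=ripped,
                    ),
                )
            )

    # 2. gene structures (exon/intron lengths)
    gene_plans: list[list[int]] = []  # alternating exon, intron, exon... lengths
    for _ in range(config.n_genes):
        parts = []
        for i in range(config.exons_per_gene):
            if i:
                parts.append(_positive_len(config.mean_intron_len, rng))
            parts.append(_positive_len(config.mean_exon_len, rng))
        gene_plans.append(parts)

    # 3. assign features to contigs round-robin, then place by stick-breaking
    features: list[tuple[str, int, object]] = []  # (kind, length, payload)
    for seq, meta in inserts:
        features.append(("element", len(seq), (seq, meta)))
    for gi, parts in enumerate(gene_plans):
        features.append(("gene", sum(parts), (f"g{gi + 1:05d}", parts)))
    order = rng.permutation(len(features))

    per_contig: list[list[tuple[str, int, object]]] = [[] for _ in range(config.n_contigs)]
    loads = [0] * max(config.n_contigs, 1)
    for k in order:
        kind, length, payload = features[k]
        if config.n_contigs == 0:
            raise PlacementError("no contigs to place features on: genome too small")
        tgt = loads.index(min(loads))  # least-loaded contig
        per_contig[tgt].append((kind, length, payload))
        loads[tgt] += length

    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    repeats: list[RepeatAnnotation] = []
    elements: list[LtrElement] = []
    truth: list[TruthRecord] = []

    for ci in range(config.n_contigs):
        name = f"contig{ci + 1:03d}"
        def _key(f):
            kind, _, payload = f
            return payload[1]["element_id"] if kind == "element" else payload[0]

        feats = sorted(per_contig[ci], key=_key)  # stable order
        starts = _plan_positions([f[1] for f in feats], config.contig_length, rng)
        pieces, cursor = [], 0
        for (kind, length, payload), start in zip(feats, starts):
            pieces.append(random_seq(start - cursor, config.gc_fraction, rng))
            if kind == "element":
                seq, meta = payload
                pieces.append(seq)
                t, L = meta["tsd_len"], meta["ltr_len"]
                s5 = start + t
                s3 = start + length - t - L
                ltr5 = Interval(name, s5, s5 + L)
                ltr3 = Interval(name, s3, s3 + L)
                internal = Interval(name, ltr5.end, ltr3.start)
                el = LtrElement(meta["element_id"], ltr5, ltr3, internal,
                                meta["superfamily"], complete=True)
                elements.append(el)
                repeats.append(el.as_repeat())
                truth.append(
                    TruthRecord(meta["element_id"], meta["superfamily"],
                                meta["age"], meta["p"], meta["ripped"])
                )
            else:
                gene_id, parts = payload
                exons, off = [], start
                for i, plen in enumerate(parts):
                    if i % 2 == 0:  # exon
                        exons.append(Interval(name, off, off + plen, "+"))
                        pieces.append(random_seq(plen, config.coding_gc, rng))
                    else:  # intron: background composition
                        pieces.append(random_seq(plen, config.gc_fraction, rng))
                    off += plen
                genes.append(GeneModel(gene_id, exons))
            cursor = start + length
        pieces.append(random_seq(config.contig_length - cursor, config.gc_fraction, rng))
        genome[name] = "".join(pieces)

    elements.sort(key=lambda e: (e.contig, e.span.start))
    genes.sort(key=lambda g: (g.contig, g.span.start))
    repeats.sort(key=lambda r: (r.interval.contig, r.interval.start))
    truth.sort(key=lambda t: t.element_id)
    return SimResult(GenomeSet(genome), genes, repeats, elements, truth, config)
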