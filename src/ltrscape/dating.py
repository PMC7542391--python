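"""Paired-LTR insertion dating and the repeat-landscape histogram.

An LTR retrotransposon's two terminal repeats are identical when it inserts
and accumulate substitutions independently afterwards, so the corrected
divergence K between them, under a per-lineage clock rate r, dates the
insertion as T = K / (2 r).  Divergence is computed from a global affine-gap
alignment of the twin repeats with pairwise deletion of gap/N columns and a
Jukes-Cantor correction (Kimura 2-parameter available as an option).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align

from .core import GenomeSet, Interval, LtrElement

logger = logging.getLogger(__name__)

DEFAULT_CLOCK_RATE = 1.02e-9  # substitutions / site / year, per lineage


class SaturationError(ValueError):
    """Observed divergence too high for the correction (p >= 3/4)."""


class UndefinedDistanceError(ValueError):
    """No gap-free, N-free aligned columns to compute a distance from."""


@dataclass(frozen=True)
class ClockRate:
    r: float = DEFAULT_CLOCK_RATE

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("clock rate must be > 0")


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring; gap_open is the score of a gap's first position."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass
class AgeEstimate:
    element_id: str
    superfamily: str
    span_length: int
    aligned_sites: int
    p: float
    K: float
    T: float


@dataclass
class LandscapeBin:
    k_low: float
    k_high: float
    lengths: dict[str, int] = field(default_factory=dict)  # superfamily -> bases

    @property
    def total(self) -> int:
        return sum(self.lengths.values())


@dataclass
class Landscape:
    bin_width: float
    bins: list[LandscapeBin]
    undatable_length: int = 0
    undatable_ids: list[str] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(b.total for b in self.bins) + self.undatable_length

    def modal_bin(self) -> Optional[LandscapeBin]:
        dated = [b for b in self.bins if b.total > 0]
        return max(dated, key=lambda b: b.total) if dated else None


# ---------------------------------------------------------------------------
# alignment and distances


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_twin_ltrs(
    seq5: str, seq3: str, scoring: Scoring = Scoring()
) -> tuple[str, str]:
    """Optimal global alignment of the two terminal repeats.

    Returns the two gapped rows (equal length).  The aligner is
    deterministic: of co-optimal alignments the first in its enumeration
    order is reported.
    """
    if not seq5 or not seq3:
        raise ValueError("cannot align empty sequences")
    aln = _make_aligner(scoring).align(seq5.upper(), seq3.upper())[0]
    return str(aln[0]), str(aln[1])


def alignment_score(seq5: str, seq3: str, scoring: Scoring = Scoring()) -> float:
    return _make_aligner(scoring).score(seq5.upper(), seq3.upper())


def p_distance(alignment: tuple[str, str]) -> tuple[float, int]:
    """Observed mismatch proportion with pairwise deletion.

    Columns containing a gap or N in either row are excluded; p is the
    mismatch fraction over the remaining columns.
    """
    row5, row3 = alignment
    if len(row5) != len(row3) or not row5:
        raise ValueError("alignment rows must be non-empty and equal length")
    sites = mismatches = 0
    for a, b in zip(row5, row3):
        if a in "-N" or b in "-N":
            continue
        sites += 1
        if a != b:
            mismatches += 1
    if sites == 0:
        raise UndefinedDistanceError("no gap-free, N-free aligned columns")
    return mismatches / sites, sites


def jc_correction(p: float) -> float:
    """Jukes-Cantor corrected divergence K = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"p = {p} is at or beyond JC saturation (3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k2p_correction(alignment: tuple[str, str]) -> float:
    """Kimura 2-parameter distance from an alignment (pairwise deletion).

    K = -(1/2) ln((1-2P-Q) sqrt(1-2Q)) with P, Q the transition and
    transversion proportions.
    """
    row5, row3 = alignment
    sites = ts = tv = 0
    for a, b in zip(row5, row3):
        if a in "-N" or b in "-N":
            continue
        sites += 1
        if a != b:
            if (a, b) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if sites == 0:
        raise UndefinedDistanceError("no gap-free, N-free aligned columns")
    P, Q = ts / sites, tv / sites
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("divergence beyond K2P saturation")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def insertion_age(K: float, rate: ClockRate = ClockRate()) -> float:
    """Years since insertion: T = K / (2 r)."""
    if K < 0:
        raise ValueError("K must be >= 0")
    return K / (2.0 * rate.r)


# ---------------------------------------------------------------------------
# element-level driver


def date_elements(
    genome: GenomeSet,
    elements: Iterable[LtrElement],
    rate: ClockRate = ClockRate(),
    scoring: Scoring = Scoring(),
    model: str = "jc",
) -> tuple[list[AgeEstimate], list[tuple[str, str]]]:
    """Estimate insertion ages for complete elements.

    Returns (estimates, skipped) where skipped holds (element_id, reason)
    for incomplete or saturated/undatable elements.
    """
    if model not in {"jc", "k2p"}:
        raise ValueError("model must be 'jc' or 'k2p'")
    estimates: list[AgeEstimate] = []
    skipped: list[tuple[str, str]] = []
    for el in elements:
        if not el.complete:
            skipped.append((el.element_id, "incomplete: missing a terminal repeat"))
            continue
        aln = align_twin_ltrs(genome.fetch(el.ltr5), genome.fetch(el.ltr3), scoring)
        try:
            p, sites = p_distance(aln)
            K = jc_correction(p) if model == "jc" else k2p_correction(aln)
        except SaturationError:
            skipped.append((el.element_id, "saturated: undatable divergence"))
            continue
        except UndefinedDistanceError:
            skipped.append((el.element_id, "no alignable sites"))
            continue
        estimates.append(
            AgeEstimate(el.element_id, el.superfamily, el.span.length,
                        sites, p, K, insertion_age(K, rate))
        )
    return estimates, skipped


def build_landscape(
    estimates: Sequence[AgeEstimate],
    elements: Iterable[LtrElement],
    bin_width_K: float = 0.01,
) -> Landscape:
    """Stacked histogram of total element length by corrected divergence K.

    Each dated element contributes its full span length to the bin holding
    its K, stacked by superfamily; elements with no estimate (incomplete or
    saturated) accumulate in the undatable tally so that bin totals plus
    undatable length conserve the total element length exactly.
    """
    if bin_width_K <= 0:
        raise ValueError("bin_width_K must be > 0")
    by_id = {e.element_id: e for e in elements}
    dated_ids = {a.element_id for a in estimates}
    n_bins = 0
    if estimates:
        n_bins = max(int(a.K // bin_width_K) for a in estimates) + 1
    bins = [
        LandscapeBin(i * bin_width_K, (i + 1) * bin_width_K) for i in range(n_bins)
    ]
    for a in estimates:
        if a.element_id not in by_id:
            raise KeyError(f"estimate for unknown element {a.element_id}")
        b = bins[int(a.K // bin_width_K)]
        b.lengths[a.superfamily] = b.lengths.get(a.superfamily, 0) + a.span_length
    undatable = [e for i, e in by_id.items() if i not in dated_ids]
    return Landscape(
        bin_width_K,
        bins,
        undatable_length=sum(e.span.length for e in undatable),
        undatable_ids=sorted(e.element_id for e in undatable),
    )


def plot_landscape(landscape: Landscape, path: str, rate: ClockRate = ClockRate()):
    """Stacked-bar landscape figure (divergence on x, summed length on y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    superfamilies = sorted({sf for b in landscape.bins for sf in b.lengths})
    x = [b.k_low for b in landscape.bins]
    bottom = [0.0] * len(landscape.bins)
    fig, ax = plt.subplots(figsize=(8, 4))
    for sf in superfamilies:
        heights = [b.lengths.get(sf, 0) / 1e3 for b in landscape.bins]
        ax.bar(x, heights, width=landscape.bin_width * 0.9, bottom=bottom,
               align="edge", label=sf)
        bottom = [b + h for b, h in zip(bottom, heights)]
    ax.set_xlabel("divergence K (substitutions/site)")
    ax.set_ylabel("summed element length (kbp)")
    secax = ax.secondary_xaxis(
        "top", functions=(lambda k: k / (2 * rate.r) / 1e6,
                          lambda t: t * 2 * rate.r * 1e6)
    )
    secax.set_xlabel("insertion age (Mya)")
    if superfamilies:
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# minimal direct-repeat detector (plumbing so synthetic genomes run
# end-to-end without an external LTR finder)


def detect_ltr_pairs(
    seq: str,
    min_ltr_len: int = 100,
    max_internal_len: int = 20_000,
    min_identity: float = 0.85,
    k: int = 13,
    max_ltr_len: int = 5_000,
    contig: str = "contig",
) -> list[LtrElement]:
    """Find candidate full-length elements as similar direct-repeat pairs.

    Exact k-mer seeds shared at an offset d are clustered per diagonal and
    extended without gaps under an X-drop rule; a candidate pair is kept if
    each repeat is >= min_ltr_len, their ungapped identity >= min_identity
    and the gap between them is within (0, max_internal_len].  Overlapping
    candidates are resolved by identity, then length, then leftmost start.
    """
    if min_ltr_len <= 0 or max_internal_len <= 0 or not 0 < min_identity <= 1:
        raise ValueError("invalid detector thresholds")
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_ltr_len:
        return []

    seeds: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        seeds.setdefault(kmer, []).append(i)

    max_d = max_ltr_len + max_internal_len
    diagonals: dict[int, list[int]] = {}
    for positions in seeds.values():
        if len(positions) < 2 or len(positions) > 50:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                d = positions[b] - positions[a]
                if min_ltr_len <= d <= max_d:
                    diagonals.setdefault(d, []).append(positions[a])

    candidates = []
    for d, starts in diagonals.items():
        starts.sort()
        runs: list[list[int]] = [[starts[0], starts[0]]]
        for s in starts[1:]:
            if s - runs[-1][1] <= 500:
                runs[-1][1] = s
            else:
                runs.append([s, s])
        for lo, hi in runs:
            hi += k
            lo, hi = _xdrop_extend(seq, lo, hi, d)
            length = hi - lo
            gap = d - length  # bases between repeat1 end and repeat2 start
            if length < min_ltr_len or length > max_ltr_len:
                continue
            if gap < 1 or gap > max_internal_len:
                continue
            ident = _ungapped_identity(seq, lo, hi, d)
            if ident < min_identity:
                continue
            candidates.append((ident, length, lo, hi, d))

    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    kept: list[tuple[int, int]] = []
    elements: list[LtrElement] = []
    for ident, length, lo, hi, d in candidates:
        span = (lo, lo + d + length)
        if any(span[0] < e and span[1] > s for s, e in kept):
            continue
        kept.append(span)
        ltr5 = Interval(contig, lo, hi)
        ltr3 = Interval(contig, lo + d, hi + d)
        internal = Interval(contig, ltr5.end, ltr3.start)
        elements.append(
            LtrElement(f"det{len(elements) + 1:05d}", ltr5, ltr3, internal,
                       "Unknown", complete=True)
        )
    elements.sort(key=lambda e: e.span.start)
    for i, e in enumerate(elements, 1):
        e.element_id = f"det{i:05d}"
    return elements


def _xdrop_extend(
    seq: str, lo: int, hi: int, d: int, xdrop: int = 15
) -> tuple[int, int]:
    """Extend [lo, hi) vs [lo+d, hi+d) ungapped in both directions."""
    n = len(seq)
    # right
    best, score, i, best_i = 0, 0, hi, hi
    while i < n - d and i < lo + d:  # repeats must not overlap
        score += 1 if seq[i] == seq[i + d] else -2
        i += 1
        if score > best:
            best, best_i = score, i
        if best - score > xdrop:
            break
    hi = best_i
    # left
    best, score, i, best_i = 0, 0, lo, lo
    while i > 0:
        i -= 1
        score += 1 if seq[i] == seq[i + d] else -2
        if score > best:
            best, best_i = score, i
        if best - score > xdrop:
            break
    lo = best_i
    return lo, hi


def _ungapped_identity(seq: str, lo: int, hi: int, d: int) -> float:
    m = sum(seq[i] == seq[i + d] for i in range(lo, hi))
    return m / (hi - lo)


# ---------------------------------------------------------------------------
# tabular output


def write_age_table(estimates: Sequence[AgeEstimate], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("element_id\tsuperfamily\tspan_length\taligned_sites\tp\tK\tT_years\n")
        for a in estimates:
            fh.write(
                f"{a.element_id}\t{a.superfamily}\t{a.span_length}\t{a.aligned_sites}"
                f"\t{a.p:.6f}\t{a.K:.6f}\t{a.T:.1f}\n"
            )


def write_landscape_table(landscape: Landscape, path: str) -> None:
    superfamilies = sorted({sf for b in landscape.bins for sf in b.lengths})
    with open(path, "w") as fh:
        fh.write("K_low\tK_high\t" + "\t".join(superfamilies) + "\ttotal\n")
        for b in landscape.bins:
            row = "\t".join(str(b.lengths.get(sf, 0)) for sf in superfamilies)
            fh.write(f"{b.k_low:.4f}\t{b.k_high:.4f}\t{row}\t{b.total}\n")
        fh.write(f"# undatable_length\t{landscape.undatable_length}\n")
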