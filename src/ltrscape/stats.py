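"""Assembly and composition accounting.

N50, GC content, sequencing coverage fold, per-category repeat composition,
LTR superfamily abundance tables and gene-model statistics.  All arithmetic
is kept at full precision; display rounding (half away from zero, one
decimal) is applied only at presentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence, Union

from .core import (
    GeneModel,
    GenomeSet,
    LtrElement,
    RepeatAnnotation,
    merge_intervals,
)

logger = logging.getLogger(__name__)


def round_display(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of printed genome tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def n50(contig_lengths: Sequence[int]) -> int:
    """Smallest length L with the summed length of contigs >= L covering at
    least half the assembly."""
    if not contig_lengths:
        raise ValueError("n50 of an empty assembly")
    if min(contig_lengths) <= 0:
        raise ValueError("contig lengths must be positive")
    ordered = sorted(contig_lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for L in ordered:
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")


def gc_content(genome: Union[GenomeSet, str]) -> float:
    """Percent G+C over non-N bases."""
    seqs = [genome] if isinstance(genome, str) else genome.contigs.values()
    gc = atgc = 0
    for seq in seqs:
        s = seq.upper()
        g = s.count("G") + s.count("C")
        gc += g
        atgc += g + s.count("A") + s.count("T")
    if atgc == 0:
        raise ValueError("no non-N bases")
    return 100.0 * gc / atgc


def coverage_fold(total_sequenced_bases: float, genome_size: float) -> float:
    if total_sequenced_bases <= 0 or genome_size <= 0:
        raise ValueError("inputs must be > 0")
    return total_sequenced_bases / genome_size


def percent(part: float, whole: float) -> float:
    if whole <= 0:
        raise ValueError("whole must be > 0")
    return 100.0 * part / whole


@dataclass
class CompositionReport:
    genome_size: int
    category_bases: dict[str, int]  # merged within category
    coding_bases: int
    gc_pct: float
    coding_gc_pct: Optional[float]

    @property
    def category_pct(self) -> dict[str, float]:
        return {c: percent(b, self.genome_size) for c, b in self.category_bases.items()}

    @property
    def repeat_total_pct(self) -> float:
        # categories are independent tracks; overlaps across categories are
        # merged here so the repeat total is a true genomic fraction
        return percent(self._repeat_union_bases, self.genome_size)

    @property
    def coding_pct(self) -> float:
        return percent(self.coding_bases, self.genome_size)

    _repeat_union_bases: int = 0

    def formatted(self) -> dict[str, float]:
        out = {f"{c}_pct": round_display(p) for c, p in self.category_pct.items()}
        out["coding_pct"] = round_display(self.coding_pct)
        out["repeat_total_pct"] = round_display(self.repeat_total_pct)
        out["GC_pct"] = round_display(self.gc_pct)
        if self.coding_gc_pct is not None:
            out["coding_GC_pct"] = round_display(self.coding_gc_pct)
        return out


def composition_report(
    genome: GenomeSet,
    genes: Iterable[GeneModel] = (),
    repeats: Iterable[RepeatAnnotation] = (),
) -> CompositionReport:
    """Per-category repeat and coding composition.

    Within a category, overlapping intervals are merged and counted once;
    across categories each track is accounted independently (so percentages
    need not sum to 100).  Coding bases come from merged exon intervals;
    coding GC from the exon sequence itself.
    """
    genes = list(genes)
    repeats = list(repeats)
    by_cat: dict[str, list] = {}
    for r in repeats:
        by_cat.setdefault(r.category, []).append(r.interval)
    category_bases = {
        cat: sum(iv.length for iv in merge_intervals(ivs))
        for cat, ivs in sorted(by_cat.items())
    }
    repeat_union = sum(
        iv.length for iv in merge_intervals([r.interval for r in repeats])
    ) if repeats else 0

    exon_ivs = merge_intervals([e for g in genes for e in g.exons]) if genes else []
    coding_bases = sum(iv.length for iv in exon_ivs)
    coding_gc = None
    if coding_bases:
        coding_seq = "".join(genome.fetch(iv) for iv in exon_ivs)
        coding_gc = gc_content(coding_seq)

    report = CompositionReport(
        genome_size=genome.total_length,
        category_bases=category_bases,
        coding_bases=coding_bases,
        gc_pct=gc_content(genome),
        coding_gc_pct=coding_gc,
    )
    report._repeat_union_bases = repeat_union
    return report


@dataclass
class LtrTypeTable:
    """Per-superfamily element counts and summed lengths with their share
    of the total LTR length."""

    counts: dict[str, int]
    lengths_bp: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.counts) != set(self.lengths_bp):
            raise ValueError("counts and lengths must cover the same superfamilies")

    @classmethod
    def from_elements(
        cls, records: Iterable[Union[LtrElement, RepeatAnnotation]]
    ) -> "LtrTypeTable":
        counts: dict[str, int] = {}
        lengths: dict[str, int] = {}
        for rec in records:
            if isinstance(rec, LtrElement):
                sf, length = rec.superfamily, rec.span.length
            else:
                if rec.category != "LTR":
                    raise ValueError("ltr_type_table expects LTR records")
                sf, length = rec.superfamily or "Unknown", rec.interval.length
            counts[sf] = counts.get(sf, 0) + 1
            lengths[sf] = lengths.get(sf, 0) + length
        return cls(counts, lengths)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def total_length_bp(self) -> int:
        return sum(self.lengths_bp.values())

    @property
    def percent_of_total_length(self) -> dict[str, float]:
        total = self.total_length_bp
        return {sf: percent(L, total) for sf, L in self.lengths_bp.items()}

    def validate_margin(self, stated_total_count: int, stated_total_length_bp: int) -> None:
        """Warn when a stated totals row disagrees with the column sums."""
        if stated_total_count != self.total_count:
            logger.warning(
                "LTR table count margin %d != column sum %d",
                stated_total_count, self.total_count,
            )
        if stated_total_length_bp != self.total_length_bp:
            logger.warning(
                "LTR table length margin %d != column sum %d",
                stated_total_length_bp, self.total_length_bp,
            )

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("superfamily\tcount\tlength_kbp\tpct_of_total_ltr\n")
            for sf in sorted(self.counts):
                fh.write(
                    f"{sf}\t{self.counts[sf]}\t{self.lengths_bp[sf] / 1e3:.3f}"
                    f"\t{round_display(self.percent_of_total_length[sf])}\n"
                )
            fh.write(
                f"Total\t{self.total_count}\t{self.total_length_bp / 1e3:.3f}\t100.0\n"
            )


def ltr_type_table(records: Iterable[Union[LtrElement, RepeatAnnotation]]) -> LtrTypeTable:
    return LtrTypeTable.from_elements(records)


def gene_model_stats(genes: Sequence[GeneModel]) -> dict[str, float]:
    """Mean gene span, exons per gene, exon length and intron length."""
    if not genes:
        raise ValueError("no genes")
    spans = [g.span.length for g in genes]
    exon_lengths = [e.length for g in genes for e in g.exons]
    intron_lengths = [iv.length for g in genes for iv in g.introns()]
    return {
        "mean_gene_span": sum(spans) / len(genes),
        "mean_exons_per_gene": len(exon_lengths) / len(genes),
        "mean_exon_length": sum(exon_lengths) / len(exon_lengths),
        "mean_intron_length": (
            sum(intron_lengths) / len(intron_lengths) if intron_lengths else float("nan")
        ),
    }


def complete_ltr_stats(
    elements: Iterable[LtrElement],
) -> tuple[int, Optional[float], int]:
    """(count, mean span length, total span length) over complete elements."""
    spans = [e.span.length for e in elements if e.complete]
    total = sum(spans)
    mean = total / len(spans) if spans else None
    return len(spans), mean, total
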