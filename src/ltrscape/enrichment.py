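"""Exact and chi-square enrichment machinery.

Covers gene-family enrichment in LTR-flanking regions (one-sided Fisher
against the genome background), subset-vs-genome enrichment of gene
classes, the k x 2 multi-genome chi-square comparison of functional
categories, and the stated threshold filter for tabular homology hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneModel, GenomeSet, Interval, interval_overlap

logger = logging.getLogger(__name__)

ALTERNATIVES = {"greater", "less", "two_sided"}


@dataclass
class EnrichmentResult:
    label: str
    foreground_count: int
    background_count: int
    p_value: float
    q_value: Optional[float] = None


@dataclass(frozen=True)
class FlankRule:
    flank: int = 1000

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass(frozen=True)
class HitFilter:
    """Thresholds applied to tabular homology hits: keep a row when
    identity >= min_identity_pct, query coverage >= min_coverage_pct and the
    reported significance value <= max_p."""

    min_identity_pct: float = 30.0
    min_coverage_pct: float = 50.0
    max_p: float = 1e-10

    def __post_init__(self) -> None:
        ok = 0 <= self.min_identity_pct <= 100 and 0 <= self.min_coverage_pct <= 100
        if not ok or not 0 < self.max_p <= 1:
            raise ValueError("invalid HitFilter thresholds")


GO_FILTER = HitFilter(30.0, 50.0, 1e-10)
PHI_FILTER = HitFilter(50.0, 50.0, 1e-10)


def fisher_exact_2x2(table: Sequence[Sequence[int]], alternative: str = "greater") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    One-sided alternatives sum the hypergeometric tail; two_sided sums all
    tables with point probability <= that of the observed table.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(ALTERNATIVES)}")
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if t.sum() == 0:
        raise ValueError("table total is zero")
    alt = "two-sided" if alternative == "two_sided" else alternative
    return float(stats.fisher_exact(t, alternative=alt).pvalue)


def chi_square_rxc(table: Sequence[Sequence[int]]) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c table: (statistic, df, p_value).

    Expected counts come from the margins; no continuity correction.  Cells
    with expected count < 5 trigger a logged warning.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2 or (t < 0).any():
        raise ValueError("table must be at least 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    res = stats.chi2_contingency(t, correction=False)
    if (res.expected_freq < 5).any():
        logger.warning(
            "chi-square: %d cell(s) with expected count < 5",
            int((res.expected_freq < 5).sum()),
        )
    return float(res.statistic), int(res.dof), float(res.pvalue)


def flank_overlap_genes(
    ltr_regions: Iterable[Interval],
    genes: Iterable[GeneModel],
    rule: FlankRule = FlankRule(),
    genome: Optional[GenomeSet] = None,
) -> set[tuple[str, Optional[str]]]:
    """Genes whose coding intervals overlap an LTR region extended by the
    flank on both sides (>= 1 base); extension is clipped at contig ends.
    Each gene appears at most once."""
    extended: dict[str, list[Interval]] = {}
    for r in ltr_regions:
        limit = len(genome.contigs[r.contig]) if genome else None
        start = max(0, r.start - rule.flank)
        end = r.end + rule.flank if limit is None else min(limit, r.end + rule.flank)
        extended.setdefault(r.contig, []).append(Interval(r.contig, start, end))
    hits: set[tuple[str, Optional[str]]] = set()
    for g in genes:
        regions = extended.get(g.contig, ())
        if any(
            interval_overlap(exon, region) > 0
            for exon in g.exons
            for region in regions
        ):
            hits.add((g.gene_id, g.family))
    return hits


def family_enrichment(
    overlap_set: set[tuple[str, Optional[str]]],
    family_of_gene: Mapping[str, str],
    all_genes: Iterable[str],
    with_q_values: bool = True,
) -> list[EnrichmentResult]:
    """Per-family one-sided (greater) Fisher enrichment of the overlap set
    against the genome background; sorted by p then descending count."""
    universe = list(dict.fromkeys(all_genes))
    n_total = len(universe)
    fg_ids = {gid for gid, _ in overlap_set}
    missing = fg_ids - set(universe)
    if missing:
        raise ValueError(f"overlap genes absent from background: {sorted(missing)[:3]}")
    n_fg = len(fg_ids)
    families = sorted({family_of_gene[g] for g in universe if g in family_of_gene})
    results = []
    for fam in families:
        members = {g for g in universe if family_of_gene.get(g) == fam}
        a = len(members & fg_ids)
        b = n_fg - a
        c = len(members) - a
        d = (n_total - n_fg) - c
        p = fisher_exact_2x2([[a, b], [c, d]], "greater")
        results.append(EnrichmentResult(fam, a, len(members), p))
    results.sort(key=lambda r: (r.p_value, -r.foreground_count, r.label))
    if with_q_values and results:
        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


def subset_enrichment(
    subset_hits: int, subset_total: int, background_hits: int, background_total: int
) -> float:
    """One-sided Fisher test that a gene class is over-represented in a
    subset relative to the rest of the genome (exclusive construction:
    subset vs genome-minus-subset)."""
    if not 0 <= subset_hits <= subset_total <= background_total:
        raise ValueError("inconsistent counts")
    if subset_hits > background_hits:
        raise ValueError("subset hits exceed genome-wide hits")
    rest_hits = background_hits - subset_hits
    rest_total = background_total - subset_total
    table = [
        [subset_hits, subset_total - subset_hits],
        [rest_hits, rest_total - rest_hits],
    ]
    return fisher_exact_2x2(table, "greater")


# ---------------------------------------------------------------------------
# tabular homology-hit filtering
#
# 12-column tab-separated dialect (outfmt-6-like, with query length so that
# coverage is computable):
#   1 query  2 subject  3 pct_identity  4 aln_length  5 query_length
#   6 mismatches  7 gap_opens  8 qstart  9 qend  10 sstart  11 send  12 p_value

HIT_COLUMNS = [
    "query", "subject", "pct_identity", "aln_length", "query_length",
    "mismatches", "gap_opens", "qstart", "qend", "sstart", "send", "p_value",
]
_NUMERIC = {
    "pct_identity": float, "aln_length": int, "query_length": int,
    "mismatches": int, "gap_opens": int, "qstart": int, "qend": int,
    "sstart": int, "send": int, "p_value": float,
}


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read the 12-column hit dialect; malformed rows fail with their line
    number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            rec = dict(zip(HIT_COLUMNS, cols))
            for key, cast in _NUMERIC.items():
                try:
                    rec[key] = cast(rec[key])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: bad {key} value {rec[key]!r}"
                    ) from None
            rows.append(rec)
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def filter_hits(hits: pd.DataFrame, rule: HitFilter = GO_FILTER) -> pd.DataFrame:
    """Keep rows meeting the identity, query-coverage and significance
    thresholds; row order is preserved."""
    if hits.empty:
        return hits
    coverage = 100.0 * hits["aln_length"] / hits["query_length"]
    keep = (
        (hits["pct_identity"] >= rule.min_identity_pct)
        & (coverage >= rule.min_coverage_pct)
        & (hits["p_value"] <= rule.max_p)
    )
    return hits[keep]


def write_enrichment_table(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tforeground_count\tbackground_count\tp_value\tq_value\n")
        for r in results:
            q = "NA" if r.q_value is None else f"{r.q_value:.6g}"
            fh.write(
                f"{r.label}\t{r.foreground_count}\t{r.background_count}"
                f"\t{r.p_value:.6g}\t{q}\n"
            )


def read_family_map(path: str | Path) -> dict[str, str]:
    """Two-column tab-separated gene_id -> family label."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out[cols[0]] = cols[1]
    return out
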