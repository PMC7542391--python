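"""Domain types, sequence/annotation I/O and coordinate conventions.

All coordinates are held internally as 0-based half-open intervals; GFF3
files are read and written with the standard 1-based inclusive convention.
Sequences are stored uppercase over the alphabet A, C, G, T, N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

# IUPAC ambiguity codes other than N collapse to N (real repeat libraries
# contain them; every scan here skips N anyway).
_AMBIGUOUS = "RYSWKMBDHVryswkmbdhv"
_IUPAC_TO_N = str.maketrans(_AMBIGUOUS, "N" * len(_AMBIGUOUS))
_VALID = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REPEAT_CATEGORIES = frozenset(
    {
        "LTR",
        "DNA_transposon",
        "LINE",
        "SINE",
        "simple_repeat",
        "low_complexity",
        "small_RNA",
        "other",
    }
)

LTR_SUPERFAMILIES = frozenset({"Copia", "Gypsy", "ERV1", "Ngaro", "Pao", "Unknown"})


class GenomeError(ValueError):
    """Malformed sequence or annotation input."""


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval: 0-based start, exclusive end, optional strand."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise GenomeError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig!r}"
            )
        if self.strand not in {"+", "-", "."}:
            raise GenomeError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def interval_overlap(a: Interval, b: Interval) -> int:
    """Bases shared by two half-open intervals (0 across contigs)."""
    if a.contig != b.contig:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals per contig, sorted; strand is discarded."""
    by_contig: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    merged: list[Interval] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(contig, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(contig, cur_start, cur_end))
    return merged


@dataclass
class GenomeSet:
    """Named contigs; the substrate of every scan and statistic."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise GenomeError("empty contig id")
            bad = set(seq) - _VALID
            if bad:
                raise GenomeError(f"contig {name!r} contains {sorted(bad)}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, iv: Interval) -> str:
        """Sequence under an interval (forward strand)."""
        return self.contigs[iv.contig][iv.start : iv.end]

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass
class GeneModel:
    """A protein-coding gene as a sorted list of exon intervals."""

    gene_id: str
    exons: list[Interval]
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise GenomeError(f"gene {self.gene_id}: no exons")
        contigs = {e.contig for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(contigs) > 1 or len(strands) > 1:
            raise GenomeError(f"gene {self.gene_id}: exons on mixed contig/strand")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise GenomeError(f"gene {self.gene_id}: overlapping exons")

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> Interval:
        return Interval(self.contig, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def coding_length(self) -> int:
        return sum(e.length for e in self.exons)

    def introns(self) -> list[Interval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(Interval(self.contig, a.end, b.start, self.strand))
        return out


@dataclass
class RepeatAnnotation:
    """One repeat interval with its category (and LTR superfamily if any)."""

    interval: Interval
    category: str
    superfamily: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in REPEAT_CATEGORIES:
            raise GenomeError(f"unknown repeat category {self.category!r}")
        if self.superfamily is not None and self.category != "LTR":
            raise GenomeError("superfamily is only meaningful for LTR repeats")
        if self.superfamily is not None and self.superfamily not in LTR_SUPERFAMILIES:
            raise GenomeError(f"unknown LTR superfamily {self.superfamily!r}")


@dataclass
class LtrElement:
    """A full-length LTR retrotransposon: twin terminal repeats + internal span.

    The two terminal repeats are identical at insertion and diverge under the
    host's substitution clock thereafter, which is what makes paired-LTR
    insertion dating possible.
    """

    element_id: str
    ltr5: Interval
    ltr3: Interval
    internal: Interval
    superfamily: str = "Unknown"
    complete: bool = True

    def __post_init__(self) -> None:
        same = self.ltr5.contig == self.internal.contig == self.ltr3.contig
        if not same:
            raise GenomeError(f"element {self.element_id}: parts on different contigs")
        if not (self.ltr5.end <= self.internal.start and self.internal.end <= self.ltr3.start):
            raise GenomeError(f"element {self.element_id}: parts out of order")
        if self.superfamily not in LTR_SUPERFAMILIES:
            raise GenomeError(f"unknown LTR superfamily {self.superfamily!r}")

    @property
    def contig(self) -> str:
        return self.ltr5.contig

    @property
    def span(self) -> Interval:
        return Interval(self.contig, self.ltr5.start, self.ltr3.end)

    def as_repeat(self) -> RepeatAnnotation:
        return RepeatAnnotation(self.span, "LTR", self.superfamily)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSet:
    """Read a (possibly wrapped) multi-FASTA into a GenomeSet.

    The contig id is the header token before the first whitespace.  Sequences
    are uppercased; IUPAC ambiguity codes other than N are coerced to N with
    a warning; any other symbol is a hard error reported with its position.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise GenomeError(f"duplicate contig id {rec.id!r} in {path}")
        raw = str(rec.seq).upper()
        seq = raw.translate(_IUPAC_TO_N)
        if seq != raw:
            n = sum(a != b for a, b in zip(raw, seq))
            logger.warning("contig %s: %d ambiguity code(s) coerced to N", rec.id, n)
        bad = set(seq) - _VALID
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise GenomeError(
                f"contig {rec.id!r}: non-nucleotide symbol {seq[pos]!r} at position {pos}"
            )
        contigs[rec.id] = seq
    return GenomeSet(contigs)


def write_fasta(genome: GenomeSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
#
# Feature-type mapping (our own harmonization convention):
#   gene + CDS children                      -> GeneModel (family= attribute)
#   LTR_retrotransposon with exactly two
#     long_terminal_repeat children          -> LtrElement (complete)
#   LTR_retrotransposon otherwise            -> RepeatAnnotation, category LTR
#   dispersed_repeat (category= attribute)   -> RepeatAnnotation


def _prescan_gff3(path: str | Path, genome: GenomeSet) -> None:
    """Line-level validation so errors carry line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise GenomeError(f"{path}:{lineno}: expected >=8 GFF3 columns")
            contig, _, _, start_s, end_s = cols[0], cols[1], cols[2], cols[3], cols[4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GenomeError(f"{path}:{lineno}: non-integer coordinates") from None
            if start > end:
                raise GenomeError(f"{path}:{lineno}: start {start} > end {end}")
            if contig not in genome.contigs:
                raise GenomeError(f"{path}:{lineno}: unknown contig {contig!r}")
            if start < 1 or end > len(genome.contigs[contig]):
                raise GenomeError(f"{path}:{lineno}: feature outside contig bounds")


def _iv(feature, strand: bool = True) -> Interval:
    s = feature.strand if strand and feature.strand in {"+", "-"} else "."
    return Interval(feature.seqid, feature.start - 1, feature.end, s)


def _attr(feature, key: str) -> Optional[str]:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def read_gff3(
    path: str | Path, genome: GenomeSet
) -> tuple[list[GeneModel], list[RepeatAnnotation], list[LtrElement]]:
    """Parse annotations; coordinates converted to 0-based half-open.

    Every LTR_retrotransposon span also appears in the repeat list (category
    LTR) so composition accounting sees it; complete elements additionally
    yield an LtrElement for dating.
    """
    _prescan_gff3(path, genome)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = [_iv(c) for c in db.children(g, featuretype="CDS", order_by="start")]
        if not exons:
            exons = [_iv(g)]
        genes.append(GeneModel(g.id, exons, family=_attr(g, "family")))

    repeats: list[RepeatAnnotation] = []
    elements: list[LtrElement] = []
    for r in db.features_of_type("dispersed_repeat"):
        category = _attr(r, "category") or "other"
        repeats.append(RepeatAnnotation(_iv(r, strand=False), category))

    for e in db.features_of_type("LTR_retrotransposon"):
        superfamily = _attr(e, "superfamily") or "Unknown"
        repeats.append(RepeatAnnotation(_iv(e, strand=False), "LTR", superfamily))
        ltrs = sorted(
            db.children(e, featuretype="long_terminal_repeat", order_by="start"),
            key=lambda f: (f.seqid, f.start),
        )
        if len(ltrs) != 2:
            continue
        if {l.seqid for l in ltrs} != {e.seqid}:
            raise GenomeError(
                f"element {e.id}: terminal repeats on a different contig than parent"
            )
        ltr5, ltr3 = (_iv(l, strand=False) for l in ltrs)
        internal = Interval(e.seqid, ltr5.end, ltr3.start)
        elements.append(LtrElement(e.id, ltr5, ltr3, internal, superfamily, complete=True))

    return genes, repeats, elements


def write_gff3(
    path: str | Path,
    genome: GenomeSet,
    genes: Iterable[GeneModel] = (),
    repeats: Iterable[RepeatAnnotation] = (),
    elements: Iterable[LtrElement] = (),
    source: str = "ltrscape",
) -> None:
    """Emit GFF3 (1-based inclusive) with deterministic ordering."""
    element_spans = {e.span for e in elements}
    lines: list[tuple[str, int, int, str]] = []  # (contig, start, rank, text)

    def add(contig, start0, end0, ftype, strand, attrs, rank=0):
        lines.append(
            (
                contig,
                start0,
                rank,
                f"{contig}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}",
            )
        )

    for g in genes:
        sp = g.span
        add(sp.contig, sp.start, sp.end, "gene", g.strand,
            f"ID={g.gene_id}" + (f";family={g.family}" if g.family else ""))
        for i, ex in enumerate(g.exons, 1):
            add(ex.contig, ex.start, ex.end, "CDS", g.strand,
                f"ID={g.gene_id}.cds{i};Parent={g.gene_id}", rank=1)
    for r in repeats:
        if r.category == "LTR" and r.interval in element_spans:
            continue  # written with its element below
        iv = r.interval
        if r.category == "LTR":
            attrs = f"superfamily={r.superfamily or 'Unknown'}"
            add(iv.contig, iv.start, iv.end, "LTR_retrotransposon", ".", attrs)
        else:
            add(iv.contig, iv.start, iv.end, "dispersed_repeat", ".",
                f"category={r.category}")
    for e in elements:
        sp = e.span
        add(sp.contig, sp.start, sp.end, "LTR_retrotransposon", ".",
            f"ID={e.element_id};superfamily={e.superfamily}")
        for tag, iv in (("ltr5", e.ltr5), ("ltr3", e.ltr3)):
            add(iv.contig, iv.start, iv.end, "long_terminal_repeat", ".",
                f"ID={e.element_id}.{tag};Parent={e.element_id}", rank=1)

    order = {name: i for i, name in enumerate(genome.contigs)}
    lines.sort(key=lambda t: (order.get(t[0], len(order)), t[1], t[2], t[3]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for *_k, text in lines:
            fh.write(text + "\n")
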