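"""Positional classification of CpG islands relative to gene models.

A CpG island (CGI) is assigned one of four positional categories by where
it falls relative to annotated transcripts:

* ``five_prime``  — overlaps the region from 3 kb upstream of a gene's
  first exon through the first exon (transcription orientation);
* ``three_prime`` — overlaps the region from the final exon through 3 kb
  downstream;
* ``intragenic``  — overlaps the region between the first and the final
  intron of a gene;
* ``intergenic``  — overlaps none of the above.

When a CGI overlaps windows of several kinds the categories are applied
in strict priority order 5' > 3' > intragenic > intergenic.  A CGI is
*coding* when at least one transcript whose window triggered its assigned
category is protein-coding; intergenic CGIs are always non-coding.

Coordinates are 0-based half-open throughout (UCSC table convention), and
"first exon" always means the first exon in transcription order, i.e. the
highest-coordinate exon for minus-strand transcripts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

UPSTREAM_DOWNSTREAM_BP = 3000

CATEGORY_PRIORITY = ("five_prime", "three_prime", "intragenic")


class ParseError(ValueError):
    """Raised for malformed gene-model or interval input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """One transcript: tx/cds bounds plus an ordered exon list.

    A transcript is non-coding exactly when ``cds_start == cds_end``
    (the convention of UCSC knownGene dumps).
    """

    name: str
    interval: GenomicInterval
    cds_start: int
    cds_end: int
    exons: tuple[GenomicInterval, ...]
    symbol: str = ""

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.name}: at least one exon required")
        prev_end = None
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.name}: exon outside tx bounds")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.name}: exons unsorted or overlapping")
            prev_end = ex.end

    @property
    def coding(self) -> bool:
        return self.cds_start != self.cds_end

    @property
    def first_exon(self) -> GenomicInterval:
        """First exon in transcription order (rightmost on minus strand)."""
        return self.exons[-1] if self.interval.strand == "-" else self.exons[0]

    @property
    def final_exon(self) -> GenomicInterval:
        return self.exons[0] if self.interval.strand == "-" else self.exons[-1]


@dataclass
class CGIClassification:
    """Positional category plus coding status for one CGI."""

    category: str
    coding: bool
    associated_genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parsing

_KNOWNGENE_COLUMNS = (
    "name",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "exonCount",
    "exonStarts",
    "exonEnds",
)


def _parse_comma_list(text: str, row_label: str) -> list[int]:
    try:
        return [int(x) for x in text.strip().rstrip(",").split(",") if x != ""]
    except ValueError as exc:
        raise ParseError(f"row {row_label}: malformed exon list {text!r}") from exc


def load_gene_models(source: str | IO[str]) -> list[GeneModel]:
    """Read transcripts from a knownGene-style TSV.

    Accepts either a headered file (columns named as in the UCSC schema)
    or a raw headerless UCSC dump in the standard column order.  Exon
    start/end lists are comma-separated with an optional trailing comma.
    """
    close = False
    if isinstance(source, str):
        source = open(source)
        close = True
    try:
        reader = csv.reader(source, delimiter="\t")
        rows = [r for r in reader if r and not r[0].startswith("#")]
    finally:
        if close:
            source.close()
    if not rows:
        return []
    if "txStart" in rows[0]:
        header = rows[0]
        rows = rows[1:]
    else:
        header = list(_KNOWNGENE_COLUMNS[: len(rows[0])])
    idx = {c: i for i, c in enumerate(header)}
    missing = [c for c in _KNOWNGENE_COLUMNS if c not in idx and c != "exonCount"]
    if missing:
        raise ParseError(f"missing gene-model columns: {missing}")

    genes: list[GeneModel] = []
    for r in rows:
        name = r[idx["name"]]
        starts = _parse_comma_list(r[idx["exonStarts"]], name)
        ends = _parse_comma_list(r[idx["exonEnds"]], name)
        if len(starts) != len(ends) or not starts:
            raise ParseError(
                f"row {name}: exonStarts/exonEnds length mismatch "
                f"({len(starts)} vs {len(ends)})"
            )
        chrom = r[idx["chrom"]]
        strand = r[idx["strand"]]
        exons = tuple(
            GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends)
        )
        genes.append(
            GeneModel(
                name=name,
                interval=GenomicInterval(
                    chrom, int(r[idx["txStart"]]), int(r[idx["txEnd"]]), strand
                ),
                cds_start=int(r[idx["cdsStart"]]),
                cds_end=int(r[idx["cdsEnd"]]),
                exons=exons,
                symbol=r[idx["symbol"]] if "symbol" in idx else "",
            )
        )
    return genes


def load_cgi_bed(source: str | IO[str]) -> list[tuple[str, GenomicInterval]]:
    """Read CGI intervals from BED3+ (optional 4th column id).

    Returns ``(cgi_id, interval)`` pairs; ids default to
    ``chrom:start-end`` when the name column is absent.
    """
    close = False
    if isinstance(source, str):
        source = open(source)
        close = True
    out = []
    try:
        for line in source:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            cgi_id = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            out.append((cgi_id, GenomicInterval(chrom, start, end)))
    finally:
        if close:
            source.close()
    return out


# ---------------------------------------------------------------------------
# windows

def five_prime_window(
    gene: GeneModel, chrom_length: int | None = None
) -> GenomicInterval:
    """Region from 3 kb upstream of the first exon through the first exon."""
    fe = gene.first_exon
    if gene.interval.strand == "+":
        start, end = fe.start - UPSTREAM_DOWNSTREAM_BP, fe.end
    else:
        start, end = fe.start, fe.end + UPSTREAM_DOWNSTREAM_BP
    return _clamp(gene.interval.chrom, start, end, chrom_length)


def three_prime_window(
    gene: GeneModel, chrom_length: int | None = None
) -> GenomicInterval:
    """Region from the final exon through 3 kb downstream of transcription."""
    fe = gene.final_exon
    if gene.interval.strand == "+":
        start, end = fe.start, fe.end + UPSTREAM_DOWNSTREAM_BP
    else:
        start, end = fe.start - UPSTREAM_DOWNSTREAM_BP, fe.end
    return _clamp(gene.interval.chrom, start, end, chrom_length)


def intragenic_window(gene: GeneModel) -> GenomicInterval | None:
    """Span from the end of the first exon to the start of the final exon.

    In genomic coordinates this is the same on either strand: the region
    between the outermost exons.  ``None`` for single-exon genes (no
    introns) or abutting outermost exons.
    """
    lo = gene.exons[0].end
    hi = gene.exons[-1].start
    if len(gene.exons) < 2 or hi <= lo:
        return None
    return GenomicInterval(gene.interval.chrom, lo, hi)


def _clamp(
    chrom: str, start: int, end: int, chrom_length: int | None
) -> GenomicInterval:
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(chrom, start, end)


# ---------------------------------------------------------------------------
# classification

def classify_cgi(
    cgi: GenomicInterval,
    genes: Sequence[GeneModel],
    chrom_lengths: dict[str, int] | None = None,
) -> CGIClassification:
    """Classify one CGI against a list of gene models.

    Categories are tested in priority order; within the winning category
    the CGI is coding iff ANY transcript whose window it overlaps is
    protein-coding, and all such transcripts are reported as associated.
    """
    chrom_len = chrom_lengths.get(cgi.chrom) if chrom_lengths else None
    window_fns = {
        "five_prime": lambda g: five_prime_window(g, chrom_len),
        "three_prime": lambda g: three_prime_window(g, chrom_len),
        "intragenic": intragenic_window,
    }
    for category in CATEGORY_PRIORITY:
        hits = []
        for g in genes:
            if g.interval.chrom != cgi.chrom:
                continue
            win = window_fns[category](g)
            if win is not None and cgi.overlaps(win):
                hits.append(g)
        if hits:
            return CGIClassification(
                category=category,
                coding=any(g.coding for g in hits),
                associated_genes=[g.name for g in hits],
            )
    return CGIClassification(category="intergenic", coding=False)


def classify_all(
    cgis: Iterable[tuple[str, GenomicInterval]],
    genes: Sequence[GeneModel],
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Classify many CGIs, using an interval tree to prefilter candidates.

    Returns a DataFrame with columns cgi_id, chrom, start, end, category,
    coding, associated_genes (comma-joined transcript ids).
    """
    # index genes by the widest window they can project (tx span +/- 3 kb)
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo = max(0, g.interval.start - UPSTREAM_DOWNSTREAM_BP)
        hi = g.interval.end + UPSTREAM_DOWNSTREAM_BP
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(lo, hi, g)

    records = []
    for cgi_id, cgi in cgis:
        tree = trees.get(cgi.chrom)
        candidates = [iv.data for iv in tree.overlap(cgi.start, cgi.end)] if tree else []
        cls = classify_cgi(cgi, candidates, chrom_lengths)
        records.append(
            {
                "cgi_id": cgi_id,
                "chrom": cgi.chrom,
                "start": cgi.start,
                "end": cgi.end,
                "category": cls.category,
                "coding": "coding" if cls.coding else "noncoding",
                "associated_genes": ",".join(sorted(cls.associated_genes)),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "cgi_id", "chrom", "start", "end", "category", "coding",
            "associated_genes",
        ],
    )
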