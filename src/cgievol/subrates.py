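"""Context-dependent substitution rates for CGIs from human/chimp/ancestor alignments.

Six per-CGI rates are estimated from a three-way alignment of human,
chimpanzee and their inferred common ancestor:

i)   CpG -> TpG/CpA             (deamination of methylcytosine)
ii)  TpG/CpA -> CpG             (CpG fixation)
iii) CpG -> GpG/ApG/CpC/CpT     (CpG loss through non-deamination paths)
iv)  GpG/ApG/CpC/CpT -> CpG     (CpG gain from non-TpG/CpA states)
v)   A/T -> G/C, non-CpG        (GC-gain; candidate biased-gene-conversion signal)
vi)  G/C -> A/T, ancestral non-CpG context (GC-loss)

Each rate is (number of derived target states summed over the human and
chimp lineages) / (2 x number of ancestral source states), so a rate is
per lineage and lies in [0, 1]; it is undefined (NaN) when the CGI has
no ancestral source state.  Dinucleotide rates i)-iv) count an ancestral
dinucleotide as two consecutive alignment columns with a non-gap,
non-N ancestor base in each; a lineage contributes at most one event
per ancestral dinucleotide and only when it has unambiguous bases in
both columns.  Single-base rates v)/vi) evaluate the CpG-context
condition on the derived sequence for v) and on the ancestral sequence
for vi); alignment-edge neighbours are treated as non-CpG context.

Rates are computed on the forward strand only: the TpG/CpA target pair
already folds in deamination on the complementary strand.

A CGI whose human bases are covered by the alignment over less than 50%
of its length is excluded from rate estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import IO, Iterable

import numpy as np
import pandas as pd
from Bio import AlignIO

from .regions import GenomicInterval

log = logging.getLogger(__name__)

MIN_COVERAGE = 0.5

RATE_NAMES = (
    "cpg_to_tpg_cpa",
    "tpg_cpa_to_cpg",
    "cpg_to_other",
    "other_to_cpg",
    "at_to_gc",
    "gc_to_at",
)

# base encoding used throughout: A C G T N gap
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
A, C, G, T, N, GAP = 0, 1, 2, 3, 4, 5

_LUT = np.full(256, N, dtype=np.uint8)
for _b, _v in _CODE.items():
    _LUT[ord(_b)] = _v
    _LUT[ord(_b.lower())] = _v
_LUT[ord(".")] = GAP


def encode(seq: str) -> np.ndarray:
    """Encode a gapped sequence as a uint8 array (unknown letters -> N)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class AlignmentBlock:
    """One gapped block of the human/chimp/ancestor alignment."""

    human: np.ndarray
    chimp: np.ndarray
    ancestor: np.ndarray
    chrom: str
    start: int  # human forward-strand start of the block

    def __post_init__(self) -> None:
        if not (len(self.human) == len(self.chimp) == len(self.ancestor)):
            raise ValueError("alignment rows differ in length")

    @cached_property
    def human_positions(self) -> np.ndarray:
        """Human genomic coordinate of each column.

        Gap columns take the coordinate of the next human base, so the
        array is non-decreasing and membership tests against half-open
        intervals remain well defined for gapped columns.
        """
        nongap = self.human != GAP
        return self.start + np.cumsum(nongap) - nongap.astype(np.int64)

    @property
    def human_span(self) -> tuple[int, int]:
        return self.start, self.start + int((self.human != GAP).sum())


@dataclass
class TripleAlignment:
    """All blocks of a three-way alignment, grouped by human chromosome."""

    blocks: list[AlignmentBlock] = field(default_factory=list)
    n_rejected: int = 0

    def blocks_for(self, chrom: str) -> list[AlignmentBlock]:
        return [b for b in self.blocks if b.chrom == chrom]


@dataclass
class SubstitutionCounts:
    """Ancestral opportunity and derived event counts for the six rates."""

    anc_cpg: int = 0
    ev_cpg_to_tpg_cpa: int = 0
    ev_cpg_to_other: int = 0
    anc_tpg_cpa: int = 0
    ev_tpg_cpa_to_cpg: int = 0
    anc_other: int = 0
    ev_other_to_cpg: int = 0
    anc_at: int = 0
    ev_at_to_gc: int = 0
    anc_gc_noncpg: int = 0
    ev_gc_to_at: int = 0

    PAIRS = (
        ("cpg_to_tpg_cpa", "ev_cpg_to_tpg_cpa", "anc_cpg"),
        ("tpg_cpa_to_cpg", "ev_tpg_cpa_to_cpg", "anc_tpg_cpa"),
        ("cpg_to_other", "ev_cpg_to_other", "anc_cpg"),
        ("other_to_cpg", "ev_other_to_cpg", "anc_other"),
        ("at_to_gc", "ev_at_to_gc", "anc_at"),
        ("gc_to_at", "ev_gc_to_at", "anc_gc_noncpg"),
    )

    def __iadd__(self, other: "SubstitutionCounts") -> "SubstitutionCounts":
        for f in self.__dataclass_fields__:
            setattr(self, f, getattr(self, f) + getattr(other, f))
        return self

    def validate(self) -> None:
        for rate, ev, anc in self.PAIRS:
            if getattr(self, ev) > 2 * getattr(self, anc):
                raise AssertionError(
                    f"{rate}: events {getattr(self, ev)} exceed "
                    f"2 x opportunities {getattr(self, anc)}"
                )


@dataclass
class SubstitutionRates:
    """The six per-CGI rates plus the alignment coverage fraction."""

    cpg_to_tpg_cpa: float
    tpg_cpa_to_cpg: float
    cpg_to_other: float
    other_to_cpg: float
    at_to_gc: float
    gc_to_at: float
    coverage_fraction: float


# ---------------------------------------------------------------------------
# MAF parsing

def read_triple_alignment(
    source: str | IO[str],
    human: str = "human",
    chimp: str = "chimp",
    ancestor: str = "ancestor",
) -> TripleAlignment:
    """Read a three-species MAF into a TripleAlignment.

    Species are matched against the text before the first '.' of each
    s-line source name.  Blocks missing any of the three species, with a
    duplicated species, or with a non-forward human row are skipped and
    counted in ``n_rejected``.
    """
    close = False
    if isinstance(source, str):
        source = open(source)
        close = True
    aln = TripleAlignment()
    try:
        for msa in AlignIO.parse(source, "maf"):
            rows: dict[str, object] = {}
            dup = False
            for rec in msa:
                species = rec.id.split(".", 1)[0]
                if species in rows:
                    dup = True
                rows[species] = rec
            if dup or not all(k in rows for k in (human, chimp, ancestor)):
                aln.n_rejected += 1
                log.warning("skipping block lacking the three expected species")
                continue
            h = rows[human]
            if h.annotations.get("strand", 1) != 1:
                aln.n_rejected += 1
                log.warning("skipping block with non-forward human row")
                continue
            chrom = h.id.split(".", 1)[1] if "." in h.id else h.id
            aln.blocks.append(
                AlignmentBlock(
                    human=encode(str(h.seq)),
                    chimp=encode(str(rows[chimp].seq)),
                    ancestor=encode(str(rows[ancestor].seq)),
                    chrom=chrom,
                    start=int(h.annotations["start"]),
                )
            )
    finally:
        if close:
            source.close()
    return aln


# ---------------------------------------------------------------------------
# coverage and counting

def cgi_coverage(cgi: GenomicInterval, aln: TripleAlignment) -> float:
    """Fraction of CGI bases present as non-gap human bases in any block."""
    covered = np.zeros(len(cgi), dtype=bool)
    for block in aln.blocks_for(cgi.chrom):
        pos = block.human_positions
        j0, j1 = np.searchsorted(pos, [cgi.start, cgi.end], side="left")
        if j0 >= j1:
            continue
        sel = pos[j0:j1][block.human[j0:j1] != GAP]
        covered[sel - cgi.start] = True
    return float(covered.mean())


_DINUC_SOURCES = {
    # source class -> set of (first, second) ancestor codes
    "cpg": {(C, G)},
    "tpg_cpa": {(T, G), (C, A)},
    "other": {(G, G), (A, G), (C, C), (C, T)},
}
_TARGETS = {
    "cpg": {"ev_cpg_to_tpg_cpa": {(T, G), (C, A)},
            "ev_cpg_to_other": {(G, G), (A, G), (C, C), (C, T)}},
    "tpg_cpa": {"ev_tpg_cpa_to_cpg": {(C, G)}},
    "other": {"ev_other_to_cpg": {(C, G)}},
}


def _pair_mask(first: np.ndarray, second: np.ndarray, pairs) -> np.ndarray:
    m = np.zeros(len(first), dtype=bool)
    for a, b in pairs:
        m |= (first == a) & (second == b)
    return m


def count_events(cgi: GenomicInterval, aln: TripleAlignment) -> SubstitutionCounts:
    """Tally ancestral opportunities and derived events within one CGI.

    A dinucleotide belongs to the CGI when its first base's human
    coordinate lies in [start, end); single-base classes use the column's
    own human coordinate.  Columns with N in the relevant species are
    skipped for both numerator and denominator.
    """
    total = SubstitutionCounts()
    for block in aln.blocks_for(cgi.chrom):
        total += _count_block(cgi, block)
    total.validate()
    return total


def _count_block(cgi: GenomicInterval, block: AlignmentBlock) -> SubstitutionCounts:
    counts = SubstitutionCounts()
    pos = block.human_positions
    j0, j1 = np.searchsorted(pos, [cgi.start, cgi.end], side="left")
    if j0 >= j1:
        return counts
    # slice with one column of context each side; a pad column only marks
    # a true block edge, where neighbours are unknown (treated as N)
    lo, hi = max(0, j0 - 1), min(len(pos), j1 + 1)
    anc = block.ancestor[lo:hi]
    hum = block.human[lo:hi]
    chp = block.chimp[lo:hi]
    in_cgi = np.zeros(hi - lo, dtype=bool)
    in_cgi[j0 - lo:j1 - lo] = True

    # --- dinucleotide classes on consecutive columns -----------------------
    a1, a2 = anc[:-1], anc[1:]
    di_in = in_cgi[:-1]
    anc_ok = (a1 < N) & (a2 < N)  # non-gap, non-N ancestor in both columns
    lineage_pairs = [(hum[:-1], hum[1:]), (chp[:-1], chp[1:])]
    for src, anc_field in (("cpg", "anc_cpg"), ("tpg_cpa", "anc_tpg_cpa"),
                           ("other", "anc_other")):
        src_mask = _pair_mask(a1, a2, _DINUC_SOURCES[src]) & anc_ok & di_in
        setattr(counts, anc_field, int(src_mask.sum()))
        for ev_field, targets in _TARGETS[src].items():
            ev = 0
            for l1, l2 in lineage_pairs:
                valid = (l1 < N) & (l2 < N)
                ev += int((_pair_mask(l1, l2, targets) & src_mask & valid).sum())
            setattr(counts, ev_field, ev)

    # --- single-base classes ----------------------------------------------
    # neighbour columns, with edges padded as N (treated as non-CpG context)
    def shifted(x: np.ndarray):
        prev = np.concatenate(([N], x[:-1]))
        nxt = np.concatenate((x[1:], [N]))
        return prev, nxt

    anc_prev, anc_next = shifted(anc)

    # v) ancestral A/T -> derived G/C not forming a CpG in the derived seq
    at_mask = ((anc == A) | (anc == T)) & in_cgi
    counts.anc_at = int(at_mask.sum())
    ev = 0
    for lin in (hum, chp):
        lin_prev, lin_next = shifted(lin)
        forms_cpg = ((lin == C) & (lin_next == G)) | ((lin == G) & (lin_prev == C))
        ev += int((at_mask & ((lin == G) | (lin == C)) & ~forms_cpg).sum())
    counts.ev_at_to_gc = ev

    # vi) ancestral G/C in ancestral non-CpG context -> derived A/T
    anc_in_cpg = ((anc == C) & (anc_next == G)) | ((anc == G) & (anc_prev == C))
    gc_mask = ((anc == C) | (anc == G)) & ~anc_in_cpg & in_cgi
    counts.anc_gc_noncpg = int(gc_mask.sum())
    ev = 0
    for lin in (hum, chp):
        ev += int((gc_mask & ((lin == A) | (lin == T))).sum())
    counts.ev_gc_to_at = ev
    return counts


def rates_from_counts(
    counts: SubstitutionCounts, coverage: float = 1.0
) -> SubstitutionRates:
    """events / (2 x opportunities) for each class; NaN when no opportunity."""
    vals = {}
    for rate, ev, anc in SubstitutionCounts.PAIRS:
        opp = getattr(counts, anc)
        vals[rate] = getattr(counts, ev) / (2.0 * opp) if opp > 0 else float("nan")
    return SubstitutionRates(coverage_fraction=coverage, **vals)


def cgi_rate_table(
    cgis: Iterable[tuple[str, GenomicInterval]],
    aln: TripleAlignment,
    min_coverage: float = MIN_COVERAGE,
) -> pd.DataFrame:
    """Coverage, counts and rates for every CGI.

    CGIs covered on less than ``min_coverage`` of their length (strictly
    below; exactly 50% is retained) get NaN rates but keep their coverage
    so the exclusion is auditable.
    """
    records = []
    for cgi_id, cgi in cgis:
        cov = cgi_coverage(cgi, aln)
        rec = {"cgi_id": cgi_id, "coverage": cov,
               "passed_coverage": cov >= min_coverage}
        if cov >= min_coverage:
            counts = count_events(cgi, aln)
            rates = rates_from_counts(counts, cov)
            for f in counts.__dataclass_fields__:
                rec[f] = getattr(counts, f)
            for r in RATE_NAMES:
                rec[r] = getattr(rates, r)
        else:
            for f in SubstitutionCounts().__dataclass_fields__:
                rec[f] = 0
            for r in RATE_NAMES:
                rec[r] = float("nan")
        records.append(rec)
    return pd.DataFrame.from_records(records)
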