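"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emits every format the analysis consumes — CGI BED, a
knownGene-style transcript table, per-site bisulfite call counts, and a
three-row (human/chimp/ancestor) MAF — together with a ground-truth
record, so each stage can be tested by parameter recovery without any
external download.

What it emulates
----------------
* An ancestral chromosome built from slots, one per planted CGI.  Slots
  carrying a gene place the CGI so that it falls in exactly one
  positional class (5', 3', intragenic) of that gene; intergenic slots
  carry no gene.  Island sequence is CpG-enriched relative to the
  background.
* Two lineages (human, chimp) diverged independently from the ancestor
  under context-dependent substitution probabilities: per ancestral CpG
  a conversion to TpG/CpA or to GpG/ApG/CpC/CpT; per ancestral TpG/CpA
  or GpG/ApG/CpC/CpT a conversion to CpG; per ancestral A/T a change to
  G/C; per ancestral non-CpG-context G/C a change to A/T.  At most one
  event is applied per ancestral dinucleotide per lineage and an applied
  dinucleotide event blocks single-base events at its two positions, so
  the simulated truth matches a single-substitution counting model.
* Bisulfite call counts: per CpG cytosine per strand, coverage is
  Poisson with a configurable mean and methylated calls are binomial at
  the CGI's true methylation level.
* Methylation group structure: each CGI belongs to a group (HM / LM by
  default) that fixes both its true methylation level per sample and
  its branch substitution probabilities.

Truth counts are recorded by re-scanning the emitted ancestor/derived
sequences with the same single-substitution classification the rate
estimator uses, so estimator output can be compared to truth exactly.
Default simulations are gapless; lineage deletions can be switched on
as a stressor for the gap-handling rules (truth counts are then not
recorded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import GenomicInterval
from .subrates import (
    A, C, G, T, N, GAP,
    AlignmentBlock,
    SubstitutionCounts,
    TripleAlignment,
)

_BASES = "ACGTN-"


def decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


@dataclass(frozen=True)
class GroupParams:
    """Per-branch substitution probabilities for one methylation group."""

    cpg_to_tpg: float = 0.005
    tpg_to_cpg: float = 0.004
    cpg_to_other: float = 0.005
    other_to_cpg: float = 0.005
    at_to_gc: float = 0.008
    gc_to_at: float = 0.012

    def __post_init__(self) -> None:
        for f, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be a probability, got {v}")
        if self.cpg_to_tpg + self.cpg_to_other > 1.0:
            raise ValueError("CpG event probabilities exceed 1")


# study-like defaults: sperm-methylated islands deaminate at ~4% per branch
# and regain CpGs about twice as fast as hypomethylated islands; the four
# remaining substitution classes do not depend on methylation.
DEFAULT_GROUPS = {
    "HM": GroupParams(cpg_to_tpg=0.04, tpg_to_cpg=0.008),
    "LM": GroupParams(cpg_to_tpg=0.005, tpg_to_cpg=0.004),
}

DEFAULT_METHYLATION_TRUTH = {
    "H1": {"HM": 0.9, "LM": 0.05},
    "sperm": {"HM": 0.9, "LM": 0.05},
}

_CELLS = (
    ("five_prime", "coding"),
    ("five_prime", "noncoding"),
    ("three_prime", "coding"),
    ("three_prime", "noncoding"),
    ("intragenic", "coding"),
    ("intragenic", "noncoding"),
    ("intergenic", "noncoding"),
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort."""

    seed: int = 0
    n_chromosomes: int = 1
    n_cgis_per_cell: int = 3          # per (category x coding) cell, 7 cells
    cgi_length_range: tuple[int, int] = (600, 1200)
    island_cpg_density: float = 0.10  # CpG starts per base inside islands
    background_cpg_density: float = 0.01
    exon_length: int = 200
    intron_length: int = 1000
    n_exons: int = 3
    slot_length: int = 20000
    groups: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    group_fractions: dict[str, float] = field(
        default_factory=lambda: {"HM": 0.5, "LM": 0.5}
    )
    background_group: str = "LM"
    methylation_truth: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_METHYLATION_TRUTH.items()}
    )
    coverage_mean: float = 30.0
    indel_rate: float = 0.0
    species: tuple[str, str, str] = ("human", "chimp", "ancestor")

    def __post_init__(self) -> None:
        if not 0 < self.background_cpg_density < 1:
            raise ValueError("background_cpg_density must be in (0,1)")
        if not 0 < self.island_cpg_density < 1:
            raise ValueError("island_cpg_density must be in (0,1)")
        lo, hi = self.cgi_length_range
        if lo < 10 or hi < lo:
            raise ValueError("bad cgi_length_range")
        gene_span = self.n_exons * self.exon_length \
            + (self.n_exons - 1) * self.intron_length
        if 6000 + gene_span + 3000 + hi > self.slot_length:
            raise ValueError("slot_length too small for gene geometry + CGI")
        if abs(sum(self.group_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("group_fractions must sum to 1")
        unknown = set(self.group_fractions) - set(self.groups)
        if unknown:
            raise ValueError(f"group_fractions references unknown groups {unknown}")


@dataclass
class GenomeSim:
    """A simulated ancestral genome plus its planted annotation and truth."""

    config: SimConfig
    chromosomes: dict[str, np.ndarray]            # ancestor sequences
    cgis: list[tuple[str, GenomicInterval]]
    genes: pd.DataFrame                           # knownGene-style rows
    truth: pd.DataFrame                           # per-CGI planted truth


# ---------------------------------------------------------------------------
# sequence generation

def _cpg_sequence(length: int, cpg_density: float, rng: np.random.Generator,
                  gc_singles: float = 0.5) -> np.ndarray:
    """Sequence of given length with the target CpG-start density.

    Built from units: a CG dinucleotide with probability q = d/(1-d),
    else a single base; accidental CG joins between singles are broken,
    so the planted units are the only CpGs and the realised density is
    d in expectation.
    """
    q = cpg_density / (1.0 - cpg_density)
    n_units = length  # each unit adds >= 1 base, so this always suffices
    is_cg = rng.random(n_units) < q
    p_single = np.array([
        (1 - gc_singles) / 2, gc_singles / 2, gc_singles / 2, (1 - gc_singles) / 2,
    ])
    singles = rng.choice(4, size=n_units, p=p_single).astype(np.uint8)
    lens = np.where(is_cg, 2, 1)
    starts = np.concatenate(([0], np.cumsum(lens)[:-1]))
    out = np.empty(int(lens.sum()), dtype=np.uint8)
    out[starts[is_cg]] = C
    out[starts[is_cg] + 1] = G
    out[starts[~is_cg]] = singles[~is_cg]
    # break accidental CG joins (single C followed by single G)
    cg = np.flatnonzero((out[:-1] == C) & (out[1:] == G))
    accidental = np.setdiff1d(cg, starts[is_cg], assume_unique=False)
    out[accidental + 1] = np.where(rng.random(len(accidental)) < 0.5, A, T)
    return out[:length]


def simulate_genome(config: SimConfig,
                    rng: np.random.Generator | None = None) -> GenomeSim:
    """Plant CGIs of every positional class on slot-structured chromosomes."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cells = [cell for cell in _CELLS for _ in range(config.n_cgis_per_cell)]
    n_slots = len(cells)
    per_chrom = -(-n_slots // config.n_chromosomes)  # ceil
    group_names = sorted(config.group_fractions)
    group_p = np.array([config.group_fractions[g] for g in group_names])

    gene_offset = 6000
    exon_span = config.exon_length
    step = config.exon_length + config.intron_length
    gene_len = (config.n_exons - 1) * step + exon_span

    chroms: dict[str, np.ndarray] = {}
    cgis: list[tuple[str, GenomicInterval]] = []
    gene_rows = []
    truth_rows = []

    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        slots = cells[ci * per_chrom:(ci + 1) * per_chrom]
        L = max(1, len(slots)) * config.slot_length
        seq = _cpg_sequence(L, config.background_cpg_density, rng)
        for si, (category, coding) in enumerate(slots):
            o = si * config.slot_length
            idx = len(cgis)
            cgi_len = int(rng.integers(*config.cgi_length_range, endpoint=True))
            strand = "+" if (idx % 2 == 0) else "-"
            tx_start = o + gene_offset
            tx_end = tx_start + gene_len
            first_exon_end = tx_start + exon_span          # genomic leftmost exon
            final_exon_start = tx_end - exon_span
            # window geometry (mirrored on the minus strand)
            if category == "intergenic":
                cgi_start = o + gene_offset + 2000
            elif (category, strand) in (("five_prime", "+"), ("three_prime", "-")):
                cgi_start = first_exon_end - 400 - cgi_len  # in 3kb-upstream zone
            elif (category, strand) in (("three_prime", "+"), ("five_prime", "-")):
                cgi_start = tx_end + 100
            else:  # intragenic, either strand
                cgi_start = first_exon_end + 100
            cgi = GenomicInterval(chrom, cgi_start, cgi_start + cgi_len)
            cgi_id = f"CGI{idx:04d}"
            cgis.append((cgi_id, cgi))
            group = group_names[int(rng.choice(len(group_names), p=group_p))]
            truth_rows.append(
                {
                    "cgi_id": cgi_id, "chrom": chrom,
                    "start": cgi.start, "end": cgi.end,
                    "category": category, "coding": coding, "group": group,
                    **{f"level_{s}": config.methylation_truth[s][group]
                       for s in config.methylation_truth},
                }
            )
            seq[cgi.start:cgi.end] = _cpg_sequence(
                cgi_len, config.island_cpg_density, rng, gc_singles=0.65
            )
            if category != "intergenic":
                exon_starts = [tx_start + k * step for k in range(config.n_exons)]
                exon_ends = [s + exon_span for s in exon_starts]
                is_coding = coding == "coding"
                gene_rows.append(
                    {
                        "name": f"tx_{cgi_id}",
                        "chrom": chrom,
                        "strand": strand,
                        "txStart": tx_start,
                        "txEnd": tx_end,
                        "cdsStart": tx_start + 10 if is_coding else tx_start,
                        "cdsEnd": tx_end - 10 if is_coding else tx_start,
                        "exonCount": config.n_exons,
                        "exonStarts": ",".join(map(str, exon_starts)) + ",",
                        "exonEnds": ",".join(map(str, exon_ends)) + ",",
                    }
                )
        chroms[chrom] = seq

    genes = pd.DataFrame(
        gene_rows,
        columns=["name", "chrom", "strand", "txStart", "txEnd", "cdsStart",
                 "cdsEnd", "exonCount", "exonStarts", "exonEnds"],
    )
    truth = pd.DataFrame(truth_rows)
    return GenomeSim(config, chroms, cgis, genes, truth)


# ---------------------------------------------------------------------------
# lineage evolution

_CPG_TARGETS_DEAM = [(T, G), (C, A)]
_CPG_TARGETS_OTHER = [(G, G), (A, G), (C, C), (C, T)]
_DINUC_SOURCE_PATTERNS = {
    "tpg_cpa": [(T, G), (C, A)],
    "other": [(G, G), (A, G), (C, C), (C, T)],
}


def _dinuc_candidates(anc: np.ndarray, group_ix: np.ndarray,
                      prob_rows: dict[str, np.ndarray],
                      rng: np.random.Generator) -> list[tuple[int, int, int]]:
    """Draw dinucleotide substitution events; returns (pos, new1, new2)."""
    a1, a2 = anc[:-1], anc[1:]
    events: list[tuple[int, int, int]] = []

    # CpG sources: two competing event families
    m = (a1 == C) & (a2 == G)
    pos = np.flatnonzero(m)
    if len(pos):
        u = rng.random(len(pos))
        p_deam = prob_rows["cpg_to_tpg"][group_ix[pos]]
        p_oth = prob_rows["cpg_to_other"][group_ix[pos]]
        deam = u < p_deam
        other = (~deam) & (u < p_deam + p_oth)
        for p in pos[deam]:
            events.append((int(p), *_CPG_TARGETS_DEAM[int(rng.integers(2))]))
        for p in pos[other]:
            events.append((int(p), *_CPG_TARGETS_OTHER[int(rng.integers(4))]))

    for src, prob_key in (("tpg_cpa", "tpg_to_cpg"), ("other", "other_to_cpg")):
        m = np.zeros(len(a1), dtype=bool)
        for x, y in _DINUC_SOURCE_PATTERNS[src]:
            m |= (a1 == x) & (a2 == y)
        pos = np.flatnonzero(m)
        if len(pos):
            hit = rng.random(len(pos)) < prob_rows[prob_key][group_ix[pos]]
            events.extend((int(p), C, G) for p in pos[hit])
    return events


def _evolve_one(anc: np.ndarray, group_ix: np.ndarray,
                prob_rows: dict[str, np.ndarray],
                rng: np.random.Generator) -> np.ndarray:
    """One lineage: dinucleotide events (leftmost-first on overlap), then
    single-base events at unconsumed positions."""
    derived = anc.copy()
    consumed = np.zeros(len(anc), dtype=bool)
    events = sorted(_dinuc_candidates(anc, group_ix, prob_rows, rng))
    last = -2
    for p, b1, b2 in events:
        if p <= last + 1:
            continue  # overlaps an already-applied dinucleotide event
        derived[p], derived[p + 1] = b1, b2
        consumed[p] = consumed[p + 1] = True
        last = p

    anc_prev = np.concatenate(([N], anc[:-1]))
    anc_next = np.concatenate((anc[1:], [N]))
    in_anc_cpg = ((anc == C) & (anc_next == G)) | ((anc == G) & (anc_prev == C))

    at = np.flatnonzero(((anc == A) | (anc == T)) & ~consumed)
    hit = at[rng.random(len(at)) < prob_rows["at_to_gc"][group_ix[at]]]
    derived[hit] = np.where(rng.random(len(hit)) < 0.5, G, C)

    gc = np.flatnonzero(((anc == C) | (anc == G)) & ~in_anc_cpg & ~consumed)
    hit = gc[rng.random(len(gc)) < prob_rows["gc_to_at"][group_ix[gc]]]
    derived[hit] = np.where(rng.random(len(hit)) < 0.5, A, T)
    return derived


@dataclass
class EvolvedPair:
    """Human and chimp sequences derived from the simulated ancestor."""

    human: dict[str, np.ndarray]
    chimp: dict[str, np.ndarray]
    alignment: TripleAlignment
    truth_counts: pd.DataFrame | None   # None when indels were simulated


def evolve_pair(genome: GenomeSim,
                rng: np.random.Generator | None = None) -> EvolvedPair:
    """Derive human and chimp from the ancestor under group-specific
    substitution probabilities; record exact per-CGI truth counts."""
    config = genome.config
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    group_names = sorted(config.groups)
    name_to_ix = {g: i for i, g in enumerate(group_names)}
    prob_rows = {
        f: np.array([getattr(config.groups[g], f) for g in group_names])
        for f in GroupParams.__dataclass_fields__
    }
    cgi_group = dict(zip(genome.truth["cgi_id"], genome.truth["group"]))

    human: dict[str, np.ndarray] = {}
    chimp: dict[str, np.ndarray] = {}
    blocks = []
    truth_rows = []
    for chrom, anc in genome.chromosomes.items():
        group_ix = np.full(len(anc), name_to_ix[config.background_group],
                           dtype=np.int64)
        for cgi_id, cgi in genome.cgis:
            if cgi.chrom == chrom:
                group_ix[cgi.start:cgi.end] = name_to_ix[cgi_group[cgi_id]]
        h = _evolve_one(anc, group_ix, prob_rows, rng)
        c = _evolve_one(anc, group_ix, prob_rows, rng)
        if config.indel_rate > 0:
            h_row, c_row = (_apply_deletions(x, config.indel_rate, rng)
                            for x in (h, c))
        else:
            h_row, c_row = h, c
        human[chrom], chimp[chrom] = h_row, c_row
        blocks.append(AlignmentBlock(
            human=h_row, chimp=c_row, ancestor=anc, chrom=chrom, start=0,
        ))
        if config.indel_rate == 0:
            for cgi_id, cgi in genome.cgis:
                if cgi.chrom != chrom:
                    continue
                counts = recount_events(anc, h, c, cgi.start, cgi.end)
                truth_rows.append(
                    {"cgi_id": cgi_id,
                     **{f: getattr(counts, f)
                        for f in counts.__dataclass_fields__}}
                )
    truth_counts = pd.DataFrame(truth_rows) if config.indel_rate == 0 else None
    return EvolvedPair(human, chimp, TripleAlignment(blocks=blocks), truth_counts)


def _apply_deletions(seq: np.ndarray, rate: float,
                     rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    out[hit] = GAP
    return out


# ---------------------------------------------------------------------------
# truth bookkeeping (gapless recount; mirrors single-substitution counting)

def recount_events(anc: np.ndarray, human: np.ndarray, chimp: np.ndarray,
                   start: int, end: int) -> SubstitutionCounts:
    """Exact event/opportunity counts for [start, end) on gapless sequences.

    A dinucleotide belongs to the interval when its first base does; the
    CpG-context of single-base classes uses chromosome-wide neighbours
    (chromosome edges count as non-CpG context).
    """
    counts = SubstitutionCounts()
    Lc = len(anc)
    sl = slice(start, min(end, Lc))
    di_end = min(end, Lc - 1)          # last valid dinucleotide start + 1
    a1, a2 = anc[start:di_end], anc[start + 1:di_end + 1]
    pairs = [(human[start:di_end], human[start + 1:di_end + 1]),
             (chimp[start:di_end], chimp[start + 1:di_end + 1])]

    def dimask(x1, x2, patterns):
        m = np.zeros(len(x1), dtype=bool)
        for p, q in patterns:
            m |= (x1 == p) & (x2 == q)
        return m

    cpg = dimask(a1, a2, [(C, G)])
    tpgcpa = dimask(a1, a2, _DINUC_SOURCE_PATTERNS["tpg_cpa"])
    other = dimask(a1, a2, _DINUC_SOURCE_PATTERNS["other"])
    counts.anc_cpg = int(cpg.sum())
    counts.anc_tpg_cpa = int(tpgcpa.sum())
    counts.anc_other = int(other.sum())
    for l1, l2 in pairs:
        counts.ev_cpg_to_tpg_cpa += int(
            (cpg & dimask(l1, l2, _CPG_TARGETS_DEAM)).sum())
        counts.ev_cpg_to_other += int(
            (cpg & dimask(l1, l2, _CPG_TARGETS_OTHER)).sum())
        counts.ev_tpg_cpa_to_cpg += int(
            (tpgcpa & dimask(l1, l2, [(C, G)])).sum())
        counts.ev_other_to_cpg += int(
            (other & dimask(l1, l2, [(C, G)])).sum())

    stop = sl.stop

    def window_ctx(x: np.ndarray):
        """(window, prev-neighbour, next-neighbour), chromosome edges as N."""
        w = x[sl]
        prev = np.full(len(w), N, dtype=np.uint8)
        nxt = np.full(len(w), N, dtype=np.uint8)
        if start > 0:
            prev[:] = x[start - 1:stop - 1]
        else:
            prev[1:] = x[:stop - 1]
        if stop < Lc:
            nxt[:] = x[start + 1:stop + 1]
        else:
            nxt[:-1] = x[start + 1:stop]
        return w, prev, nxt

    aw, prev, nxt = window_ctx(anc)
    counts.anc_at = int(((aw == A) | (aw == T)).sum())
    anc_in_cpg = ((aw == C) & (nxt == G)) | ((aw == G) & (prev == C))
    gc_noncpg = ((aw == C) | (aw == G)) & ~anc_in_cpg
    counts.anc_gc_noncpg = int(gc_noncpg.sum())
    for lin in (human, chimp):
        lw, lprev, lnext = window_ctx(lin)
        forms_cpg = ((lw == C) & (lnext == G)) | ((lw == G) & (lprev == C))
        counts.ev_at_to_gc += int(
            (((aw == A) | (aw == T)) & ((lw == G) | (lw == C)) & ~forms_cpg).sum())
        counts.ev_gc_to_at += int((gc_noncpg & ((lw == A) | (lw == T))).sum())
    counts.validate()
    return counts


# ---------------------------------------------------------------------------
# methylome and stump-data simulation

def simulate_methylome(genome: GenomeSim, sample: str,
                       sequences: dict[str, np.ndarray] | None = None,
                       rng: np.random.Generator | None = None,
                       coverage_mean: float | None = None) -> pd.DataFrame:
    """Per-site bisulfite call counts for one sample.

    CpG cytosines are located on the given sequences (default: the
    ancestor, appropriate for gapless cohorts where human coordinates
    match); the plus-strand site is the C, the minus-strand site the
    paired G.  Coverage is Poisson, methylated calls binomial at the
    CGI's true level for ``sample``; zero-coverage sites are dropped.
    """
    config = genome.config
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    coverage_mean = config.coverage_mean if coverage_mean is None else coverage_mean
    if f"level_{sample}" not in genome.truth.columns:
        raise KeyError(f"no truth level for sample {sample!r}")
    levels = dict(zip(genome.truth["cgi_id"], genome.truth[f"level_{sample}"]))
    seqs = genome.chromosomes if sequences is None else sequences
    rows = []
    for cgi_id, cgi in genome.cgis:
        seq = seqs[cgi.chrom]
        level = levels[cgi_id]
        segment = seq[cgi.start:cgi.end + 1]
        cpg = np.flatnonzero((segment[:-1] == C) & (segment[1:] == G)) + cgi.start
        cpg = cpg[cpg < cgi.end]  # site attribution by the C position
        for offset, strand in ((0, "+"), (1, "-")):
            pos = cpg + offset
            cov = rng.poisson(coverage_mean, size=len(pos))
            meth = rng.binomial(cov, level)
            keep = cov > 0
            for p, cv, mt in zip(pos[keep], cov[keep], meth[keep]):
                rows.append((cgi.chrom, int(p), strand, int(mt), int(cv - mt)))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                     "meth_calls", "unmeth_calls"])
    return df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def simulate_stump_dataset(
    n_per_class: dict[str, int],
    class_rate_ranges: dict[str, tuple[float, float]],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Labelled per-CGI rates drawn from per-class uniform distributions.

    Returns the (cgi_id, rate, label) table plus a truth dict; when the
    class supports are disjoint the Bayes threshold (midpoint of the
    support gap) is recorded.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label in sorted(n_per_class):
        lo, hi = class_rate_ranges[label]
        for r in rng.uniform(lo, hi, size=n_per_class[label]):
            rows.append({"cgi_id": f"CGI{len(rows):04d}", "rate": float(r),
                         "label": label})
    truth: dict = {"ranges": {k: list(v) for k, v in class_rate_ranges.items()}}
    if len(class_rate_ranges) == 2:
        (l1, (a1, b1)), (l2, (a2, b2)) = sorted(
            class_rate_ranges.items(), key=lambda kv: kv[1][0])
        if b1 < a2:
            truth["bayes_threshold"] = 0.5 * (b1 + a2)
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# island-cohort shortcut for rate-recovery experiments

def simulate_island_cohort(
    n_per_group: int = 200,
    cgi_length: int = 800,
    island_cpg_density: float = 0.10,
    groups: dict[str, GroupParams] | None = None,
    spacer: int = 100,
    seed: int = 0,
) -> tuple[GenomeSim, EvolvedPair]:
    """A cohort of intergenic islands only — no genes, minimal background.

    Islands are laid head-to-tail with short background spacers on one
    chromosome, each assigned to a group in a deterministic interleaving.
    Suited to substitution-rate parameter-recovery experiments where the
    positional classification is irrelevant.
    """
    groups = dict(DEFAULT_GROUPS) if groups is None else groups
    group_names = sorted(groups)
    n_groups = len(group_names)
    rng = np.random.default_rng(seed)
    L = n_per_group * n_groups * (cgi_length + spacer) + spacer
    config = SimConfig(
        seed=seed, n_cgis_per_cell=0, slot_length=max(L, 20000),
        island_cpg_density=island_cpg_density, groups=groups,
        group_fractions={g: 1.0 / n_groups for g in group_names},
    )
    seq = _cpg_sequence(L, config.background_cpg_density, rng)
    cgis = []
    truth_rows = []
    pos = spacer
    for i in range(n_per_group * n_groups):
        group = group_names[i % n_groups]
        cgi = GenomicInterval("chr1", pos, pos + cgi_length)
        cgi_id = f"CGI{i:04d}"
        seq[cgi.start:cgi.end] = _cpg_sequence(
            cgi_length, island_cpg_density, rng, gc_singles=0.65)
        cgis.append((cgi_id, cgi))
        truth_rows.append(
            {"cgi_id": cgi_id, "chrom": "chr1", "start": cgi.start,
             "end": cgi.end, "category": "intergenic", "coding": "noncoding",
             "group": group,
             **{f"level_{s}": config.methylation_truth[s][group]
                for s in config.methylation_truth if group in
                config.methylation_truth[s]}}
        )
        pos += cgi_length + spacer
    genome = GenomeSim(config, {"chr1": seq}, cgis,
                       pd.DataFrame(columns=["name", "chrom", "strand",
                                             "txStart", "txEnd", "cdsStart",
                                             "cdsEnd", "exonCount",
                                             "exonStarts", "exonEnds"]),
                       pd.DataFrame(truth_rows))
    evolved = evolve_pair(genome, rng)
    return genome, evolved


# ---------------------------------------------------------------------------
# file emission

def write_bed(cgis: list[tuple[str, GenomicInterval]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cgi_id, cgi in cgis:
            fh.write(f"{cgi.chrom}\t{cgi.start}\t{cgi.end}\t{cgi_id}\n")


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def write_site_calls(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def write_maf(evolved: EvolvedPair, genome: GenomeSim, path: str | Path) -> None:
    """Emit the three-way alignment as MAF, one block per chromosome."""
    from Bio import AlignIO
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    hs, cs, anc_name = genome.config.species
    msas = []
    for block in evolved.alignment.blocks:
        src_size = len(genome.chromosomes[block.chrom])
        rows = []
        for name, codes in ((hs, block.human), (cs, block.chimp),
                            (anc_name, block.ancestor)):
            ungapped = int((codes != GAP).sum())
            rows.append(SeqRecord(
                Seq(decode(codes)), id=f"{name}.{block.chrom}",
                annotations={"start": block.start, "size": ungapped,
                             "strand": 1, "srcSize": src_size},
            ))
        msas.append(MultipleSeqAlignment(rows))
    with open(path, "w") as fh:
        AlignIO.write(msas, fh, "maf")


def write_truth(genome: GenomeSim, evolved: EvolvedPair | None,
                path: str | Path) -> None:
    payload = {"config": _config_dict(genome.config),
               "cgis": genome.truth.to_dict(orient="records")}
    if evolved is not None and evolved.truth_counts is not None:
        payload["counts"] = evolved.truth_counts.to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=float)
        fh.write("\n")


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["groups"] = {k: asdict(v) if isinstance(v, GroupParams) else v
                   for k, v in config.groups.items()}
    return d


def generate_all(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full generator and write every pipeline input to ``outdir``.

    Emits cgis.bed, genes.tsv, alignment.maf, one sites_<sample>.tsv per
    sample in the methylation truth, and truth.json.  Deterministic and
    byte-identical under a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    evolved = evolve_pair(genome)
    paths = {
        "cgis": outdir / "cgis.bed",
        "genes": outdir / "genes.tsv",
        "maf": outdir / "alignment.maf",
        "truth": outdir / "truth.json",
    }
    write_bed(genome.cgis, paths["cgis"])
    write_gene_table(genome.genes, paths["genes"])
    write_maf(evolved, genome, paths["maf"])
    for i, sample in enumerate(sorted(config.methylation_truth)):
        rng = np.random.default_rng(config.seed + 100 + i)
        sites = simulate_methylome(genome, sample, sequences=evolved.human,
                                   rng=rng)
        p = outdir / f"sites_{sample}.tsv"
        write_site_calls(sites, p)
        paths[f"sites_{sample}"] = p
    write_truth(genome, evolved, paths["truth"])
    return paths
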