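"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cgievol.regions import GenomicInterval
from cgievol.subrates import AlignmentBlock, TripleAlignment, encode

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_triple(anc: str, human: str, chimp: str, chrom: str = "chr1",
                start: int = 0) -> TripleAlignment:
    """One-block three-way alignment from gapped strings."""
    return TripleAlignment(blocks=[AlignmentBlock(
        human=encode(human), chimp=encode(chimp), ancestor=encode(anc),
        chrom=chrom, start=start,
    )])


DINUC_OTHER = ("GG", "AG", "CC", "CT")


def brute_force_counts(anc: str, human: str, chimp: str,
                       start: int, end: int) -> dict[str, int]:
    """Per-position enumeration of the six count classes on gapless rows.

    Written as explicit per-(position, lineage) loops, independent of the
    vectorised implementation it checks.
    """
    c: Counter = Counter()
    L = len(anc)
    for i in range(start, end):
        a = anc[i]
        if i + 1 < L:
            ad = anc[i:i + 2]
            if "N" not in ad and "-" not in ad:
                src = None
                if ad == "CG":
                    src = "cpg"
                elif ad in ("TG", "CA"):
                    src = "tpg_cpa"
                elif ad in DINUC_OTHER:
                    src = "other"
                if src == "cpg":
                    c["anc_cpg"] += 1
                elif src == "tpg_cpa":
                    c["anc_tpg_cpa"] += 1
                elif src == "other":
                    c["anc_other"] += 1
                if src is not None:
                    for lin in (human, chimp):
                        dd = lin[i:i + 2]
                        if "-" in dd or "N" in dd:
                            continue
                        if src == "cpg" and dd in ("TG", "CA"):
                            c["ev_cpg_to_tpg_cpa"] += 1
                        elif src == "cpg" and dd in DINUC_OTHER:
                            c["ev_cpg_to_other"] += 1
                        elif src in ("tpg_cpa", "other") and dd == "CG":
                            c["ev_tpg_cpa_to_cpg" if src == "tpg_cpa"
                              else "ev_other_to_cpg"] += 1
        if a in "AT":
            c["anc_at"] += 1
            for lin in (human, chimp):
                b = lin[i]
                if b in "GC":
                    prev = lin[i - 1] if i > 0 else "N"
                    nxt = lin[i + 1] if i + 1 < L else "N"
                    forms_cpg = (b == "C" and nxt == "G") or \
                                (b == "G" and prev == "C")
                    if not forms_cpg:
                        c["ev_at_to_gc"] += 1
        elif a in "CG":
            aprev = anc[i - 1] if i > 0 else "N"
            anext = anc[i + 1] if i + 1 < L else "N"
            in_cpg = (a == "C" and anext == "G") or (a == "G" and aprev == "C")
            if not in_cpg:
                c["anc_gc_noncpg"] += 1
                for lin in (human, chimp):
                    if lin[i] in "AT":
                        c["ev_gc_to_at"] += 1
    return dict(c)


def brute_force_category(cgi: GenomicInterval, genes) -> str:
    """Per-base window enumeration of the positional category.

    Builds explicit base sets for each window kind and intersects them
    with the CGI's base range, independent of the interval arithmetic in
    the implementation.
    """
    cgi_bases = set(range(cgi.start, cgi.end))
    five, three, intra = set(), set(), set()
    for g in genes:
        if g.interval.chrom != cgi.chrom:
            continue
        exon_spans = [(e.start, e.end) for e in g.exons]
        if g.interval.strand == "+":
            fe, le = exon_spans[0], exon_spans[-1]
            five |= set(range(max(0, fe[0] - 3000), fe[1]))
            three |= set(range(le[0], le[1] + 3000))
        else:
            fe, le = exon_spans[-1], exon_spans[0]
            five |= set(range(fe[0], fe[1] + 3000))
            three |= set(range(max(0, le[0] - 3000), le[1]))
        if len(exon_spans) > 1:
            intra |= set(range(exon_spans[0][1], exon_spans[-1][0]))
    if cgi_bases & five:
        return "five_prime"
    if cgi_bases & three:
        return "three_prime"
    if cgi_bases & intra:
        return "intragenic"
    return "intergenic"


@pytest.fixture(scope="session")
def small_genome():
    """A default-condition simulated genome shared across tests."""
    from cgievol.synthetic import SimConfig, simulate_genome

    return simulate_genome(SimConfig(seed=11, n_cgis_per_cell=2))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
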