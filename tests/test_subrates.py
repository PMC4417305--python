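"""MAF parsing, coverage, and the six substitution-rate counters."""

import io
import math

import numpy as np
import pytest

from cgievol.regions import GenomicInterval
from cgievol.subrates import (
    SubstitutionCounts,
    cgi_coverage,
    cgi_rate_table,
    count_events,
    rates_from_counts,
    read_triple_alignment,
)
from conftest import brute_force_counts, make_triple


def maf_block(rows, start=1000):
    """MAF text for one block; rows = [(species, seq), ...]."""
    lines = ["a score=0"]
    for name, seq in rows:
        size = len(seq.replace("-", ""))
        lines.append(f"s {name}.chr1 {start} {size} + 100000 {seq}")
    return "##maf version=1\n\n" + "\n".join(lines) + "\n\n"


class TestMafParsing:
    def test_three_row_block_anchored(self):
        text = maf_block([("human", "ACGTACGT"), ("chimp", "ACGTACGT"),
                          ("ancestor", "ACGTACGT")])
        aln = read_triple_alignment(io.StringIO(text))
        assert len(aln.blocks) == 1 and aln.n_rejected == 0
        assert aln.blocks[0].start == 1000
        assert aln.blocks[0].chrom == "chr1"

    def test_block_missing_ancestor_rejected(self):
        text = maf_block([("human", "ACGT"), ("chimp", "ACGT")])
        aln = read_triple_alignment(io.StringIO(text))
        assert len(aln.blocks) == 0 and aln.n_rejected == 1

    def test_empty_file(self):
        aln = read_triple_alignment(io.StringIO("##maf version=1\n"))
        assert aln.blocks == [] and aln.n_rejected == 0

    def test_configurable_species_labels(self):
        text = maf_block([("hg18", "ACGT"), ("panTro2", "ACGT"),
                          ("anc9", "ACGT")])
        aln = read_triple_alignment(io.StringIO(text), "hg18", "panTro2", "anc9")
        assert len(aln.blocks) == 1

    def test_lowercase_and_unknown_bases_normalised(self):
        text = maf_block([("human", "acgx"), ("chimp", "ACGT"),
                          ("ancestor", "ACGT")])
        block = read_triple_alignment(io.StringIO(text)).blocks[0]
        from cgievol.subrates import A, C, G, N
        assert list(block.human) == [A, C, G, N]


class TestCoverage:
    def test_partial_coverage_below_half(self):
        aln = make_triple("A" * 80, "A" * 80, "A" * 80, start=0)
        cgi = GenomicInterval("chr1", 0, 200)
        assert cgi_coverage(cgi, aln) == pytest.approx(0.4)

    def test_full_coverage(self):
        aln = make_triple("A" * 50, "A" * 50, "A" * 50, start=0)
        assert cgi_coverage(GenomicInterval("chr1", 0, 50), aln) == 1.0

    def test_human_gaps_do_not_count_as_coverage(self):
        aln = make_triple("ACGTACGT", "AC----GT", "ACGTACGT", start=0)
        assert cgi_coverage(GenomicInterval("chr1", 0, 8), aln) == 0.5

    def test_exactly_half_retained_in_rate_table(self):
        aln = make_triple("A" * 100, "A" * 100, "A" * 100, start=0)
        table = cgi_rate_table([("c", GenomicInterval("chr1", 0, 200))], aln)
        assert table.loc[0, "coverage"] == 0.5
        assert bool(table.loc[0, "passed_coverage"])


class TestCountEvents:
    def test_single_deamination_on_human_branch(self):
        aln = make_triple("ACGT", "ATGT", "ACGT", start=0)
        c = count_events(GenomicInterval("chr1", 0, 4), aln)
        assert (c.anc_cpg, c.ev_cpg_to_tpg_cpa) == (1, 1)
        assert c.ev_cpg_to_other == 0

    def test_cpa_in_both_lineages_counts_twice(self):
        aln = make_triple("ACGT", "ACAT", "ACAT", start=0)
        c = count_events(GenomicInterval("chr1", 0, 4), aln)
        assert (c.anc_cpg, c.ev_cpg_to_tpg_cpa) == (1, 2)

    def test_identity_alignment_no_events(self):
        s = "ACGTTGCACGGT"
        c = count_events(GenomicInterval("chr1", 0, len(s)),
                         make_triple(s, s, s, start=0))
        for f in c.__dataclass_fields__:
            if f.startswith("ev_"):
                assert getattr(c, f) == 0

    def test_fixation_and_other_classes(self):
        #           anc TG -> human CG: one fixation; anc GG -> chimp CG
        aln = make_triple("TTGAGGA", "TCGAGGA", "TTGACGA", start=0)
        c = count_events(GenomicInterval("chr1", 0, 7), aln)
        assert c.ev_tpg_cpa_to_cpg == 1
        assert c.ev_other_to_cpg == 1

    def test_derived_cpg_excluded_from_at_to_gc(self):
        # ancestral A after C; human A->G creates a derived CpG, so it is
        # not a (non-CpG-context) GC-gain event for v)
        aln = make_triple("CAT", "CGT", "CAT", start=0)
        c = count_events(GenomicInterval("chr1", 0, 3), aln)
        assert c.ev_at_to_gc == 0
        # ...but the ancestral CpA -> derived CpG is a fixation event
        assert c.ev_tpg_cpa_to_cpg == 1

    def test_ancestral_cpg_context_excluded_from_gc_denominator(self):
        aln = make_triple("ACGA", "ACGA", "ACGA", start=0)
        c = count_events(GenomicInterval("chr1", 0, 4), aln)
        assert c.anc_gc_noncpg == 0 and c.anc_cpg == 1

    def test_lineage_gap_voids_dinucleotide_event(self):
        aln = make_triple("ACGT", "A-GT", "ACGT", start=0)
        c = count_events(GenomicInterval("chr1", 0, 4), aln)
        assert c.anc_cpg == 1 and c.ev_cpg_to_tpg_cpa == 0

    def test_ancestor_n_removes_opportunity(self):
        aln = make_triple("ANGT", "ATGT", "ANGT", start=0)
        c = count_events(GenomicInterval("chr1", 0, 4), aln)
        assert c.anc_cpg == 0

    def test_dinucleotide_must_start_inside_cgi(self):
        # CpG straddling the CGI end: first base inside -> counted;
        # first base outside -> not
        aln = make_triple("TACGTT", "TACGTT", "TACGTT", start=0)
        inside = count_events(GenomicInterval("chr1", 0, 3), aln)
        outside = count_events(GenomicInterval("chr1", 0, 2), aln)
        assert inside.anc_cpg == 1 and outside.anc_cpg == 0

    def test_multi_block_counts_add(self):
        a1 = make_triple("ACGT", "ATGT", "ACGT", start=0)
        a2 = make_triple("ACGT", "ACGT", "ACAT", start=4)
        a1.blocks.extend(a2.blocks)
        c = count_events(GenomicInterval("chr1", 0, 8), a1)
        assert (c.anc_cpg, c.ev_cpg_to_tpg_cpa) == (2, 2)


class TestRatesFromCounts:
    def test_rate_is_events_over_twice_opportunities(self):
        c = SubstitutionCounts(anc_cpg=1, ev_cpg_to_tpg_cpa=1)
        assert rates_from_counts(c).cpg_to_tpg_cpa == 0.5

    def test_zero_opportunities_is_undefined(self):
        r = rates_from_counts(SubstitutionCounts())
        assert math.isnan(r.cpg_to_tpg_cpa)

    def test_no_events_gives_zero_rates(self):
        c = SubstitutionCounts(anc_cpg=3, anc_tpg_cpa=2, anc_other=4,
                               anc_at=5, anc_gc_noncpg=6)
        r = rates_from_counts(c)
        for name in ("cpg_to_tpg_cpa", "tpg_cpa_to_cpg", "cpg_to_other",
                     "other_to_cpg", "at_to_gc", "gc_to_at"):
            assert getattr(r, name) == 0.0


class TestBruteForceOracle:
    def test_exact_agreement_on_random_gapless_triples(self):
        """count_events vs an independent per-(position, lineage) scanner
        on random gapless triples up to 100 bp, including sub-interval
        CGIs and occasional N bases."""
        rng = np.random.default_rng(20260923)
        alphabet = np.array(list("ACGTN"))
        probs = [0.24, 0.26, 0.26, 0.22, 0.02]
        for trial in range(300):
            L = int(rng.integers(2, 101))
            anc, hum, chp = (
                "".join(rng.choice(alphabet, size=L, p=probs))
                for _ in range(3))
            start = int(rng.integers(0, L))
            end = int(rng.integers(start + 1, L + 1))
            aln = make_triple(anc, hum, chp, start=0)
            got = count_events(GenomicInterval("chr1", start, end), aln)
            want = brute_force_counts(anc, hum, chp, start, end)
            for f in got.__dataclass_fields__:
                assert getattr(got, f) == want.get(f, 0), (trial, f)

    def test_defined_rates_bounded(self):
        rng = np.random.default_rng(99)
        alphabet = np.array(list("ACGT"))
        for _ in range(50):
            L = int(rng.integers(4, 60))
            anc, hum, chp = ("".join(rng.choice(alphabet, size=L))
                             for _ in range(3))
            aln = make_triple(anc, hum, chp, start=0)
            r = rates_from_counts(
                count_events(GenomicInterval("chr1", 0, L), aln))
            for name in ("cpg_to_tpg_cpa", "tpg_cpa_to_cpg", "cpg_to_other",
                         "other_to_cpg", "at_to_gc", "gc_to_at"):
                v = getattr(r, name)
                assert math.isnan(v) or 0.0 <= v <= 1.0
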