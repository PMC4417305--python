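"""Gene-model parsing, window arithmetic and positional classification."""

import io

import pytest
from hypothesis import given, strategies as st

from cgievol.regions import (
    GeneModel,
    GenomicInterval,
    ParseError,
    classify_all,
    classify_cgi,
    five_prime_window,
    intragenic_window,
    load_cgi_bed,
    load_gene_models,
    three_prime_window,
)
from conftest import brute_force_category


def make_gene(name="g", chrom="chr1", strand="+", exons=((5000, 5200),),
              coding=True, symbol=""):
    tx = (exons[0][0], exons[-1][1])
    return GeneModel(
        name=name,
        interval=GenomicInterval(chrom, *tx, strand),
        cds_start=tx[0],
        cds_end=tx[1] if coding else tx[0],
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        symbol=symbol,
    )


GENE_TSV_HEADER = "name\tchrom\tstrand\ttxStart\ttxEnd\tcdsStart\tcdsEnd\texonCount\texonStarts\texonEnds\n"


class TestLoadGeneModels:
    def test_coding_flag_from_cds_bounds(self):
        tsv = GENE_TSV_HEADER + (
            "nc1\tchr1\t+\t100\t900\t500\t500\t1\t100,\t900,\n"
            "cd1\tchr1\t+\t100\t900\t100\t900\t1\t100,\t900,\n"
        )
        genes = load_gene_models(io.StringIO(tsv))
        assert [g.coding for g in genes] == [False, True]

    def test_headerless_ucsc_order(self):
        tsv = "tx\tchr2\t-\t100\t900\t100\t100\t2\t100,500,\t200,900,\n"
        (g,) = load_gene_models(io.StringIO(tsv))
        assert g.interval.chrom == "chr2" and not g.coding
        assert [(e.start, e.end) for e in g.exons] == [(100, 200), (500, 900)]

    def test_empty_input(self):
        assert load_gene_models(io.StringIO("")) == []

    def test_exon_list_mismatch_names_row(self):
        tsv = GENE_TSV_HEADER + "badtx\tchr1\t+\t100\t900\t100\t900\t2\t100,500,\t200,\n"
        with pytest.raises(ParseError, match="badtx"):
            load_gene_models(io.StringIO(tsv))

    def test_malformed_exon_list(self):
        tsv = GENE_TSV_HEADER + "oops\tchr1\t+\t100\t900\t100\t900\t1\t1x0,\t900,\n"
        with pytest.raises(ParseError, match="oops"):
            load_gene_models(io.StringIO(tsv))


class TestWindows:
    def test_five_prime_plus_strand(self):
        g = make_gene(exons=((5000, 5200), (8000, 8100)))
        w = five_prime_window(g)
        assert (w.start, w.end) == (2000, 5200)

    def test_five_prime_minus_strand_uses_rightmost_exon(self):
        g = make_gene(strand="-", exons=((100, 200), (300, 400)))
        w = five_prime_window(g)
        assert (w.start, w.end) == (300, 3400)

    def test_five_prime_clamped_at_zero(self):
        g = make_gene(exons=((1000, 1100),))
        w = five_prime_window(g)
        assert (w.start, w.end) == (0, 1100)

    def test_three_prime_plus_strand_includes_final_exon(self):
        g = make_gene(exons=((5000, 5200), (9000, 9500)))
        w = three_prime_window(g)
        assert (w.start, w.end) == (9000, 12500)

    def test_three_prime_minus_strand_clamped(self):
        g = make_gene(strand="-", exons=((100, 200), (5000, 5100)))
        w = three_prime_window(g)
        assert (w.start, w.end) == (0, 200)

    def test_windows_clamped_to_chrom_length(self):
        g = make_gene(exons=((5000, 5200),))
        w = three_prime_window(g, chrom_length=6000)
        assert (w.start, w.end) == (5000, 6000)

    @pytest.mark.parametrize(
        "exons, expected",
        [
            (((100, 200), (500, 600), (900, 1000)), (200, 900)),
            (((100, 200), (900, 1000)), (200, 900)),
        ],
    )
    def test_intragenic_spans_first_to_final_intron(self, exons, expected):
        g = make_gene(exons=exons)
        w = intragenic_window(g)
        assert (w.start, w.end) == expected

    def test_intragenic_empty_for_single_exon(self):
        assert intragenic_window(make_gene()) is None

    def test_single_exon_gene_has_both_flank_windows(self):
        g = make_gene(exons=((5000, 5200),))
        assert five_prime_window(g).overlaps(three_prime_window(g))


class TestClassifyCGI:
    def test_priority_five_prime_beats_intragenic(self):
        a = make_gene("a", exons=((5000, 5200), (9000, 9100)))
        b = make_gene("b", exons=((2000, 2100), (8000, 8100)))
        cgi = GenomicInterval("chr1", 4000, 4200)  # in a's 5' win, b's introns
        cls = classify_cgi(cgi, [a, b])
        assert cls.category == "five_prime"
        assert cls.associated_genes == ["a"]

    def test_no_overlap_is_intergenic_noncoding(self):
        cls = classify_cgi(GenomicInterval("chr1", 50000, 50500), [make_gene()])
        assert (cls.category, cls.coding) == ("intergenic", False)

    def test_three_prime_coding_from_triggering_transcript(self):
        g = make_gene(exons=((5000, 5200), (9000, 9500)), coding=True)
        cls = classify_cgi(GenomicInterval("chr1", 11000, 11200), [g])
        assert (cls.category, cls.coding) == ("three_prime", True)

    def test_coding_if_any_triggering_transcript_codes(self):
        g1 = make_gene("nc", exons=((5000, 5200),), coding=False)
        g2 = make_gene("cd", exons=((5100, 5300),), coding=True)
        cls = classify_cgi(GenomicInterval("chr1", 4900, 5000), [g1, g2])
        assert cls.coding and set(cls.associated_genes) == {"nc", "cd"}

    def test_adding_five_prime_overlap_never_demotes(self):
        g = make_gene(exons=((5000, 5200), (9000, 9500)))
        cgi = GenomicInterval("chr1", 9600, 9700)
        assert classify_cgi(cgi, [g]).category == "three_prime"
        extra = make_gene("x", exons=((9600, 9900),))
        assert classify_cgi(cgi, [g, extra]).category == "five_prime"


@st.composite
def toy_layout(draw):
    """<=5 genes and a CGI on a 10 kb toy chromosome."""
    genes = []
    for i in range(draw(st.integers(0, 5))):
        n_exons = draw(st.integers(1, 3))
        bounds = sorted(draw(st.lists(
            st.integers(0, 9999), min_size=2 * n_exons,
            max_size=2 * n_exons, unique=True)))
        exons = tuple(
            (bounds[2 * k], bounds[2 * k + 1]) for k in range(n_exons))
        genes.append(make_gene(
            name=f"g{i}", strand=draw(st.sampled_from("+-")), exons=exons,
            coding=draw(st.booleans())))
    lo = draw(st.integers(0, 9998))
    hi = draw(st.integers(lo + 1, 10000))
    return genes, GenomicInterval("chr1", lo, hi)


class TestProperties:
    @given(toy_layout())
    def test_agrees_with_per_base_enumeration(self, layout):
        genes, cgi = layout
        assert classify_cgi(cgi, genes).category == \
            brute_force_category(cgi, genes)

    @given(toy_layout())
    def test_mirror_symmetry(self, layout):
        """Mirroring all coordinates and flipping strands preserves class."""
        genes, cgi = layout
        L = 20000  # mirror about a chromosome of length L with margin
        mirrored_genes = []
        for g in genes:
            exons = tuple(
                (L - e.end, L - e.start) for e in reversed(g.exons))
            mirrored_genes.append(make_gene(
                name=g.name,
                strand="-" if g.interval.strand == "+" else "+",
                exons=exons, coding=g.coding))
        mirrored_cgi = GenomicInterval("chr1", L - cgi.end, L - cgi.start)
        assert classify_cgi(cgi, genes).category == \
            classify_cgi(mirrored_cgi, mirrored_genes).category


class TestClassifyAll:
    def test_bed_roundtrip_and_table(self):
        bed = "chr1\t4000\t4200\tcgi_a\nchr1\t50000\t50500\n"
        cgis = load_cgi_bed(io.StringIO(bed))
        assert cgis[1][0] == "chr1:50000-50500"
        table = classify_all(cgis, [make_gene(exons=((5000, 5200),))])
        assert list(table["category"]) == ["five_prime", "intergenic"]
        assert list(table["coding"]) == ["coding", "noncoding"]

    def test_every_cgi_gets_exactly_one_category(self, small_genome):
        from cgievol.regions import load_gene_models as lgm

        genes = lgm(io.StringIO(small_genome.genes.to_csv(sep="\t", index=False)))
        table = classify_all(small_genome.cgis, genes)
        assert len(table) == len(small_genome.cgis)
        assert table["category"].isin(
            ["five_prime", "three_prime", "intragenic", "intergenic"]).all()
        assert (table.loc[table["category"] == "intergenic", "coding"]
                == "noncoding").all()
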