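"""Domain types, file round-trips, regulatory-region calling and
site-to-gene association."""

import pytest
from hypothesis import given, settings, strategies as st

from reginfluence import (
    BindingSite,
    TSSAnnotation,
    associate_sites,
    classify_proximal,
    define_regulatory_regions,
    nearest_gene_assignment,
    read_sites_bed,
    read_tss_table,
    signed_distance,
    write_sites_bed,
    write_tss_table,
)


class TestParsing:
    def test_tss_row_parses(self, tmp_path):
        p = tmp_path / "tss.tsv"
        p.write_text("gene_id\tchrom\tpos\tstrand\ng1\tchr1\t1000\t+\n")
        (rec,) = read_tss_table(p)
        assert rec == TSSAnnotation("g1", "chr1", 1000, "+")

    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "tss.tsv"
        p.write_text("gene_id\tchrom\tpos\tstrand\n")
        assert read_tss_table(p) == []

    @pytest.mark.parametrize(
        "row,msg",
        [
            ("g1\tchr1\t1000\t*", "strand"),
            ("g1\tchr1\tabc\t+", "position"),
        ],
    )
    def test_malformed_rows_rejected(self, tmp_path, row, msg):
        p = tmp_path / "tss.tsv"
        p.write_text(f"gene_id\tchrom\tpos\tstrand\n{row}\n")
        with pytest.raises(ValueError, match=msg):
            read_tss_table(p)

    def test_duplicate_gene_id_named_in_error(self, tmp_path):
        p = tmp_path / "tss.tsv"
        p.write_text(
            "gene_id\tchrom\tpos\tstrand\ng1\tchr1\t10\t+\ng1\tchr1\t20\t-\n"
        )
        with pytest.raises(ValueError, match="g1"):
            read_tss_table(p)

    def test_bed7_row_parses(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1 500 900 s1 p300,CEBPA 12.5 0.4\n")
        (site,) = read_sites_bed(p, "liver")
        assert site.regulators == frozenset({"p300", "CEBPA"})
        assert site.enrichment == 12.5
        assert site.conservation == 0.4
        assert site.tissue == "liver"

    def test_bed3_row_has_empty_regulators(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t500\t900\n")
        (site,) = read_sites_bed(p, "liver")
        assert site.regulators == frozenset()
        assert site.enrichment is None

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1 900 500\n")
        with pytest.raises(ValueError, match="start"):
            read_sites_bed(p, "liver")


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 10**6),
            st.integers(1, 5000),
            st.sets(st.sampled_from(["p300", "CEBPA", "FOXA1"])),
            st.one_of(st.none(), st.floats(0.1, 100.0)),
            st.one_of(st.none(), st.floats(0.0, 1.0)),
        ),
        min_size=1,
        max_size=20,
    )
)
def test_sites_bed_round_trip(tmp_path_factory, raw):
    """Writing then re-reading a BED7 preserves every field exactly."""
    sites = [
        BindingSite(f"s{i}", "chr1", start, start + length, "t",
                    frozenset(regs), enr, cons)
        for i, (start, length, regs, enr, cons) in enumerate(raw)
    ]
    path = tmp_path_factory.mktemp("bed") / "sites.bed"
    write_sites_bed(sites, path)
    assert read_sites_bed(path, "t") == sites


def test_tss_round_trip(tmp_path, toy_genes):
    path = tmp_path / "tss.tsv"
    write_tss_table(toy_genes, path)
    assert read_tss_table(path) == toy_genes


class TestRegulatoryRegions:
    def _peak(self, start, end, reg, tissue="liver"):
        return BindingSite(f"{reg}:{start}", "chr1", start, end, tissue)

    def test_single_p300_peak_kept(self):
        out = define_regulatory_regions({"p300": [self._peak(0, 100, "p300")]}, "p300")
        assert len(out) == 1
        assert out[0].regulators == frozenset({"p300"})

    def test_single_other_factor_dropped(self):
        out = define_regulatory_regions(
            {"p300": [], "CEBPA": [self._peak(0, 100, "CEBPA")]}, "p300"
        )
        assert out == []

    def test_two_cobound_factors_kept_without_p300(self):
        out = define_regulatory_regions(
            {
                "p300": [],
                "CEBPA": [self._peak(0, 100, "CEBPA")],
                "FOXA1": [self._peak(50, 150, "FOXA1")],
            },
            "p300",
        )
        assert len(out) == 1
        assert out[0].regulators == frozenset({"CEBPA", "FOXA1"})
        assert (out[0].start, out[0].end) == (0, 150)

    def test_unknown_p300_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            define_regulatory_regions({"CBP": []}, "p300")

    def test_single_coregulator_mode_keeps_everything(self):
        out = define_regulatory_regions({"CBP": [self._peak(0, 100, "CBP")]}, None)
        assert len(out) == 1

    def test_enrichment_is_max_over_contributors(self):
        peaks = {
            "p300": [BindingSite("a", "chr1", 0, 100, "t", enrichment=3.0)],
            "CEBPA": [BindingSite("b", "chr1", 50, 150, "t", enrichment=9.0)],
        }
        (region,) = define_regulatory_regions(peaks, "p300")
        assert region.enrichment == 9.0

    def test_idempotent_on_own_output(self):
        peaks = {
            "p300": [self._peak(0, 100, "p300"), self._peak(400, 500, "p300")],
            "CEBPA": [self._peak(80, 200, "CEBPA")],
        }
        regions = define_regulatory_regions(peaks, "p300")
        again = define_regulatory_regions({"p300": regions}, "p300")
        assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in regions]


class TestSignedDistance:
    @pytest.mark.parametrize(
        "strand,mid_1based,expected",
        [("+", 9500, -500), ("+", 10000, 0), ("-", 10500, -500)],
    )
    def test_sign_convention(self, strand, mid_1based, expected):
        # A 1 bp interval [m-1, m) covers the 1-based base m exactly.
        site = BindingSite("s", "chr1", mid_1based - 1, mid_1based, "t")
        tss = TSSAnnotation("g", "chr1", 10_000, strand)
        assert site.midpoint == mid_1based
        assert signed_distance(site, tss) == expected

    def test_cross_chromosome_rejected(self):
        site = BindingSite("s", "chr2", 0, 10, "t")
        with pytest.raises(ValueError):
            signed_distance(site, TSSAnnotation("g", "chr1", 100, "+"))

    @settings(max_examples=100, deadline=None)
    @given(offset=st.integers(-50_000, 50_000), tss=st.integers(60_000, 200_000))
    def test_strand_flip_with_mirrored_position_negates(self, offset, tss):
        """Mirroring a site about the TSS and flipping strand negates d."""
        site_fwd = BindingSite("s", "chr1", tss + offset - 1, tss + offset, "t")
        site_mir = BindingSite("s", "chr1", tss - offset - 1, tss - offset, "t")
        d_fwd = signed_distance(site_fwd, TSSAnnotation("g", "chr1", tss, "+"))
        d_mir = signed_distance(site_mir, TSSAnnotation("g", "chr1", tss, "-"))
        assert d_fwd == d_mir


class TestAssociation:
    def test_multi_gene_association(self):
        genes = [
            TSSAnnotation("g1", "chr1", 100_000, "+"),
            TSSAnnotation("g2", "chr1", 170_000, "+"),
        ]
        site = BindingSite("s", "chr1", 139_999, 140_000, "t")  # 40 kb / 30 kb away
        p1, p2 = associate_sites(genes, [site], 50_000)
        assert p1.entries and p2.entries
        p1, p2 = associate_sites(genes, [site], 10_000)
        assert not p1.entries and not p2.entries

    def test_boundary_distance_is_inclusive(self):
        genes = [TSSAnnotation("g1", "chr1", 100_000, "+")]
        site = BindingSite("s", "chr1", 109_999, 110_000, "t")  # exactly 10 kb
        (p,) = associate_sites(genes, [site], 10_000)
        assert [e.site_id for e in p.entries] == ["s"]

    def test_nearest_gene_takes_closest(self):
        genes = [
            TSSAnnotation("g1", "chr1", 100_000, "+"),
            TSSAnnotation("g2", "chr1", 125_000, "+"),
        ]
        site = BindingSite("s", "chr1", 104_999, 105_000, "t")  # 5 kb vs 20 kb
        p1, p2 = nearest_gene_assignment(genes, [site], 50_000)
        assert p1.entries and not p2.entries

    def test_nearest_gene_tie_breaks_lexicographically(self):
        genes = [
            TSSAnnotation("gB", "chr1", 120_000, "+"),
            TSSAnnotation("gA", "chr1", 100_000, "+"),
        ]
        site = BindingSite("s", "chr1", 109_999, 110_000, "t")  # 10 kb from both
        profiles = {p.gene_id: p for p in nearest_gene_assignment(genes, [site], 50_000)}
        assert profiles["gA"].entries and not profiles["gB"].entries

    def test_asymmetric_promoter_window_is_strand_aware(self):
        """A (-5500, 2500) window keeps a site 3 kb upstream but drops
        one 3 kb downstream, following each gene's strand."""
        genes = [
            TSSAnnotation("gP", "chr1", 100_000, "+"),
            TSSAnnotation("gM", "chr1", 500_000, "-"),
        ]
        up_p = BindingSite("upP", "chr1", 96_999, 97_000, "t")     # d = -3000 for gP
        down_p = BindingSite("dnP", "chr1", 102_999, 103_000, "t")  # d = +3000 for gP
        up_m = BindingSite("upM", "chr1", 502_999, 503_000, "t")   # d = -3000 for gM
        profiles = {p.gene_id: p for p in associate_sites(
            genes, [up_p, down_p, up_m], window=(-5500, 2500))}
        assert [e.site_id for e in profiles["gP"].entries] == ["upP"]
        assert [e.site_id for e in profiles["gM"].entries] == ["upM"]

    def test_site_beyond_cutoff_assigned_nowhere(self):
        genes = [TSSAnnotation("g1", "chr1", 100_000, "+")]
        site = BindingSite("s", "chr1", 0, 200, "t")
        (p,) = nearest_gene_assignment(genes, [site], 10_000)
        assert not p.entries

    def test_nearest_is_refinement_of_multi(self, small_dataset):
        """Every (site, gene) pair under nearest-gene assignment also
        appears under multi-gene association at the same cutoff."""
        ds = small_dataset
        sites = ds.sites[ds.spec.tissues[0]]
        multi = {
            (e.site_id, p.gene_id)
            for p in associate_sites(ds.genome, sites, 50_000)
            for e in p.entries
        }
        near = {
            (e.site_id, p.gene_id)
            for p in nearest_gene_assignment(ds.genome, sites, 50_000)
            for e in p.entries
        }
        assert near <= multi
        # and each site appears at most once under nearest assignment
        near_sites = [s for s, _ in near]
        assert len(near_sites) == len(set(near_sites))


class TestProximal:
    @pytest.mark.parametrize("offset,expected", [(200, True), (250, True), (251, False)])
    def test_window_boundary(self, offset, expected):
        genes = [TSSAnnotation("g", "chr1", 10_000, "+")]
        mid = 10_000 + offset
        site = BindingSite("s", "chr1", mid - 1, mid, "t")
        assert classify_proximal(site, genes) is expected

    def test_no_genes_on_chromosome(self):
        site = BindingSite("s", "chrX", 0, 10, "t")
        assert classify_proximal(site, [TSSAnnotation("g", "chr1", 10, "+")]) is False
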