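import numpy as np
import pandas as pd
import pytest

from methfert.regions import (AnnotationBundle, annotate_region, annotate_site,
                              call_dmrs, dmr_sample_means, enrichment)

from .conftest import make_matrix
from .test_diffmeth import fisher_exact_enumeration


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def dmr_bruteforce(positions, min_dmcs=3, max_gap=100):
    """Enumerate every contiguous subset; keep maximal gap-compliant runs."""
    pos = sorted(positions)
    n = len(pos)
    valid = []
    for i in range(n):
        for j in range(i + min_dmcs - 1, n):
            seg = pos[i:j + 1]
            if all(seg[k + 1] - seg[k] <= max_gap for k in range(len(seg) - 1)):
                valid.append((i, j))
    maximal = [(i, j) for (i, j) in valid
               if not any(a <= i and j <= b and (a, b) != (i, j)
                          for (a, b) in valid)]
    return sorted((pos[i], pos[j], j - i + 1) for i, j in maximal)


def as_dmc_frame(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": sorted(positions)})


class TestCallDmrs:
    @pytest.mark.parametrize("positions,expected", [
        ([100, 150, 240], [(100, 240, 3)]),    # gaps 50, 90
        ([100, 150, 260], []),                 # gap 110 breaks the run
        ([100, 200, 300], [(100, 300, 3)]),    # gaps exactly 100: inclusive
    ])
    def test_rule_examples(self, positions, expected):
        out = call_dmrs(as_dmc_frame(positions))
        got = [(r.start, r.end, r.n_dmcs) for r in out.itertuples(index=False)]
        assert got == expected

    def test_empty_input(self):
        assert len(call_dmrs(as_dmc_frame([]))) == 0

    def test_matches_bruteforce_on_random_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(150):
            n = int(rng.integers(0, 50))
            positions = sorted(rng.choice(5000, size=n, replace=False))
            out = call_dmrs(as_dmc_frame(positions))
            got = sorted((r.start, r.end, r.n_dmcs)
                         for r in out.itertuples(index=False))
            assert got == dmr_bruteforce(positions)

    def test_idempotent_and_gap_compliant(self):
        rng = np.random.default_rng(3)
        positions = sorted(rng.choice(3000, size=40, replace=False))
        out = call_dmrs(as_dmc_frame(positions))
        for r in out.itertuples(index=False):
            gaps = np.diff(r.member_pos)
            assert (gaps <= 100).all()
            # re-calling on the members reproduces the region
            again = call_dmrs(as_dmc_frame(r.member_pos))
            assert len(again) == 1
            assert (again.iloc[0]["start"], again.iloc[0]["end"]) == (r.start, r.end)

    def test_direction_from_mean_delta(self):
        dmcs = as_dmc_frame([100, 150, 200])
        dmcs["delta"] = [20.0, 15.0, -5.0]
        out = call_dmrs(dmcs)
        assert out.iloc[0]["direction"] == "hyper"
        assert out.iloc[0]["mixed_direction"]


class TestDmrSampleMeans:
    def test_mean_of_member_percentages(self):
        m = make_matrix([[4, 10], [6, 10]], [[10, 10], [10, 10]],
                        start=100, step=50)
        dmr = {"chrom": "chr1", "member_pos": [100, 150]}
        means = dmr_sample_means(dmr, m)
        assert means["s1"] == pytest.approx(50.0)
        assert means["s2"] == pytest.approx(100.0)

    def test_sample_without_coverage_is_missing(self):
        m = make_matrix([[4, 0], [6, 0]], [[10, 0], [10, 0]],
                        start=100, step=50)
        means = dmr_sample_means({"chrom": "chr1", "member_pos": [100, 150]}, m)
        assert np.isnan(means["s2"])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def bundle():
    genes = pd.DataFrame([
        ("GPLUS", "chr1", 10_000, 20_000, "+"),
        ("GMINUS", "chr1", 30_000, 40_000, "-"),
    ], columns=["gene_id", "chrom", "start", "end", "strand"])
    exons = pd.DataFrame([
        ("GPLUS", "chr1", 10_000, 11_000),
        ("GPLUS", "chr1", 19_000, 20_000),
    ], columns=["gene_id", "chrom", "start", "end"])
    utr5 = pd.DataFrame([("GPLUS", "chr1", 10_000, 10_400)],
                        columns=["gene_id", "chrom", "start", "end"])
    utr3 = pd.DataFrame([("GPLUS", "chr1", 19_600, 20_000)],
                        columns=["gene_id", "chrom", "start", "end"])
    cgis = pd.DataFrame([("chr1", 50_000, 51_000)],
                        columns=["chrom", "start", "end"])
    repeats = pd.DataFrame([("chr1", 70_000, 70_500, "L1")],
                           columns=["chrom", "start", "end", "family"])
    return AnnotationBundle(genes=genes, exons=exons, utr5=utr5, utr3=utr3,
                            cgis=cgis, repeats=repeats)


class TestAnnotateSite:
    @pytest.mark.parametrize("pos,feature", [
        (10_050, "TSS"),        # TSS+50 on a plus-strand gene
        (8_500, "promoter"),    # TSS-1500
        (10_300, "5UTR"),       # past the TSS window, inside the 5'UTR
    ])
    def test_plus_strand_windows(self, bundle, pos, feature):
        assert annotate_site("chr1", pos, bundle)["gene_feature"] == feature

    def test_intron_and_exon(self, bundle):
        assert annotate_site("chr1", 15_000, bundle)["gene_feature"] == "intron"
        assert annotate_site("chr1", 10_700, bundle)["gene_feature"] == "exon"

    def test_tts_precedence_over_utr3(self, bundle):
        assert annotate_site("chr1", 19_950, bundle)["gene_feature"] == "TTS"

    def test_minus_strand_promoter_is_upstream_of_tss(self, bundle):
        # TSS of the minus-strand gene is its right end (40,000)
        assert annotate_site("chr1", 41_500, bundle)["gene_feature"] == "promoter"
        assert annotate_site("chr1", 40_050, bundle)["gene_feature"] == "TSS"

    @pytest.mark.parametrize("pos,context", [
        (50_500, "CGI"),
        (51_500, "shore"),     # 500 bp outside the CGI edge
        (53_500, "shelf"),     # 2500 bp outside
        (55_500, "open_sea"),  # 4500 bp outside
    ])
    def test_cgi_context_distances(self, bundle, pos, context):
        assert annotate_site("chr1", pos, bundle)["cgi_context"] == context

    def test_repeat_any_overlap(self, bundle):
        hit = annotate_site("chr1", 70_100, bundle)
        assert hit["repeat_overlap"] and hit["repeat_family"] == "L1"
        assert not annotate_site("chr1", 80_000, bundle)["repeat_overlap"]

    def test_gene_assignment_within_10kb(self, bundle):
        assert "GPLUS" in annotate_site("chr1", 25_000, bundle)["genes"]
        assert annotate_site("chr1", 95_000, bundle)["genes"] == []

    def test_unknown_chromosome_falls_back(self, bundle):
        out = annotate_site("chrUn", 100, bundle)
        assert out["gene_feature"] == "intergenic"
        assert out["cgi_context"] == "open_sea"

    def test_exactly_one_label_of_each_kind(self, bundle):
        rng = np.random.default_rng(8)
        for pos in rng.integers(1, 100_000, size=50):
            out = annotate_site("chr1", int(pos), bundle)
            assert isinstance(out["gene_feature"], str)
            assert out["cgi_context"] in ("CGI", "shore", "shelf", "open_sea")


class TestAnnotateRegion:
    def test_cgi_at_80_percent_overlap(self, bundle):
        # 100-bp region with 80 bp inside the CGI: 0.80 >= 0.75
        out = annotate_region("chr1", 50_921, 51_020, bundle)
        assert out["cgi_context"] == "CGI"

    def test_74_percent_falls_to_open_sea(self, bundle):
        # 74 bp inside the CGI, 26 bp in shore: neither reaches 75%
        out = annotate_region("chr1", 50_927, 51_026, bundle)
        assert out["cgi_context"] == "open_sea"

    def test_intron_open_sea_region(self, bundle):
        out = annotate_region("chr1", 14_000, 14_200, bundle)
        assert out["gene_feature"] == "intron"
        assert out["cgi_context"] == "open_sea"

    def test_one_bp_region_agrees_with_site(self, bundle):
        for pos in (10_050, 8_500, 15_000, 50_500, 51_500, 53_500, 70_100):
            site = annotate_site("chr1", pos, bundle)
            region = annotate_region("chr1", pos, pos, bundle)
            assert region["gene_feature"] == site["gene_feature"]
            assert region["cgi_context"] == site["cgi_context"]
            assert region["repeat_overlap"] == site["repeat_overlap"]


class TestEnrichment:
    def test_fold_change_arithmetic(self):
        dmc = pd.Series(["LINE"] * 38 + ["other"] * 62)
        bg = pd.Series(["LINE"] * 16 + ["other"] * 84)
        table = enrichment(dmc, bg).set_index("category")
        assert table.loc["LINE", "fold"] == pytest.approx(0.38 / 0.16)
        assert table.loc["LINE", "fold"] == pytest.approx(2.375)

    def test_identical_proportions(self):
        labels = pd.Series(["a"] * 5 + ["b"] * 5)
        table = enrichment(labels, labels).set_index("category")
        assert table.loc["a", "fold"] == pytest.approx(1.0)
        assert table.loc["a", "fisher_p"] == pytest.approx(1.0)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        dmc = pd.Series(["x"] * 7 + ["y"] * 3)
        bg = pd.Series(["x"] * 2 + ["y"] * 18)
        table = enrichment(dmc, bg).set_index("category")
        expected = fisher_exact_enumeration(7, 3, 2, 18)
        assert table.loc["x", "fisher_p"] == pytest.approx(expected, rel=1e-9)

    def test_category_absent_from_background_reported(self):
        dmc = pd.Series(["new", "old"])
        bg = pd.Series(["old"] * 10)
        table = enrichment(dmc, bg).set_index("category")
        assert np.isnan(table.loc["new", "fold"])
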