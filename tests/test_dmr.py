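import numpy as np
import pytest
from scipy import stats

from twinmeth import (
    CpGSite,
    ValidationError,
    count_cpgs_in_regions,
    datasets,
    estimate_acf,
    find_candidate_regions,
    find_dmrs,
    region_site_coverage,
    score_region,
    slk_adjust,
)
from twinmeth.dmr import AcfEstimate, DmrRecord, total_span
from twinmeth.simulate import simulate_null_pvalue_track


def _identity_acf():
    return AcfEstimate(
        bin_edges=np.arange(0, 550, 50), corr=np.zeros(10), counts=np.zeros(10, int)
    )


class TestEstimateAcf:
    def test_iid_track_near_zero(self):
        sites, p = simulate_null_pvalue_track(10000, seed=2)
        acf = estimate_acf(sites, p)
        assert np.abs(acf.corr).max() < 0.05

    def test_known_correlation_recovered(self):
        ac = lambda d: np.where(np.asarray(d) <= 100, 0.5, 0.0)
        sites, p = simulate_null_pvalue_track(10000, ac_range=ac, seed=3)
        acf = estimate_acf(sites, p)
        assert acf.corr[0] == pytest.approx(0.5, abs=0.05)
        assert acf.corr[1] == pytest.approx(0.5, abs=0.05)
        assert np.abs(acf.corr[4:]).max() < 0.05

    def test_single_site_errors(self):
        with pytest.raises(ValidationError):
            estimate_acf([CpGSite("chr1", 10)], np.array([0.5]))


class TestSlkAdjust:
    def test_isolated_site_keeps_raw_p(self):
        sites = [CpGSite("chr1", 100), CpGSite("chr1", 5000)]
        adj = slk_adjust(sites, np.array([0.05, 0.7]), _identity_acf(), window=500)
        np.testing.assert_allclose(adj, [0.05, 0.7])

    def test_two_site_stouffer_hand_computation(self):
        # z(0.05) = 1.6449; combined = 2 * 1.6449 / sqrt(2) = 2.3262 -> p = 0.0100
        sites = [CpGSite("chr1", 100), CpGSite("chr1", 150)]
        adj = slk_adjust(sites, np.array([0.05, 0.05]), _identity_acf(), window=500)
        np.testing.assert_allclose(adj, [0.01000, 0.01000], atol=5e-5)

    def test_perfect_correlation_adds_nothing(self):
        acf = AcfEstimate(
            bin_edges=np.arange(0, 550, 50),
            corr=np.full(10, 0.999999),
            counts=np.zeros(10, int),
        )
        sites = [CpGSite("chr1", 100), CpGSite("chr1", 150)]
        adj = slk_adjust(sites, np.array([0.05, 0.05]), acf, window=500)
        np.testing.assert_allclose(adj, [0.05, 0.05], atol=1e-4)

    def test_identity_equals_classic_stouffer_on_random_tracks(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = rng.integers(3, 30)
            pos = np.sort(rng.choice(np.arange(1, 10000), n, replace=False))
            sites = [CpGSite("chr1", int(x)) for x in pos]
            p = rng.uniform(0.01, 0.99, n)
            adj = slk_adjust(sites, p, _identity_acf(), window=300)
            z = stats.norm.isf(p)
            for i in range(n):
                nb = np.abs(pos - pos[i]) <= 300
                expect = (
                    p[i]
                    if nb.sum() == 1
                    else stats.norm.sf(z[nb].sum() / np.sqrt(nb.sum()))
                )
                assert adj[i] == pytest.approx(expect, abs=1e-12)


class TestRegions:
    def test_far_apart_sites_stay_singletons(self):
        sites = [CpGSite("chr1", 1000 * (i + 1)) for i in range(6)]
        p = np.array([0.01, 0.5, 0.01, 0.5, 0.01, 0.5])
        regions = find_candidate_regions(sites, p, seed_p=0.05, join_dist=500)
        assert [list(r) for r in regions] == [[0], [2], [4]]

    def test_consecutive_significant_run_becomes_one_region(self):
        # six significant CpGs spanning 151 bp, mirroring a real DMR's layout
        pos = [27052679, 27052702, 27052741, 27052771, 27052816, 27052830]
        sites = [CpGSite("chr17", p) for p in pos]
        p = np.full(6, 0.001)
        regions = find_candidate_regions(sites, p, seed_p=0.05, join_dist=500)
        assert len(regions) == 1 and len(regions[0]) == 6
        rec = score_region(regions[0], sites, p, _identity_acf(), total_span_bp=152)
        assert (rec.start, rec.end, rec.n_cpgs) == (27052679, 27052830, 6)

    def test_empty_track_gives_no_regions(self):
        sites = [CpGSite("chr1", 10), CpGSite("chr1", 20)]
        assert find_candidate_regions(sites, np.array([0.5, 0.9])) == []


class TestScoreRegion:
    def test_whole_track_region_sidak_equals_slk(self):
        sites = [CpGSite("chr1", 100), CpGSite("chr1", 200)]
        p = np.array([0.01, 0.02])
        rec = score_region(np.array([0, 1]), sites, p, _identity_acf(), total_span_bp=101)
        assert rec.sidak_p == pytest.approx(rec.slk_p, abs=1e-12)

    def test_sidak_hand_computation(self):
        # slk 0.01, span ratio 10 -> 1 - 0.99^10 = 0.09562
        sites = [CpGSite("chr1", 100), CpGSite("chr1", 199)]
        z = stats.norm.isf(0.01)
        p_single = stats.norm.sf(2 * z / np.sqrt(2))
        rec = score_region(
            np.array([0, 1]),
            sites,
            np.array([0.01, 0.01]),
            _identity_acf(),
            total_span_bp=1000,
        )
        assert rec.sidak_p == pytest.approx(1 - (1 - p_single) ** 10, abs=1e-9)

    def test_single_site_region_keeps_raw_p(self):
        sites = [CpGSite("chr1", 100)]
        rec = score_region(np.array([0]), sites, np.array([0.03]), _identity_acf(), 1)
        assert rec.slk_p == pytest.approx(0.03)

    def test_sidak_never_below_slk(self):
        rng = np.random.default_rng(9)
        sites, p = simulate_null_pvalue_track(300, seed=9)
        span = total_span(sites)
        for _ in range(30):
            a = rng.integers(0, 290)
            idx = np.arange(a, a + rng.integers(1, 10))
            rec = score_region(idx, sites, p, _identity_acf(), span)
            assert 0.0 <= rec.slk_p <= rec.sidak_p <= 1.0


class TestCoverageCounting:
    def test_published_interval_examples(self):
        top = datasets.top_cpg_associations()
        sites = [CpGSite(c, p) for c, p in zip(top["chrom"], top["pos"])]
        dmr1 = DmrRecord("chr17", 27052679, 27052830, 6, 0.0, 0.0)
        dmr25 = DmrRecord("chr10", 126489968, 126490164, 9, 0.0, 0.0)
        counts = count_cpgs_in_regions([dmr1, dmr25], sites)
        assert list(counts) == [4, 1]

    def test_empty_site_list_gives_zeros(self):
        regions = [DmrRecord("chr1", 1, 100, 3, 0.0, 0.0)]
        assert list(count_cpgs_in_regions(regions, [])) == [0]

    def test_positional_and_concordant_coverage_modes(self):
        top = datasets.top_cpg_associations()
        dmrs = datasets.dmr_intervals()
        positional = region_site_coverage(dmrs, top)
        concordant = region_site_coverage(dmrs, top, require_gene_concordance=True)
        # gene-discordant overlaps exist, so the positional mode finds more
        assert len(positional) >= len(concordant)
        assert set(concordant["dmr_id"]) <= set(positional["dmr_id"])


def test_full_pipeline_on_implanted_region():
    ac = lambda d: np.clip(0.3 * (1 - np.asarray(d) / 200.0), 0, 0.3)
    sites, p = simulate_null_pvalue_track(5000, mean_spacing=80, ac_range=ac, seed=13)
    p = p.copy()
    p[2000:2020] = np.random.default_rng(14).beta(0.05, 1, 20)
    recs = find_dmrs(sites, p, threshold=0.05)
    lo, hi = sites[2000].pos, sites[2019].pos
    assert any(r.start <= hi and r.end >= lo for r in recs)
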