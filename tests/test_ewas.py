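import numpy as np
import pandas as pd
import pytest

from twinmeth import (
    CpGSite,
    ValidationError,
    annotate_nearest_gene,
    bh_fdr,
    ewas_scan,
    fit_gee_cpg,
)
from twinmeth.ewas import build_design, cluster_robust_ols


def _aligned(ph, ids):
    return ph.aligned_to(ids)


class TestFitGee:
    def test_independence_equals_ols(self, small_mvalues):
        mv, ph, _ = small_mvalues
        y = mv.m[0]
        keep = ~np.isnan(y)
        x = build_design(_aligned(ph, mv.sample_ids)[keep], ("age", "sex", "dbp")).to_numpy()
        ols = np.linalg.lstsq(x, y[keep], rcond=None)[0][1]
        coef, _, _ = fit_gee_cpg(
            y, ph, ("age", "sex", "dbp"), working="independence", sample_ids=mv.sample_ids
        )
        assert coef == pytest.approx(ols, abs=1e-8)

    def test_exact_linear_relation_recovered(self, small_mvalues):
        _, ph, _ = small_mvalues
        fpg = ph.data["fpg"].to_numpy()
        coef, se, p = fit_gee_cpg(2.0 * fpg, ph, covariates=())
        assert coef == pytest.approx(2.0, abs=1e-8)
        assert p < 1e-10

    def test_invariant_to_pair_relabeling_and_twin_order(self, small_mvalues):
        mv, ph, _ = small_mvalues
        ref = fit_gee_cpg(mv.m[1], ph, ("age", "sex", "dbp"), sample_ids=mv.sample_ids)
        relabeled = ph.data.copy()
        relabeled["pair_id"] = relabeled["pair_id"].map(lambda s: "x" + s[::-1])
        relabeled["twin_index"] = relabeled["twin_index"].map({1: 2, 2: 1})
        from twinmeth import TwinPhenotypeTable

        alt = fit_gee_cpg(
            mv.m[1],
            TwinPhenotypeTable(relabeled),
            ("age", "sex", "dbp"),
            sample_ids=mv.sample_ids,
        )
        np.testing.assert_allclose(ref, alt, atol=1e-10)

    def test_refuses_too_few_pairs(self, small_mvalues):
        mv, ph, _ = small_mvalues
        y = mv.m[0].copy()
        y[10:] = np.nan
        with pytest.raises(ValidationError, match="complete pairs"):
            fit_gee_cpg(y, ph, sample_ids=mv.sample_ids)

    def test_collinear_design_named(self, small_mvalues):
        mv, ph, _ = small_mvalues
        ph2 = ph.data.copy()
        ph2["dbp"] = ph2["age"] * 2.0  # exact collinearity
        from twinmeth import TwinPhenotypeTable

        with pytest.raises(ValidationError, match="collinear"):
            fit_gee_cpg(
                mv.m[0],
                TwinPhenotypeTable(ph2),
                ("age", "sex", "dbp"),
                sample_ids=mv.sample_ids,
            )

    def test_cluster_robust_matches_statsmodels(self, small_mvalues):
        import statsmodels.api as sm

        mv, ph, _ = small_mvalues
        y = mv.m[2]
        keep = ~np.isnan(y)
        al = _aligned(ph, mv.sample_ids)[keep]
        x = build_design(al, ("age", "sex", "dbp")).to_numpy()
        beta, se = cluster_robust_ols(x, y[keep], al["pair_id"].to_numpy())
        res = sm.GEE(
            y[keep],
            x,
            groups=al["pair_id"].to_numpy(),
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Independence(),
        ).fit()
        np.testing.assert_allclose(beta, res.params, atol=1e-8)
        np.testing.assert_allclose(se, res.bse, rtol=1e-6)


class TestScan:
    def test_null_type_one_error_near_nominal(self, small_mvalues):
        mv, ph, truth = small_mvalues
        nulls = np.flatnonzero(truth.scenario == "null")
        res = ewas_scan(mv.subset_sites(nulls), ph, ("age", "sex", "dbp"))
        ps = np.array([r.p for r in res])
        assert np.nanmean(ps < 0.05) < 0.20  # small panel: loose binomial bound

    def test_causal_site_ranks_high(self, small_mvalues):
        mv, ph, truth = small_mvalues
        res = ewas_scan(mv, ph, ("age", "sex", "dbp"))
        ps = np.array([r.p for r in res])
        causal = np.flatnonzero(truth.scenario == "causal_y_to_m")[0]
        assert (np.nansum(ps < ps[causal])) <= 2

    def test_zero_variance_covariate_dropped(self, small_mvalues):
        mv, ph, _ = small_mvalues
        from twinmeth import TwinPhenotypeTable

        smoke_free = ph.data.copy()
        smoke_free["smoking"] = "never"
        smoke_free["drinking"] = "never"
        ph2 = TwinPhenotypeTable(smoke_free)
        base = ewas_scan(mv, ph2, ("age", "sex", "dbp"))
        extended = ewas_scan(mv, ph2, ("age", "sex", "dbp", "smoking", "drinking"))
        np.testing.assert_allclose(
            [r.p for r in base], [r.p for r in extended], atol=1e-12
        )

    def test_q_values_filled_in_input_order(self, small_mvalues):
        mv, ph, _ = small_mvalues
        res = ewas_scan(mv, ph, ("age", "sex", "dbp"))
        assert [r.site.site_id for r in res] == mv.site_ids
        ps = np.array([r.p for r in res])
        qs = np.array([r.q for r in res])
        ok = ~np.isnan(ps)
        np.testing.assert_allclose(qs[ok], bh_fdr(ps[ok]), atol=1e-12)


class TestBhFdr:
    def test_worked_example(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.04])
        np.testing.assert_allclose(q, [0.004, 0.02, 0.0266667, 0.04], atol=1e-6)

    def test_degenerate_inputs(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            q = bh_fdr(p)
            m = len(p)
            order = np.argsort(p, kind="stable")
            ranks = np.empty(m, int)
            ranks[order] = np.arange(1, m + 1)
            brute = np.array(
                [min(min(m * pj / rj for pj, rj in zip(p, ranks) if pj >= pi), 1.0) for pi in p]
            )
            np.testing.assert_allclose(q, brute, atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0, 1, 200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestNearestGene:
    genes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [100, 500, 10],
            "end": [200, 600, 20],
            "gene": ["BBB", "AAA", "CCC"],
        }
    )

    def test_inside_outside_and_ties(self):
        sites = [CpGSite("chr1", 150), CpGSite("chr1", 350), CpGSite("chr1", 800)]
        out = annotate_nearest_gene(sites, self.genes)
        assert out[0] == ("BBB", 0)
        # 350 is equidistant (150 bp) from BBB's end and AAA's start
        assert out[1] == ("AAA", 150)
        assert out[2] == ("AAA", 200)

    def test_unannotated_chromosome(self):
        out = annotate_nearest_gene([CpGSite("chrX", 5)], self.genes)
        assert out[0] == (None, None)
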