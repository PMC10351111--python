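import numpy as np
import pandas as pd
import pytest

from twinmeth import (
    ScenarioSpec,
    TwinPhenotypeTable,
    ValidationError,
    beta_matrix_to_m,
    classify_printed_rows,
    datasets,
    fit_direction_models,
    simulate_twin_cohort,
    summarize_causal_counts,
)
from twinmeth.icefalcon import (
    IceFalconRecord,
    _SiteData,
    analyze_site,
    bootstrap_changes,
    classify_direction,
    direction_is_causal,
)


@pytest.fixture(scope="module")
def scenario_cohort():
    spec = ScenarioSpec(
        n_pairs=2000,
        n_sites=3,
        scenarios=("confounded", "causal_m_to_y", "causal_y_to_m"),
        seed=9,
        informative_frac=0.0,
        missing_rate=0.0,
        effect_size=0.8,
    )
    matrix, ph, truth = simulate_twin_cohort(spec)
    return beta_matrix_to_m(matrix), ph, truth


class TestDirectionModels:
    def test_pure_confounding_gives_ratio_near_one(self, scenario_cohort):
        mv, ph, truth = scenario_cohort
        i = list(truth.scenario).index("confounded")
        data = _SiteData(mv.m[i], ph, "meth_to_fpg", ("age", "sex", "dbp"), None, mv.sample_ids)
        _, _, ratio, ex = bootstrap_changes(data, B=200, seed=1)
        assert ex["beta_cotwin"] == pytest.approx(ex["beta_self"], rel=0.35)
        assert abs(ratio) == pytest.approx(1.0, abs=0.4)

    def test_true_causation_attenuates_cotwin_coefficient(self, scenario_cohort):
        mv, ph, truth = scenario_cohort
        i = list(truth.scenario).index("causal_m_to_y")
        b_self, b_cotwin, b_self_adj, b_cotwin_adj = fit_direction_models(
            mv.m[i], ph, "meth_to_fpg", sample_ids=mv.sample_ids
        )
        assert abs(b_cotwin_adj) < abs(b_cotwin)
        data = _SiteData(mv.m[i], ph, "meth_to_fpg", ("age", "sex", "dbp"), None, mv.sample_ids)
        _, p_cotwin, ratio, _ = bootstrap_changes(data, B=200, seed=2)
        assert abs(ratio) > 1.5 and p_cotwin < 0.05

    def test_degenerate_identical_predictor_errors(self, tiny_phenotypes):
        m = np.array([0.5, 0.5, 1.2, 1.2])  # identical within every pair
        with pytest.raises(ValidationError, match="informative pairs"):
            fit_direction_models(m, tiny_phenotypes, "meth_to_fpg", covariates=())

    def test_invariant_to_twin_order(self, scenario_cohort):
        mv, ph, _ = scenario_cohort
        ref = fit_direction_models(mv.m[0], ph, "meth_to_fpg", sample_ids=mv.sample_ids)
        flipped = ph.data.copy()
        flipped["twin_index"] = flipped["twin_index"].map({1: 2, 2: 1})
        alt = fit_direction_models(
            mv.m[0],
            TwinPhenotypeTable(flipped),
            "meth_to_fpg",
            sample_ids=mv.sample_ids,
        )
        np.testing.assert_allclose(ref, alt, atol=1e-10)


class TestBootstrap:
    def test_requires_minimum_replicates(self, scenario_cohort):
        mv, ph, _ = scenario_cohort
        data = _SiteData(mv.m[0], ph, "meth_to_fpg", (), None, mv.sample_ids)
        with pytest.raises(ValidationError):
            bootstrap_changes(data, B=50)

    def test_ratio_uses_observed_changes(self, scenario_cohort):
        mv, ph, _ = scenario_cohort
        data = _SiteData(mv.m[1], ph, "meth_to_fpg", (), None, mv.sample_ids)
        _, _, ratio, ex = bootstrap_changes(data, B=150, seed=3)
        assert ratio == pytest.approx(
            ex["beta_cotwin_change"] / ex["beta_self_change"], abs=1e-12
        )


class TestClassification:
    def test_printed_ratio_arithmetic(self):
        rows = datasets.causal_inference_rows()
        # where the 3-decimal change columns determine the ratio, recomputing
        # it reproduces the printed magnitude
        r22 = rows.iloc[21]
        assert abs(r22["m2f_cotwin_change"] / r22["m2f_self_change"]) == pytest.approx(
            abs(r22["m2f_ratio"]), abs=0.01
        )
        r30 = rows.iloc[29]
        assert abs(r30["m2f_cotwin_change"] / r30["m2f_self_change"]) == pytest.approx(
            abs(r30["m2f_ratio"]), abs=0.01
        )

    def test_strict_threshold_boundary(self):
        assert not direction_is_causal(1.5, 0.001)
        assert direction_is_causal(1.51, 0.001)
        assert direction_is_causal(-1.51, 0.001)
        assert not direction_is_causal(10.0, 0.06)
        assert not direction_is_causal(np.nan, 0.001)

    def test_published_rows_reproduce_footnote_flags(self):
        rows = classify_printed_rows(datasets.causal_inference_rows())
        pd.testing.assert_series_equal(
            rows["call_meth_to_fpg"],
            rows["flag_meth_to_fpg"].astype(bool),
            check_names=False,
        )
        pd.testing.assert_series_equal(
            rows["call_fpg_to_meth"],
            rows["flag_fpg_to_meth"].astype(bool),
            check_names=False,
        )
        assert rows["call_meth_to_fpg"].sum() == 15
        assert rows["call_fpg_to_meth"].sum() == 12

    def test_label_combination_rules(self):
        def rec(ratio, p):
            from twinmeth import CpGSite

            return IceFalconRecord(
                CpGSite("chr1", 1), "x", 0, 0, 0, 0, 0, 0, 1.0, p, ratio
            )

        assert classify_direction(rec(2.0, 0.01), rec(2.0, 0.01)) == "bidirectional"
        assert classify_direction(rec(2.0, 0.01), rec(1.2, 0.01)) == "meth_to_fpg_only"
        assert classify_direction(rec(1.0, 0.5), rec(-2.0, 0.01)) == "fpg_to_meth_only"
        assert classify_direction(rec(1.0, 0.5), rec(8.0, 0.5)) == "none"

    def test_summarize_counts_partitions(self):
        labels = ["bidirectional"] * 7 + ["meth_to_fpg_only"] * 8 + [
            "fpg_to_meth_only"
        ] * 5 + ["none"] * 10
        counts = summarize_causal_counts(labels)
        assert counts == {
            "bidirectional": 7,
            "meth_to_fpg_only": 8,
            "fpg_to_meth_only": 5,
            "none": 10,
        }
        assert sum(counts.values()) == 30
        with pytest.raises(ValidationError):
            summarize_causal_counts(["nonsense"])


def test_analyze_site_end_to_end(scenario_cohort):
    mv, ph, truth = scenario_cohort
    i = list(truth.scenario).index("causal_m_to_y")
    r1, r2, label = analyze_site(
        mv.m[i], mv.sites[i], ph, B=150, seed=5, sample_ids=mv.sample_ids
    )
    assert r1.direction == "meth_to_fpg" and r2.direction == "fpg_to_meth"
    assert r1.causal_flag  # the true direction must be flagged
    assert r1.beta_self_change == pytest.approx(
        r1.beta_self - r1.beta_self_adj, abs=1e-12
    )
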