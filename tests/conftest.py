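import numpy as np
import pandas as pd
import pytest

from twinmeth import (
    CpGSite,
    MethylationMatrix,
    ScenarioSpec,
    TwinPhenotypeTable,
    beta_matrix_to_m,
    simulate_twin_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """52-pair cohort with mixed scenarios, session-cached for speed."""
    scenarios = ["null"] * 60
    scenarios[10] = "confounded"
    scenarios[20] = "causal_m_to_y"
    scenarios[30] = "causal_y_to_m"
    spec = ScenarioSpec(
        n_pairs=52, n_sites=60, scenarios=tuple(scenarios), seed=42, effect_size=0.8
    )
    return simulate_twin_cohort(spec)


@pytest.fixture(scope="session")
def small_mvalues(small_cohort):
    matrix, ph, truth = small_cohort
    return beta_matrix_to_m(matrix), ph, truth


@pytest.fixture
def tiny_matrix():
    sites = [CpGSite("chr1", 100), CpGSite("chr1", 200), CpGSite("chr2", 50)]
    beta = np.array([[0.1, 0.2], [0.5, np.nan], [0.9, 0.8]])
    cov = np.array([[10.0, 20.0], [5.0, np.nan], [7.0, 30.0]])
    return MethylationMatrix(
        sites=sites, beta=beta, sample_ids=["s1", "s2"], coverage=cov
    )


@pytest.fixture
def tiny_phenotypes():
    rows = []
    for i, (f1, f2) in enumerate([(5.0, 5.5), (4.8, 6.0)], start=1):
        for t, f in ((1, f1), (2, f2)):
            rows.append(
                {
                    "individual_id": f"p{i}_t{t}",
                    "pair_id": f"p{i}",
                    "twin_index": t,
                    "fpg": f,
                    "age": 50 + i,
                    "sex": "female",
                    "dbp": 80.0,
                    "smoking": "never",
                    "drinking": "never",
                }
            )
    return TwinPhenotypeTable(pd.DataFrame(rows))
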