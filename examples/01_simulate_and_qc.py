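"""Simulate a 52-pair MZ twin cohort and run the site-level quality control.

Prints the cohort dimensions, the inclusion-rule check, and how many CpGs
survive the QC filters (mean beta >= 0.05, at most 10 missing observations),
then converts the retained beta values to the M scale used for regression.
"""

import numpy as np

from twinmeth import (
    ScenarioSpec,
    beta_matrix_to_m,
    cap_coverage,
    filter_sites,
    select_discordant_pairs,
    simulate_twin_cohort,
)

spec = ScenarioSpec(n_pairs=52, n_sites=300, seed=1)
matrix, phenotypes, truth = simulate_twin_cohort(spec)
print(f"cohort: {matrix.n_sites} CpGs x {matrix.n_samples} individuals "
      f"({phenotypes.n_pairs} MZ pairs)")
print(f"smallest intra-pair |dFPG|: {phenotypes.pair_deltas('fpg').min():.3f} mmol/L "
      "(inclusion rule requires >= 0.1)")

matrix = cap_coverage(matrix, q=0.90)  # winsorize read depth at its 90% quantile
kept, removed = filter_sites(matrix, min_mean_beta=0.05, max_missing=10)
print(f"QC kept {kept.n_sites} sites; removed {len(removed)} "
      f"({dict(removed['reason'].value_counts())})")

phenotypes = select_discordant_pairs(phenotypes, min_delta=0.1)
mvalues = beta_matrix_to_m(kept)
print(f"M-value range: [{np.nanmin(mvalues.m):.2f}, {np.nanmax(mvalues.m):.2f}] "
      "(M = log2(beta/(1-beta)))")
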