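"""Synthetic monozygotic twin cohorts with known ground truth.

The generator emulates the structure of a blood RRBS methylation study on MZ
twins: a familial factor shared within each pair drives the intra-pair
fasting-plasma-glucose correlation (default 0.68, the FPG heritability
reported for Chinese twins), cohort inclusion requires an intra-pair FPG
difference of at least 0.1 mmol/L, observed beta values mix cell-type
reference profiles for a fraction of "informative" sites, and every CpG is
assigned one of four ground-truth scenarios:

* ``null`` - familially correlated methylation, independent of FPG;
* ``confounded`` - methylation loads on the same familial factor as FPG
  (association without causation);
* ``causal_m_to_y`` - methylation shifts FPG;
* ``causal_y_to_m`` - FPG shifts methylation.

Because genetic and shared-environment effects are inseparable within MZ
pairs they are merged into a single familial factor per pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CpGSite,
    MethylationMatrix,
    TwinPhenotypeTable,
    ValidationError,
)
from .preprocess import m_to_beta

logger = logging.getLogger("twinmeth")

__all__ = [
    "ScenarioSpec",
    "SyntheticTruth",
    "simulate_twin_cohort",
    "simulate_null_pvalue_track",
    "power_curve",
    "simulate_case_control",
]

SCENARIOS = ("null", "confounded", "causal_m_to_y", "causal_y_to_m")


@dataclass
class ScenarioSpec:
    """Study conditions for one simulated cohort.

    Defaults mirror the emulated study: 52 MZ pairs (27 male pairs), target
    intra-pair FPG correlation 0.68, inclusion threshold |dFPG| >= 0.1
    mmol/L, FPG median 5.44 mmol/L, mean age 52 (SD 7). Effect sizes act on
    the latent (standardized) scale: ``effect_size`` is the causal loading
    for both causal scenarios and ``familial_loading`` the familial loading
    of methylation.
    """

    n_pairs: int = 52
    n_sites: int = 200
    scenarios: tuple | str = "null"  # one label, or one per site
    effect_size: float = 0.5
    familial_loading: float = 0.7
    r_target: float = 0.68
    n_cell_types: int = 3
    dirichlet_conc: float = 8.0
    informative_frac: float = 0.20
    beta_age: float = 0.01  # latent FPG units per standardized-age unit
    beta_sex: float = 0.1
    male_pair_frac: float = 27 / 52
    fpg_median: float = 5.44
    fpg_log_sd: float = 0.15
    min_fpg_delta: float = 0.1
    missing_rate: float = 0.02
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.r_target < 1.0):
            raise ValidationError(f"r_target must be in [0, 1), got {self.r_target}")
        if self.n_cell_types < 2:
            raise ValidationError("n_cell_types must be >= 2")
        if self.n_pairs < 1 or self.n_sites < 1:
            raise ValidationError("n_pairs and n_sites must be positive")
        if isinstance(self.scenarios, str):
            if self.scenarios not in SCENARIOS:
                raise ValidationError(f"unknown scenario {self.scenarios!r}")
        else:
            self.scenarios = tuple(self.scenarios)
            if len(self.scenarios) != self.n_sites:
                raise ValidationError("need one scenario label per site")
            bad = set(self.scenarios) - set(SCENARIOS)
            if bad:
                raise ValidationError(f"unknown scenario labels {bad}")

    def scenario_labels(self) -> np.ndarray:
        if isinstance(self.scenarios, str):
            return np.array([self.scenarios] * self.n_sites)
        return np.array(self.scenarios)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated cohort."""

    scenario: np.ndarray  # per site
    effect_size: np.ndarray  # per site
    informative: np.ndarray  # per site bool: dominated by cell mixing
    cell_props: np.ndarray  # samples x K, rows sum to 1
    familial_factor: np.ndarray  # per pair
    latent_fpg: np.ndarray  # per sample, standardized latent scale
    seed: int = 0


def _calibrated_rho(spec: ScenarioSpec) -> float:
    """Latent correlation that yields r_target after inclusion filtering.

    Conditioning on |dFPG| >= min_fpg_delta removes the most concordant
    pairs and so deflates the realized intra-pair correlation below the
    latent one. Because r_target is defined as the realized correlation, the
    latent input is raised to compensate, by bisection against a pilot
    Monte-Carlo of the FPG model (common random numbers make the objective
    smooth and monotone). The pilot uses the null backbone; causal scenario
    effects add on top of it.
    """
    return _calibrated_rho_cached(
        spec.r_target,
        spec.fpg_median,
        spec.fpg_log_sd,
        spec.min_fpg_delta,
        spec.beta_age,
        spec.beta_sex,
        spec.male_pair_frac,
    )


@lru_cache(maxsize=64)
def _calibrated_rho_cached(
    r_target, fpg_median, fpg_log_sd, min_fpg_delta, beta_age, beta_sex, male_pair_frac
) -> float:
    # the calibration is a deterministic numerical solve: it uses its own
    # fixed random stream, not the cohort seed
    n_pilot = 100000
    rng = np.random.default_rng(0x5EED)
    f = rng.normal(size=n_pilot)
    eps = rng.normal(size=(n_pilot, 2))
    age_std = (np.clip(rng.normal(52.0, 7.0, n_pilot), 25.0, 80.0) - 52.0) / 7.0
    sex = (rng.random(n_pilot) < male_pair_frac).astype(float)
    shift = beta_age * age_std + beta_sex * sex

    def realized(rho: float) -> float:
        lat = np.sqrt(rho) * f[:, None] + np.sqrt(1.0 - rho) * eps + shift[:, None]
        fpg = fpg_median * np.exp(fpg_log_sd * lat)
        keep = np.abs(fpg[:, 0] - fpg[:, 1]) >= min_fpg_delta
        if keep.sum() < 100:
            return 1.0
        return float(np.corrcoef(fpg[keep, 0], fpg[keep, 1])[0, 1])

    lo, hi = r_target, min(0.999, r_target + 0.3)
    if realized(lo) >= r_target:
        return lo
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if realized(mid) < r_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_pair_category(rng, n, p_both, p_neither):
    """Pair-level never/ever habits: both, neither, or discordant."""
    cat = rng.choice(3, size=n, p=[p_both, p_neither, 1 - p_both - p_neither])
    twin1 = np.where(cat == 0, 1, np.where(cat == 1, 0, rng.integers(0, 2, n)))
    twin2 = np.where(cat == 0, 1, np.where(cat == 1, 0, 1 - twin1))
    return twin1, twin2


def simulate_twin_cohort(
    spec: ScenarioSpec,
) -> tuple[MethylationMatrix, TwinPhenotypeTable, SyntheticTruth]:
    """Generate (methylation matrix, phenotypes, ground truth) for one cohort.

    Pairs whose final |FPG difference| falls below the inclusion threshold are
    redrawn (rejection sampling over the FPG-determining randomness), so the
    returned cohort honors the inclusion rule exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n_pairs, n_sites = spec.n_pairs, spec.n_sites
    n = 2 * n_pairs
    labels = spec.scenario_labels()

    # --- pair-level phenotypes -------------------------------------------
    age_pair = np.clip(rng.normal(52.0, 7.0, n_pairs), 25.0, 80.0)
    male_pair = rng.random(n_pairs) < spec.male_pair_frac
    smoking1, smoking2 = _draw_pair_category(rng, n_pairs, 19 / 52, 28 / 52)
    drinking1, drinking2 = _draw_pair_category(rng, n_pairs, 17 / 52, 32 / 52)
    dbp = rng.normal(78.0, 10.0, n)  # essentially uncorrelated within pairs

    age_std = (age_pair - 52.0) / 7.0
    sex_num = male_pair.astype(float)

    # --- FPG and causal-site latents with rejection on |dFPG| ------------
    r = _calibrated_rho(spec) if spec.min_fpg_delta > 0 else spec.r_target
    causal_my = np.flatnonzero(labels == "causal_m_to_y")
    gamma = spec.familial_loading
    m_scale = np.sqrt(1.0 + gamma**2)

    familial = np.empty(n_pairs)
    latent = np.empty((n_pairs, 2))
    m_causal = np.empty((n_pairs, 2, len(causal_my)))
    pending = np.arange(n_pairs)
    for _ in range(1000):
        k = len(pending)
        f = rng.normal(size=k)
        eps = rng.normal(size=(k, 2))
        lat = np.sqrt(r) * f[:, None] + np.sqrt(1.0 - r) * eps
        lat = lat + (spec.beta_age * age_std[pending] + spec.beta_sex * sex_num[pending])[:, None]
        g_site = rng.normal(size=(k, 1, len(causal_my)))
        e_site = rng.normal(size=(k, 2, len(causal_my)))
        mc = (gamma * g_site + e_site) / m_scale
        lat = lat + spec.effect_size * mc.sum(axis=2)
        fpg_try = spec.fpg_median * np.exp(spec.fpg_log_sd * lat)
        ok = np.abs(fpg_try[:, 0] - fpg_try[:, 1]) >= spec.min_fpg_delta
        sel = pending[ok]
        familial[sel] = f[ok]
        latent[sel] = lat[ok]
        m_causal[sel] = mc[ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
    else:
        raise ValidationError("rejection sampling failed to satisfy the FPG rule")

    fpg = spec.fpg_median * np.exp(spec.fpg_log_sd * latent)  # (n_pairs, 2)
    latent_flat = latent.ravel()  # sample order: pair-major, twin 1 then 2

    # --- per-site latent methylation -------------------------------------
    m_latent = np.empty((n_sites, n))
    eff = np.zeros(n_sites)
    g_shared = rng.normal(size=(n_pairs, n_sites))
    noise = rng.normal(size=(n_pairs, 2, n_sites))
    base = (gamma * g_shared[:, None, :] + noise) / m_scale  # familial + unique
    ci = 0
    for s, lab in enumerate(labels):
        if lab == "causal_m_to_y":
            vals = m_causal[:, :, ci]
            ci += 1
            eff[s] = spec.effect_size
        elif lab == "confounded":
            vals = (gamma * familial[:, None] + noise[:, :, s]) / m_scale
            eff[s] = gamma
        elif lab == "causal_y_to_m":
            vals = base[:, :, s] + spec.effect_size * latent
            eff[s] = spec.effect_size
        else:
            vals = base[:, :, s]
        m_latent[s] = vals.reshape(-1)

    # --- cell mixing and observed beta ------------------------------------
    k_types = spec.n_cell_types
    base_props = np.linspace(1.0, 2.0, k_types)
    base_props /= base_props.sum()
    cell_props = rng.dirichlet(spec.dirichlet_conc * base_props, size=n)

    informative = np.zeros(n_sites, dtype=bool)
    null_sites = np.flatnonzero(labels == "null")
    n_inf = int(round(spec.informative_frac * n_sites))
    if n_inf > len(null_sites):
        raise ValidationError(
            "informative_frac too high: cell-informative sites must be scenario-null"
        )
    informative[rng.choice(null_sites, size=n_inf, replace=False)] = True

    beta = np.empty((n_sites, n))
    # reference profiles: type-specific means spread over (0.15, 0.85)
    type_means = np.linspace(0.2, 0.8, k_types)
    m0 = rng.uniform(-2.5, 2.5, n_sites)  # site baseline on the M scale
    for s in range(n_sites):
        if informative[s]:
            ref = rng.beta(type_means * 12.0, (1.0 - type_means) * 12.0)
            vals = cell_props @ ref + rng.normal(0.0, 0.02, n)
        else:
            vals = m_to_beta(m0[s] + 1.2 * m_latent[s]) + rng.normal(0.0, 0.01, n)
        beta[s] = np.clip(vals, 0.0, 1.0)

    # --- coverage and missingness -----------------------------------------
    disp = spec.coverage_dispersion
    p_nb = disp / (disp + spec.coverage_mean)
    coverage = rng.negative_binomial(disp, p_nb, size=(n_sites, n)).astype(float) + 1.0
    if spec.missing_rate > 0:
        miss = rng.random((n_sites, n)) < spec.missing_rate
        beta[miss] = np.nan
        coverage[miss] = np.nan

    # --- containers --------------------------------------------------------
    positions = np.sort(rng.choice(np.arange(1, 120 * n_sites + 1), n_sites, replace=False))
    sites = [CpGSite("chr1", int(p)) for p in positions]
    sample_ids = [f"p{i + 1:04d}_t{t}" for i in range(n_pairs) for t in (1, 2)]
    matrix = MethylationMatrix(
        sites=sites, beta=beta, sample_ids=sample_ids, coverage=coverage
    )
    rows = []
    for i in range(n_pairs):
        for t in (1, 2):
            rows.append(
                {
                    "individual_id": sample_ids[2 * i + t - 1],
                    "pair_id": f"p{i + 1:04d}",
                    "twin_index": t,
                    "fpg": fpg[i, t - 1],
                    "age": age_pair[i],
                    "sex": "male" if male_pair[i] else "female",
                    "dbp": dbp[2 * i + t - 1],
                    "smoking": "ever" if (smoking1[i] if t == 1 else smoking2[i]) else "never",
                    "drinking": "ever" if (drinking1[i] if t == 1 else drinking2[i]) else "never",
                }
            )
    ph = TwinPhenotypeTable(pd.DataFrame(rows))
    truth = SyntheticTruth(
        scenario=labels,
        effect_size=eff,
        informative=informative,
        cell_props=cell_props,
        familial_factor=familial,
        latent_fpg=latent_flat,
        seed=spec.seed,
    )
    return matrix, ph, truth


def simulate_null_pvalue_track(
    n_sites: int,
    mean_spacing: float = 100.0,
    ac_range=None,
    seed: int = 0,
    max_support: int = 1000,
) -> tuple[list[CpGSite], np.ndarray]:
    """Uniform p-values with distance-decaying neighbor correlation.

    Positions follow cumulative exponential spacings (rounded up to >= 1 bp);
    ``ac_range`` maps a bp distance to a correlation in [0, 1), nonincreasing
    (``None`` means independent sites). z-scores are drawn from the banded
    Gaussian covariance implied by ``ac_range`` (a Gaussian copula on the p
    scale), then mapped through the normal survival function, so each p is
    marginally uniform.
    """
    if n_sites < 1:
        raise ValidationError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    gaps = np.maximum(1, np.ceil(rng.exponential(mean_spacing, n_sites)).astype(int))
    pos = np.cumsum(gaps)
    sites = [CpGSite("chr1", int(p)) for p in pos]

    if ac_range is None:
        z = rng.normal(size=n_sites)
    else:
        probe = ac_range(np.arange(1, max_support + 1))
        probe = np.asarray(probe, dtype=float)
        if np.any(probe < 0) or np.any(probe >= 1):
            raise ValidationError("ac_range must take values in [0, 1)")
        if np.any(np.diff(probe) > 1e-12):
            raise ValidationError("ac_range must be nonincreasing in distance")
        z = _correlated_normals(pos, ac_range, max_support, rng)
    p = stats.norm.sf(z)
    return sites, p


def _correlated_normals(pos, ac_range, max_support, rng) -> np.ndarray:
    """Sample N(0, Sigma) for Sigma_ij = ac_range(|pos_i - pos_j|).

    Sites further apart than the correlation support are independent, so the
    covariance is block diagonal over runs of closely spaced sites; each
    block is sampled through its eigendecomposition. Marginally PSD blocks
    (e.g. hard-threshold correlation functions) are handled by clipping
    negative eigenvalues at zero and rescaling rows back to unit marginal
    variance, which leaves p-values uniform and neighbor correlations
    essentially untouched.
    """
    n = len(pos)
    probe = np.asarray(ac_range(np.arange(1, max_support + 1)), dtype=float)
    nz = np.flatnonzero(probe > 1e-12)
    if nz.size == 0:
        return rng.normal(size=n)
    support = int(nz[-1] + 1)
    z = np.empty(n)
    gaps = np.diff(pos)
    breaks = np.concatenate([[0], np.flatnonzero(gaps > support) + 1, [n]])
    for a, b in zip(breaks[:-1], breaks[1:]):
        k = b - a
        if k == 1:
            z[a] = rng.normal()
            continue
        d = np.abs(pos[a:b, None] - pos[None, a:b])
        sigma = np.where((d > 0) & (d <= support), ac_range(np.maximum(d, 1)), 0.0)
        np.fill_diagonal(sigma, 1.0)
        w, v = np.linalg.eigh(sigma)
        factor = v * np.sqrt(np.clip(w, 0.0, None))
        norms = np.linalg.norm(factor, axis=1)
        factor /= np.where(norms > 0, norms, 1.0)[:, None]
        z[a:b] = factor @ rng.normal(size=k)
    return z


def power_curve(
    grid,
    alpha: float = 0.05,
    reps: int = 200,
    seed: int = 0,
    base_spec: ScenarioSpec | None = None,
    working: str = "exchangeable",
) -> pd.DataFrame:
    """Empirical power of the per-CpG association test over a design grid.

    ``grid`` is an iterable of (n_pairs, effect_size). Each replicate
    simulates a cohort with a single methylation-to-FPG causal site and
    tests it at level ``alpha``; power is the passing fraction. Covariates
    (age, sex, DBP) ride along as in the main analysis.
    """
    from .ewas import fit_gee_cpg
    from .preprocess import beta_matrix_to_m

    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for n_pairs, effect in grid:
        hits = 0
        for _ in range(reps):
            spec_kwargs = {} if base_spec is None else dict(base_spec.__dict__)
            spec_kwargs.update(
                n_pairs=int(n_pairs),
                n_sites=1,
                scenarios=("causal_m_to_y",),
                effect_size=float(effect),
                informative_frac=0.0,
                missing_rate=0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            matrix, ph, _ = simulate_twin_cohort(ScenarioSpec(**spec_kwargs))
            mv = beta_matrix_to_m(matrix)
            _, _, p = fit_gee_cpg(
                mv.m[0], ph, ("age", "sex", "dbp"), working=working,
                sample_ids=mv.sample_ids,
            )
            hits += p < alpha
        rows.append(
            {
                "n_pairs": int(n_pairs),
                "effect_size": float(effect),
                "reps": reps,
                "power": hits / reps,
            }
        )
    return pd.DataFrame(rows)


def simulate_case_control(
    n_cases: int = 72,
    n_controls: int = 170,
    n_cpgs: int = 3,
    meth_shift: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Case-control validation-arm data: per-subject methylation fractions
    plus lipid covariates (CHOL, TG, LDLC in mmol/L).

    ``meth_shift`` is the case-minus-control difference in methylation
    fraction (0 gives a null dataset). Defaults mirror the emulated
    validation arm: 72 diabetic cases, 170 controls.
    """
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    group = np.array(["case"] * n_cases + ["control"] * n_controls)
    is_case = group == "case"
    df = pd.DataFrame({"subject_id": [f"s{i + 1:04d}" for i in range(n)], "group": group})
    df["chol"] = rng.normal(4.8, 0.9, n) + 0.4 * is_case
    df["tg"] = np.exp(rng.normal(0.3, 0.4, n)) + 0.3 * is_case
    df["ldlc"] = rng.normal(2.9, 0.8, n) - 0.2 * is_case
    for j in range(n_cpgs):
        base = rng.uniform(0.3, 0.6)
        vals = rng.normal(base, 0.08, n) + meth_shift * is_case
        df[f"cpg{j + 1}"] = np.clip(vals, 0.0, 1.0)
    return df
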