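"""Per-CpG association scan with twin-pair clustering.

Each CpG's M-value is regressed on fasting plasma glucose with age, sex,
diastolic blood pressure and cell-composition surrogates as covariates.
Twins within a pair are correlated, so coefficients come from generalized
estimating equations with the pair as the cluster and a robust (sandwich)
covariance; genome-wide multiplicity is handled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .celltype import CellTypeComponents
from .core import CpGSite, MValueMatrix, TwinPhenotypeTable, ValidationError

logger = logging.getLogger("twinmeth")

__all__ = [
    "EwasResult",
    "fit_gee_cpg",
    "ewas_scan",
    "bh_fdr",
    "annotate_nearest_gene",
    "cluster_robust_ols",
    "build_design",
]

SEX_CODES = {"female": 0.0, "male": 1.0}
BINARY_CODES = {"never": 0.0, "ever": 1.0}


def cluster_robust_ols(
    x: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """OLS point estimates with a cluster-robust sandwich covariance.

    Identical point estimates to a Gaussian GEE with independence working
    correlation; returns (coefficients, robust standard errors).
    """
    xtx = x.T @ x
    if np.linalg.matrix_rank(xtx) < x.shape[1]:
        raise ValidationError("singular design matrix")
    a = np.linalg.inv(xtx)
    beta = a @ (x.T @ y)
    resid = y - x @ beta
    meat = np.zeros_like(xtx)
    for g in np.unique(groups):
        idx = groups == g
        s = x[idx].T @ resid[idx]
        meat += np.outer(s, s)
    cov = a @ meat @ a
    return beta, np.sqrt(np.diag(cov))


def build_design(
    ph_aligned: pd.DataFrame,
    covariates: tuple = ("age", "sex", "dbp"),
    celltype: CellTypeComponents | None = None,
) -> pd.DataFrame:
    """Design matrix: intercept, fpg, requested covariates, cell components.

    Sex is coded female=0/male=1 and smoking/drinking never=0/ever=1.
    Zero-variance covariates are dropped with a warning (e.g. smoking in a
    smoke-free cohort) so that sensitivity analyses degrade gracefully.
    """
    cols = {"const": np.ones(len(ph_aligned)), "fpg": ph_aligned["fpg"].to_numpy(float)}
    for cov in covariates:
        if cov == "sex":
            v = ph_aligned["sex"].map(SEX_CODES).to_numpy(float)
        elif cov in ("smoking", "drinking"):
            v = ph_aligned[cov].map(BINARY_CODES).to_numpy(float)
        elif cov in ph_aligned.columns:
            v = ph_aligned[cov].to_numpy(float)
        else:
            raise ValidationError(f"unknown covariate {cov!r}")
        if np.ptp(v) == 0:
            logger.warning("covariate %r has zero variance; dropped", cov)
            continue
        cols[cov] = v
    if celltype is not None:
        if list(celltype.sample_ids) != list(ph_aligned["individual_id"]):
            raise ValidationError("cell-type component samples do not match phenotypes")
        for j in range(celltype.d):
            cols[f"ct{j + 1}"] = celltype.scores[:, j]
    return pd.DataFrame(cols, index=ph_aligned["individual_id"])


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-10 if diag.size else 0.0
    return [names[i] for i in np.flatnonzero(diag <= tol)]


def fit_gee_cpg(
    mv_site: np.ndarray,
    ph: TwinPhenotypeTable,
    covariates: tuple = ("age", "sex", "dbp"),
    celltype: CellTypeComponents | None = None,
    working: str = "exchangeable",
    sample_ids: list[str] | None = None,
    min_pairs: int = 10,
) -> tuple[float, float, float]:
    """Fit M ~ FPG + covariates with pair clusters; return (coef, se, p).

    The returned coefficient is the FPG term in M-units per mmol/L, its
    standard error is cluster-robust, and the p-value uses the two-sided
    normal approximation to the robust z statistic. Samples with missing
    methylation are dropped; at least ``min_pairs`` complete pairs must
    remain.
    """
    ids = sample_ids if sample_ids is not None else ph.individual_ids
    aligned = ph.aligned_to(ids)
    y = np.asarray(mv_site, dtype=float)
    keep = ~np.isnan(y)
    aligned = aligned[keep].reset_index(drop=True)
    y = y[keep]
    counts = aligned.groupby("pair_id").size()
    complete = counts[counts == 2]
    if len(complete) < min_pairs:
        raise ValidationError(
            f"only {len(complete)} complete pairs after missing-data removal "
            f"(need >= {min_pairs})"
        )
    design = build_design(aligned, covariates, celltype=_subset_ct(celltype, keep))
    x = design.to_numpy()
    names = list(design.columns)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError(f"collinear design columns: {_collinear_columns(x, names)}")
    groups = aligned["pair_id"].to_numpy()

    if working == "independence":
        beta, se = cluster_robust_ols(x, y, groups)
        j = names.index("fpg")
        coef, se_f = beta[j], se[j]
    elif working == "exchangeable":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(
                y,
                x,
                groups=groups,
                family=sm.families.Gaussian(),
                cov_struct=sm.cov_struct.Exchangeable(),
            )
            res = model.fit()
        j = names.index("fpg")
        coef, se_f = res.params[j], res.bse[j]
        if not (np.isfinite(coef) and np.isfinite(se_f)):
            # degenerate fits (e.g. zero residual variance) break the
            # exchangeable moment estimator; independence gives the same
            # point estimate there
            beta, se = cluster_robust_ols(x, y, groups)
            coef, se_f = beta[j], se[j]
    else:
        raise ValidationError(f"unknown working correlation {working!r}")
    z = coef / se_f
    p = 2.0 * stats.norm.sf(abs(z))
    return float(coef), float(se_f), float(p)


def _subset_ct(celltype: CellTypeComponents | None, keep: np.ndarray):
    if celltype is None:
        return None
    return CellTypeComponents(
        scores=celltype.scores[keep],
        sample_ids=[s for s, k in zip(celltype.sample_ids, keep) if k],
        selected_sites=celltype.selected_sites,
        explained_variance_ratio=celltype.explained_variance_ratio,
    )


@dataclass
class EwasResult:
    """Association result for one CpG."""

    site: CpGSite
    beta_coef: float
    se: float
    p: float
    q: float
    gene: str | None = None


def ewas_scan(
    mv: MValueMatrix,
    ph: TwinPhenotypeTable,
    covariates: tuple = ("age", "sex", "dbp"),
    celltype: CellTypeComponents | None = None,
    working: str = "exchangeable",
    gene_table: pd.DataFrame | None = None,
) -> list[EwasResult]:
    """Run the per-CpG association over a whole matrix.

    Sites whose fit preconditions fail get NaN statistics with a logged
    reason; q-values are BH-FDR over the non-missing p-values. Output is in
    input site order.
    """
    stats_out = np.full((mv.n_sites, 3), np.nan)
    for i in range(mv.n_sites):
        try:
            stats_out[i] = fit_gee_cpg(
                mv.m[i],
                ph,
                covariates,
                celltype=celltype,
                working=working,
                sample_ids=mv.sample_ids,
            )
        except ValidationError as exc:
            logger.info("site %s skipped: %s", mv.sites[i].site_id, exc)
    fitted = ~np.isnan(stats_out[:, 2])
    if not fitted.any():
        raise ValidationError("no site could be fitted")
    q = np.full(mv.n_sites, np.nan)
    q[fitted] = bh_fdr(stats_out[fitted, 2])
    genes = (
        annotate_nearest_gene(mv.sites, gene_table)
        if gene_table is not None
        else [None] * mv.n_sites
    )
    return [
        EwasResult(
            site=mv.sites[i],
            beta_coef=stats_out[i, 0],
            se=stats_out[i, 1],
            p=stats_out[i, 2],
            q=q[i],
            gene=genes[i][0] if isinstance(genes[i], tuple) else genes[i],
        )
        for i in range(mv.n_sites)
    ]


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    q_i = min over p_j >= p_i of (m * p_j / rank_j), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def annotate_nearest_gene(
    sites: list[CpGSite], genes: pd.DataFrame
) -> list[tuple[str | None, int | None]]:
    """Nearest gene symbol and distance per site (distance 0 inside a gene).

    ``genes`` carries 1-based closed intervals (chrom, start, end, gene).
    Ties are broken by smaller distance, then lexicographically smaller
    symbol; sites on chromosomes absent from the annotation get (None, None)
    with a warning.
    """
    if genes is None or len(genes) == 0:
        raise ValidationError("gene annotation table is empty")
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    out: list[tuple[str | None, int | None]] = []
    warned = set()
    for s in sites:
        g = by_chrom.get(s.chrom)
        if g is None:
            if s.chrom not in warned:
                logger.warning("chromosome %s absent from gene annotation", s.chrom)
                warned.add(s.chrom)
            out.append((None, None))
            continue
        start = g["start"].to_numpy()
        end = g["end"].to_numpy()
        dist = np.maximum(0, np.maximum(start - s.pos, s.pos - end))
        best = np.lexsort((g["gene"].to_numpy(), dist))[0]
        out.append((str(g["gene"].iloc[best]), int(dist[best])))
    return out
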