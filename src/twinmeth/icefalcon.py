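"""Bidirectional causal inference within monozygotic twin pairs (ICE FALCON).

For an exposure-outcome pair measured on both members of MZ twin pairs,
three models are fitted per direction: the outcome on the individual's own
exposure (beta_self), on the co-twin's exposure (beta_cotwin), and on both
jointly (beta'_self, beta'_cotwin). Familial confounding moves both
coefficients similarly between marginal and joint fits, whereas a true
causal effect of the exposure attenuates the co-twin coefficient much more
than the self coefficient. The ratio of the co-twin change to the self
change, together with the significance of the co-twin change, drives the
causal call: |ratio| > 1.5 and p(co-twin change) < 0.05.

Each individual serves as "self" once, so results are invariant to the
within-pair twin ordering. Change significance comes from a pair-level
nonparametric bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .celltype import CellTypeComponents
from .core import CpGSite, MValueMatrix, TwinPhenotypeTable, ValidationError
from .ewas import build_design, cluster_robust_ols

logger = logging.getLogger("twinmeth")

__all__ = [
    "IceFalconRecord",
    "DIRECTIONS",
    "fit_direction_models",
    "bootstrap_changes",
    "analyze_site",
    "run_ice_falcon",
    "direction_is_causal",
    "classify_direction",
    "classify_printed_rows",
    "summarize_causal_counts",
]

DIRECTIONS = ("meth_to_fpg", "fpg_to_meth")
LABELS = ("bidirectional", "meth_to_fpg_only", "fpg_to_meth_only", "none")


@dataclass
class IceFalconRecord:
    """Three-model summary for one CpG and one direction."""

    site: CpGSite
    direction: str
    beta_self: float
    beta_cotwin: float
    beta_self_adj: float
    beta_cotwin_adj: float
    beta_self_change: float
    beta_cotwin_change: float
    p_self_change: float
    p_cotwin_change: float
    ratio: float  # signed; NaN when the self change is exactly zero
    causal_flag: bool = False


class _SiteData:
    """Row-per-individual arrays for one site, complete pairs only.

    ``exposure``/``outcome`` are the direction-resolved variables;
    ``exposure_co`` is the co-twin's exposure aligned to each row.
    """

    def __init__(
        self,
        mv_site: np.ndarray,
        ph: TwinPhenotypeTable,
        direction: str,
        covariates: tuple,
        celltype: CellTypeComponents | None,
        sample_ids: list[str],
    ):
        if direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {direction!r}")
        aligned = ph.aligned_to(sample_ids)
        meth = np.asarray(mv_site, dtype=float)
        ok = ~np.isnan(meth)
        aligned = aligned.assign(_meth=meth, _row=np.arange(len(aligned)))[ok]
        counts = aligned.groupby("pair_id").size()
        keep_pairs = set(counts[counts == 2].index)
        aligned = aligned[aligned["pair_id"].isin(keep_pairs)]
        if aligned.empty:
            raise ValidationError("no complete pairs for this site")
        aligned = aligned.sort_values(["pair_id", "twin_index"]).reset_index(drop=True)

        design = build_design(
            aligned,
            covariates,
            celltype=_ct_rows(celltype, aligned["_row"].to_numpy()),
        )
        cov = design.drop(columns=["fpg"]).to_numpy()  # const + covariates
        self.cov_names = [c for c in design.columns if c != "fpg"]
        fpg = aligned["fpg"].to_numpy(float)
        meth = aligned["_meth"].to_numpy(float)
        if direction == "meth_to_fpg":
            self.outcome, exposure = fpg, meth
        else:
            self.outcome, exposure = meth, fpg
        # co-twin's exposure: rows come in pair order (twin 1, twin 2)
        swap = np.arange(len(aligned)).reshape(-1, 2)[:, ::-1].ravel()
        self.exposure = exposure
        self.exposure_co = exposure[swap]
        self.cov = cov
        self.groups = aligned["pair_id"].to_numpy()
        self.n_pairs = len(aligned) // 2
        within = np.abs(np.diff(exposure.reshape(-1, 2), axis=1))
        if np.all(within < 1e-12):
            raise ValidationError(
                "no informative pairs: the predictor is identical within every pair"
            )

    def model_design(self, which: str) -> np.ndarray:
        if which == "self":
            return np.column_stack([self.exposure, self.cov])
        if which == "cotwin":
            return np.column_stack([self.exposure_co, self.cov])
        return np.column_stack([self.exposure, self.exposure_co, self.cov])


def _ct_rows(celltype: CellTypeComponents | None, rows: np.ndarray):
    if celltype is None:
        return None
    return CellTypeComponents(
        scores=celltype.scores[rows],
        sample_ids=[celltype.sample_ids[i] for i in rows],
        selected_sites=celltype.selected_sites,
        explained_variance_ratio=celltype.explained_variance_ratio,
    )


def _fit_three(data: _SiteData) -> tuple[float, float, float, float]:
    x3 = data.model_design("joint")
    if np.linalg.matrix_rank(x3) < x3.shape[1]:
        raise ValidationError("joint model collinear (self and co-twin predictors)")
    b1, _ = cluster_robust_ols(data.model_design("self"), data.outcome, data.groups)
    b2, _ = cluster_robust_ols(data.model_design("cotwin"), data.outcome, data.groups)
    b3, _ = cluster_robust_ols(x3, data.outcome, data.groups)
    return float(b1[0]), float(b2[0]), float(b3[0]), float(b3[1])


def fit_direction_models(
    mv_site: np.ndarray,
    ph: TwinPhenotypeTable,
    direction: str,
    covariates: tuple = ("age", "sex", "dbp"),
    celltype: CellTypeComponents | None = None,
    sample_ids: list[str] | None = None,
) -> tuple[float, float, float, float]:
    """Return (beta_self, beta_cotwin, beta'_self, beta'_cotwin).

    Fits are GEE with independence working correlation (ordinary
    least-squares point estimates, pair-cluster robust errors); covariates
    ride along in every model.
    """
    ids = sample_ids if sample_ids is not None else ph.individual_ids
    data = _SiteData(mv_site, ph, direction, covariates, celltype, ids)
    return _fit_three(data)


def _batched_coefs(g: np.ndarray, h: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """Solve per-replicate normal equations from per-pair Gram blocks.

    g: (n_pairs, p, p) pair contributions X_p' X_p; h: (n_pairs, p) X_p' y_p;
    draws: (B, n_pairs) resampled pair indices. Returns (B, p) coefficients
    with NaN rows for singular replicates.
    """
    xtx = g[draws].sum(axis=1)
    xty = h[draws].sum(axis=1)
    B, p = xty.shape
    out = np.full((B, p), np.nan)
    try:
        out = np.linalg.solve(xtx, xty[..., None])[..., 0]
    except np.linalg.LinAlgError:
        for b in range(B):
            try:
                out[b] = np.linalg.solve(xtx[b], xty[b])
            except np.linalg.LinAlgError:
                pass
    return out


def bootstrap_changes(
    data: _SiteData,
    B: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float, dict]:
    """Pair-bootstrap p-values for the two coefficient changes, plus the ratio.

    Pairs are resampled with replacement; the three models are refitted per
    replicate and the changes recomputed. The standard error is the standard
    deviation over replicates and p the two-sided normal p for
    observed / SE. The ratio uses the observed (not resampled) changes.
    """
    if B < 100:
        raise ValidationError("bootstrap replicates must be >= 100")
    rng = rng if rng is not None else np.random.default_rng(seed)
    b_self, b_cotwin, b_self_adj, b_cotwin_adj = _fit_three(data)
    self_change = b_self - b_self_adj
    cotwin_change = b_cotwin - b_cotwin_adj

    designs = {w: data.model_design(w) for w in ("self", "cotwin", "joint")}
    n = data.n_pairs
    draws = rng.integers(0, n, size=(B, n))
    reps = {}
    for w, x in designs.items():
        xp = x.reshape(n, 2, -1)
        yp = data.outcome.reshape(n, 2)
        g = np.einsum("nij,nik->njk", xp, xp)
        h = np.einsum("nij,ni->nj", xp, yp)
        reps[w] = _batched_coefs(g, h, draws)
    ok = ~(
        np.isnan(reps["self"][:, 0])
        | np.isnan(reps["cotwin"][:, 0])
        | np.isnan(reps["joint"][:, 0])
    )
    if ok.mean() < 0.8:
        raise ValidationError(
            f"bootstrap failed in {(~ok).mean():.0%} of replicates (> 20%)"
        )
    self_changes = reps["self"][ok, 0] - reps["joint"][ok, 0]
    cotwin_changes = reps["cotwin"][ok, 0] - reps["joint"][ok, 1]
    se_self = float(self_changes.std(ddof=1))
    se_cotwin = float(cotwin_changes.std(ddof=1))
    p_self = _change_p(self_change, se_self)
    p_cotwin = _change_p(cotwin_change, se_cotwin)
    ratio = cotwin_change / self_change if self_change != 0.0 else np.nan
    extras = {
        "beta_self": b_self,
        "beta_cotwin": b_cotwin,
        "beta_self_adj": b_self_adj,
        "beta_cotwin_adj": b_cotwin_adj,
        "beta_self_change": self_change,
        "beta_cotwin_change": cotwin_change,
        "se_self_change": se_self,
        "se_cotwin_change": se_cotwin,
    }
    return p_self, p_cotwin, float(ratio), extras


def _change_p(change: float, se: float) -> float:
    if se == 0.0:
        return 1.0 if change == 0.0 else 0.0
    return float(2.0 * stats.norm.sf(abs(change) / se))


def direction_is_causal(
    ratio: float,
    p_cotwin_change: float,
    ratio_threshold: float = 1.5,
    alpha: float = 0.05,
) -> bool:
    """Causal call for one direction: |ratio| strictly above threshold AND a
    significant co-twin coefficient change. An undefined (NaN) ratio is
    non-causal."""
    if not np.isfinite(ratio):
        return False
    return bool(abs(ratio) > ratio_threshold and p_cotwin_change < alpha)


def classify_direction(
    rec_m2f: IceFalconRecord,
    rec_f2m: IceFalconRecord,
    ratio_threshold: float = 1.5,
    alpha: float = 0.05,
) -> str:
    """Combine both directions into one label for a site."""
    m2f = direction_is_causal(rec_m2f.ratio, rec_m2f.p_cotwin_change, ratio_threshold, alpha)
    f2m = direction_is_causal(rec_f2m.ratio, rec_f2m.p_cotwin_change, ratio_threshold, alpha)
    if m2f and f2m:
        return "bidirectional"
    if m2f:
        return "meth_to_fpg_only"
    if f2m:
        return "fpg_to_meth_only"
    return "none"


def classify_printed_rows(
    rows: pd.DataFrame,
    ratio_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the causal rule to a table of published per-direction summaries.

    Expects columns ``m2f_ratio``, ``m2f_p_cotwin``, ``f2m_ratio``,
    ``f2m_p_cotwin``; returns the table with per-direction calls and a
    combined label.
    """
    out = rows.copy()
    out["call_meth_to_fpg"] = [
        direction_is_causal(r, p, ratio_threshold, alpha)
        for r, p in zip(rows["m2f_ratio"], rows["m2f_p_cotwin"])
    ]
    out["call_fpg_to_meth"] = [
        direction_is_causal(r, p, ratio_threshold, alpha)
        for r, p in zip(rows["f2m_ratio"], rows["f2m_p_cotwin"])
    ]
    out["label"] = [
        "bidirectional"
        if a and b
        else "meth_to_fpg_only"
        if a
        else "fpg_to_meth_only"
        if b
        else "none"
        for a, b in zip(out["call_meth_to_fpg"], out["call_fpg_to_meth"])
    ]
    return out


def summarize_causal_counts(labels) -> dict:
    """Count sites per causal label; labels partition the input."""
    counts = {lab: 0 for lab in LABELS}
    for lab in labels:
        if lab not in counts:
            raise ValidationError(f"unknown label {lab!r}")
        counts[lab] += 1
    return counts


def analyze_site(
    mv_site: np.ndarray,
    site: CpGSite,
    ph: TwinPhenotypeTable,
    covariates: tuple = ("age", "sex", "dbp"),
    celltype: CellTypeComponents | None = None,
    sample_ids: list[str] | None = None,
    B: int = 1000,
    seed: int = 0,
    ratio_threshold: float = 1.5,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[IceFalconRecord, IceFalconRecord, str]:
    """Run both directions for one CpG; returns the two records and the label."""
    ids = sample_ids if sample_ids is not None else ph.individual_ids
    recs = {}
    for direction in DIRECTIONS:
        data = _SiteData(mv_site, ph, direction, covariates, celltype, ids)
        p_self, p_cotwin, ratio, ex = bootstrap_changes(data, B=B, seed=seed, rng=rng)
        recs[direction] = IceFalconRecord(
            site=site,
            direction=direction,
            beta_self=ex["beta_self"],
            beta_cotwin=ex["beta_cotwin"],
            beta_self_adj=ex["beta_self_adj"],
            beta_cotwin_adj=ex["beta_cotwin_adj"],
            beta_self_change=ex["beta_self_change"],
            beta_cotwin_change=ex["beta_cotwin_change"],
            p_self_change=p_self,
            p_cotwin_change=p_cotwin,
            ratio=ratio,
            causal_flag=direction_is_causal(ratio, p_cotwin, ratio_threshold, alpha),
        )
    label = classify_direction(
        recs["meth_to_fpg"], recs["fpg_to_meth"], ratio_threshold, alpha
    )
    return recs["meth_to_fpg"], recs["fpg_to_meth"], label


def run_ice_falcon(
    mv: MValueMatrix,
    ph: TwinPhenotypeTable,
    site_indices=None,
    covariates: tuple = ("age", "sex", "dbp"),
    celltype: CellTypeComponents | None = None,
    B: int = 1000,
    seed: int = 0,
    ratio_threshold: float = 1.5,
    alpha: float = 0.05,
) -> tuple[list[IceFalconRecord], dict]:
    """ICE FALCON over a set of sites; returns records and label counts."""
    idx = range(mv.n_sites) if site_indices is None else site_indices
    rng = np.random.default_rng(seed)
    records: list[IceFalconRecord] = []
    labels = []
    for i in idx:
        r1, r2, label = analyze_site(
            mv.m[i],
            mv.sites[i],
            ph,
            covariates,
            celltype,
            mv.sample_ids,
            B=B,
            ratio_threshold=ratio_threshold,
            alpha=alpha,
            rng=rng,
        )
        records.extend([r1, r2])
        labels.append(label)
    return records, summarize_causal_counts(labels)
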