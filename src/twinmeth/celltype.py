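"""Reference-free cell-type composition surrogates (ReFACTor-style).

Whole-blood methylation mixes signals from several leukocyte types, and
between-sample differences in composition masquerade as trait associations.
Without reference profiles, composition can still be approximated: sites
whose between-sample variation is well captured by a low-rank structure are
the ones dominated by cell mixing. This module selects those sites and uses
their principal components as composition covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import MValueMatrix, ValidationError

logger = logging.getLogger("twinmeth")

__all__ = ["CellTypeComponents", "refactor_components"]


@dataclass
class CellTypeComponents:
    """Sample scores of the composition-surrogate PCA.

    ``scores`` is samples x d; columns are mutually orthogonal with signs
    fixed so each component's largest-magnitude site loading is positive.
    """

    scores: np.ndarray
    sample_ids: list[str]
    selected_sites: list[str]
    explained_variance_ratio: np.ndarray

    @property
    def d(self) -> int:
        return self.scores.shape[1]


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean unit-variance rows; returns (standardized, nonconstant mask)."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    z = np.zeros_like(x)
    z[ok] = (x[ok] - mu[ok]) / sd[ok]
    return z, ok


def refactor_components(
    mv: MValueMatrix, k: int = 5, t: int = 500, d: int = 5
) -> CellTypeComponents:
    """Estimate composition surrogates by informative-site PCA.

    Steps: (1) impute missing cells with the site mean and standardize each
    site; (2) form the rank-``k`` SVD approximation of the standardized
    matrix; (3) score each site by the distance between its observed and
    reconstructed row; (4) keep the ``t`` best-approximated (lowest-distance)
    sites; (5) return the first ``d`` principal-component scores of the
    samples over those sites.

    ``k`` is the assumed number of cell types, ``d`` how many components to
    return (the analysis default is five).
    """
    n_sites, n_samples = mv.m.shape
    if t > n_sites:
        raise ValidationError(f"t={t} informative sites requested, only {n_sites} present")
    if d >= n_samples:
        raise ValidationError(f"d={d} components require more than d samples")

    x = mv.m.copy()
    # site-mean imputation keeps the procedure deterministic
    row_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=1)
    nan_r, nan_c = np.nonzero(np.isnan(x))
    x[nan_r, nan_c] = row_mean[nan_r]

    z, ok = _standardize_rows(x)
    if not ok.all():
        logger.warning("%d constant sites excluded from standardization", (~ok).sum())

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k_eff = min(k, len(s))
    approx = (u[:, :k_eff] * s[:k_eff]) @ vt[:k_eff]
    dist = np.linalg.norm(z - approx, axis=1)
    dist[~ok] = np.inf  # constant sites carry no composition signal

    ranked = np.argsort(dist, kind="stable")[:t]
    ranked = np.sort(ranked)  # genomic order, selection unchanged
    zs = z[ranked]

    u2, s2, vt2 = np.linalg.svd(zs, full_matrices=False)
    d_eff = min(d, len(s2))
    scores = vt2[:d_eff].T * s2[:d_eff]
    # sign convention: largest-|loading| per component positive
    for j in range(d_eff):
        i_max = np.argmax(np.abs(u2[:, j]))
        if u2[i_max, j] < 0:
            scores[:, j] = -scores[:, j]
    ev = (s2**2) / np.sum(s2**2)
    return CellTypeComponents(
        scores=scores[:, :d_eff],
        sample_ids=list(mv.sample_ids),
        selected_sites=[mv.sites[i].site_id for i in ranked],
        explained_variance_ratio=ev[:d_eff],
    )
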