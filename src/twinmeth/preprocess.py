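"""Site-level quality control and beta/M scale conversion.

The QC pipeline winsorizes read coverage at an upper quantile, drops CpGs
with very low mean methylation or too many missing observations, and converts
beta values to M-values, M = log2(beta / (1 - beta)), the standard variance-
stabilized regression scale for methylation fractions.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import (
    MethylationMatrix,
    MValueMatrix,
    TwinPhenotypeTable,
    ValidationError,
)

logger = logging.getLogger("twinmeth")

__all__ = [
    "cap_coverage",
    "filter_sites",
    "FilterResult",
    "beta_to_m",
    "m_to_beta",
    "beta_matrix_to_m",
    "select_discordant_pairs",
    "remove_m_outliers",
]


def cap_coverage(m: MethylationMatrix, q: float = 0.90) -> MethylationMatrix:
    """Winsorize coverage at its q-quantile (computed over non-missing cells).

    Beta values are untouched; only the coverage channel is capped. High
    coverage is capped rather than removed so that well-measured sites are
    retained.
    """
    if m.coverage is None:
        raise ValidationError("cap_coverage requires a coverage matrix")
    if not (0.0 < q <= 1.0):
        raise ValidationError(f"quantile must be in (0, 1], got {q}")
    vals = m.coverage[~np.isnan(m.coverage)]
    if vals.size == 0:
        return m
    cap = np.quantile(vals, q)
    capped = np.minimum(m.coverage, cap)
    return MethylationMatrix(
        sites=list(m.sites), beta=m.beta, sample_ids=list(m.sample_ids), coverage=capped
    )


class FilterResult(NamedTuple):
    matrix: MethylationMatrix
    removed: pd.DataFrame  # columns: site_id, reason


def filter_sites(
    m: MethylationMatrix, min_mean_beta: float = 0.05, max_missing: int = 10
) -> FilterResult:
    """Drop CpGs with mean beta below threshold or too many missing values.

    Boundaries are inclusive for keeping: a site with mean beta exactly at
    ``min_mean_beta`` or exactly ``max_missing`` missing observations stays.
    Site order is preserved; removals are returned as a (site_id, reason) log.
    """
    with np.errstate(invalid="ignore"):
        mean_beta = np.nanmean(m.beta, axis=1)
    n_missing = m.missing_per_site()
    low = mean_beta < min_mean_beta
    low |= np.isnan(mean_beta)  # all-missing sites count as low signal
    many = n_missing > max_missing
    keep = ~(low | many)
    records = []
    for i in np.flatnonzero(~keep):
        reason = "low_beta" if low[i] else "missing"
        records.append({"site_id": m.sites[i].site_id, "reason": reason})
    removed = pd.DataFrame(records, columns=["site_id", "reason"])
    if not keep.any():
        logger.warning("filter_sites removed every site")
    return FilterResult(m.subset_sites(keep), removed)


def beta_to_m(b, eps: float = 1e-6):
    """logit2 transform: beta in [0, 1] -> M, clipping to [eps, 1-eps] first.

    Accepts scalars or arrays; NaN (missing) propagates.
    """
    arr = np.asarray(b, dtype=float)
    valid = ~np.isnan(arr)
    if np.any((arr[valid] < 0.0) | (arr[valid] > 1.0)):
        raise ValidationError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, eps, 1.0 - eps)
    with np.errstate(invalid="ignore"):
        out = np.log2(clipped / (1.0 - clipped))
    out = np.where(valid, out, np.nan)
    return float(out) if np.isscalar(b) else out


def m_to_beta(mv):
    """Inverse transform: beta = 2^M / (1 + 2^M), in (0, 1)."""
    arr = np.asarray(mv, dtype=float)
    # equivalent to expit(M * ln 2), numerically stable for large |M|
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-arr[pos]))
    e = np.exp2(arr[~pos])
    out[~pos] = e / (1.0 + e)
    out = np.where(np.isnan(arr), np.nan, out)
    return float(out) if np.isscalar(mv) else out


def beta_matrix_to_m(m: MethylationMatrix, eps: float = 1e-6) -> MValueMatrix:
    """Convert a whole beta matrix to the M scale."""
    return MValueMatrix(
        sites=list(m.sites), m=beta_to_m(m.beta, eps=eps), sample_ids=list(m.sample_ids)
    )


def select_discordant_pairs(
    ph: TwinPhenotypeTable, min_delta: float = 0.1
) -> TwinPhenotypeTable:
    """Keep only pairs whose intra-pair |FPG difference| >= min_delta mmol/L.

    Both members of a pair are kept or dropped together; the boundary is
    inclusive (a difference of exactly ``min_delta`` is kept).
    """
    deltas = ph.pair_deltas("fpg")
    # tolerate float representation error at the boundary (0.1 is not exact)
    keep = deltas[deltas >= min_delta - 1e-9].index
    return ph.subset_pairs(keep)


def remove_m_outliers(mv: MValueMatrix, rule: str = "tukey3iqr") -> MValueMatrix:
    """Per-site outlier removal on the M scale.

    ``tukey3iqr`` marks values outside [Q1 - 3*IQR, Q3 + 3*IQR] missing;
    ``none`` is the identity.
    """
    if rule == "none":
        return mv
    if rule != "tukey3iqr":
        raise ValidationError(f"unknown outlier rule {rule!r}")
    m = mv.m.copy()
    with np.errstate(invalid="ignore"):
        q1 = np.nanpercentile(m, 25, axis=1)
        q3 = np.nanpercentile(m, 75, axis=1)
    iqr = q3 - q1
    lo = (q1 - 3.0 * iqr)[:, None]
    hi = (q3 + 3.0 * iqr)[:, None]
    with np.errstate(invalid="ignore"):
        out = (m < lo) | (m > hi)
    m[out] = np.nan
    return MValueMatrix(sites=list(mv.sites), m=m, sample_ids=list(mv.sample_ids))
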