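"""Case-control statistics for the targeted validation arm.

Candidate CpGs quantified in an independent case-control sample are compared
between groups (Wilcoxon rank-sum or t test) and tested for association with
disease status by covariate-adjusted binary logistic regression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import ValidationError

logger = logging.getLogger("twinmeth")

__all__ = ["compare_groups", "logistic_association", "validate_cpgs"]


def compare_groups(
    values, groups, test: str = "wilcoxon_rank_sum"
) -> tuple[float, float, float]:
    """Two-group comparison; returns (statistic, two-sided p, case-minus-control
    mean difference).

    ``groups`` holds exactly two labels; the difference sign is reported so a
    replication-direction check (e.g. hypermethylation in cases) is
    mechanical. The Wilcoxon test uses the normal approximation with tie and
    continuity corrections.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {labels}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 observations")
    diff = float(a.mean() - b.mean())
    if test == "wilcoxon_rank_sum":
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return float(res.statistic), float(res.pvalue), diff
    if test == "t_test":
        res = stats.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue), diff
    raise ValidationError(f"unknown test {test!r}")


def logistic_association(
    cc: pd.DataFrame,
    cpg: str,
    adjust: tuple = ("chol", "tg", "ldlc"),
    group_col: str = "group",
    case_label: str = "case",
) -> dict:
    """Covariate-adjusted logistic regression of disease status on one CpG.

    Returns the odds ratio per unit methylation fraction (plus per 0.01 as a
    convenience), its Wald 95% CI and p-value. Perfect separation and
    zero-variance predictors are rejected rather than silently fitted.
    """
    y = (cc[group_col] == case_label).to_numpy(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("both cases and controls are required")
    x = cc[[cpg, *adjust]].to_numpy(float)
    if np.isnan(x).any():
        raise ValidationError("complete covariates required")
    if np.ptp(x[:, 0]) == 0:
        raise ValidationError(f"CpG {cpg!r} has zero variance")
    xd = sm.add_constant(x)
    try:
        res = sm.Logit(y, xd).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValidationError(
            f"logistic fit failed ({exc}); consider a penalized fit"
        ) from None
    # near-perfect separation also shows up as saturated fitted probabilities
    fitted = res.predict(xd)
    if np.all((fitted > 0.999) == (y == 1)) and np.all((fitted < 0.001) == (y == 0)):
        raise ValidationError("perfect separation detected; consider a penalized fit")
    coef = res.params[1]
    se = res.bse[1]
    ci = (coef - 1.96 * se, coef + 1.96 * se)
    return {
        "odds_ratio": float(np.exp(coef)),
        "or_per_0.01": float(np.exp(coef * 0.01)),
        "ci_low": float(np.exp(ci[0])),
        "ci_high": float(np.exp(ci[1])),
        "p": float(res.pvalues[1]),
        "coef": float(coef),
        "n": int(len(y)),
    }


def validate_cpgs(
    cc: pd.DataFrame,
    cpg_cols,
    test: str = "wilcoxon_rank_sum",
    adjust: tuple = ("chol", "tg", "ldlc"),
) -> pd.DataFrame:
    """Run the two-group comparison and adjusted logistic model per CpG."""
    rows = []
    for cpg in cpg_cols:
        stat, p_grp, diff = compare_groups(cc[cpg], cc["group"], test=test)
        logi = logistic_association(cc, cpg, adjust=adjust)
        rows.append(
            {
                "cpg": cpg,
                "group_stat": stat,
                "group_p": p_grp,
                "case_minus_control": diff,
                "direction": "+" if diff > 0 else ("-" if diff < 0 else "0"),
                "odds_ratio": logi["odds_ratio"],
                "or_ci_low": logi["ci_low"],
                "or_ci_high": logi["ci_high"],
                "logistic_p": logi["p"],
            }
        )
    return pd.DataFrame(rows)
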