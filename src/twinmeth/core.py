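"""Core data model for twin-design methylation analysis.

The pipeline operates on two aligned containers: a :class:`MethylationMatrix`
(CpG sites x samples, beta scale with optional read coverage) and a
:class:`TwinPhenotypeTable` (one row per individual, keyed by monozygotic
pair). All coordinates are 1-based and inclusive; chromosome order is natural
numeric first (chr1 < chr2 < ... < chr22 < chrX, lexical for the rest).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("twinmeth")

MISSING_TOKENS = {"NA", "NaN", ""}

__all__ = [
    "CpGSite",
    "MethylationMatrix",
    "MValueMatrix",
    "TwinPhenotypeTable",
    "AnalysisConfig",
    "ValidationError",
    "chrom_sort_key",
    "sort_sites",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def chrom_sort_key(chrom: str) -> tuple:
    """Sort key: numeric chromosomes in natural order, then lexical labels."""
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


@dataclass(frozen=True, order=False)
class CpGSite:
    """A single CpG, located by chromosome label and 1-based coordinate."""

    chrom: str
    pos: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"CpG position must be >= 1, got {self.pos}")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @classmethod
    def from_id(cls, site_id: str) -> "CpGSite":
        chrom, _, pos = site_id.rpartition(":")
        return cls(chrom=chrom, pos=int(pos))

    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.pos)


def sort_sites(sites: Iterable[CpGSite]) -> list[CpGSite]:
    return sorted(sites, key=CpGSite.sort_key)


def _check_sorted_unique(sites: Sequence[CpGSite]) -> None:
    keys = [s.sort_key() for s in sites]
    for a, b in zip(keys, keys[1:]):
        if a == b:
            raise ValidationError(f"duplicate site {b}")
        if a > b:
            raise ValidationError("sites are not sorted by (chrom, pos)")


@dataclass
class MethylationMatrix:
    """Sites x samples matrix of methylation fractions (beta values).

    ``beta`` holds floats in [0, 1] with NaN marking missing observations.
    ``coverage`` (optional) is the read depth per cell, NaN exactly where
    ``beta`` is NaN.
    """

    sites: list[CpGSite]
    beta: np.ndarray
    sample_ids: list[str]
    coverage: np.ndarray | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.sites), len(self.sample_ids)):
            raise ValidationError(
                f"beta shape {self.beta.shape} does not match "
                f"{len(self.sites)} sites x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids are not unique")
        _check_sorted_unique(self.sites)
        finite = ~np.isnan(self.beta)
        vals = self.beta[finite]
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValidationError("beta values outside [0, 1]")
        if self.coverage is not None:
            self.coverage = np.asarray(self.coverage, dtype=float)
            if self.coverage.shape != self.beta.shape:
                raise ValidationError("coverage shape differs from beta shape")
            if not np.array_equal(np.isnan(self.coverage), np.isnan(self.beta)):
                raise ValidationError(
                    "coverage must be missing exactly where beta is missing"
                )
            cov = self.coverage[~np.isnan(self.coverage)]
            if cov.size and cov.min() < 0:
                raise ValidationError("coverage values must be nonnegative")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def missing_per_site(self) -> np.ndarray:
        return np.isnan(self.beta).sum(axis=1)

    def subset_sites(self, keep: np.ndarray) -> "MethylationMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return MethylationMatrix(
            sites=[self.sites[i] for i in idx],
            beta=self.beta[idx],
            sample_ids=list(self.sample_ids),
            coverage=None if self.coverage is None else self.coverage[idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return MethylationMatrix(
            sites=list(self.sites),
            beta=self.beta[:, idx],
            sample_ids=list(sample_ids),
            coverage=None if self.coverage is None else self.coverage[:, idx],
        )


@dataclass
class MValueMatrix:
    """Sites x samples matrix on the M scale, M = log2(beta / (1 - beta))."""

    sites: list[CpGSite]
    m: np.ndarray
    sample_ids: list[str]

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != (len(self.sites), len(self.sample_ids)):
            raise ValidationError("m shape does not match sites x samples")
        _check_sorted_unique(self.sites)
        vals = self.m[~np.isnan(self.m)]
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValidationError("non-missing M values must be finite")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def subset_sites(self, keep: np.ndarray) -> "MValueMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return MValueMatrix(
            sites=[self.sites[i] for i in idx],
            m=self.m[idx],
            sample_ids=list(self.sample_ids),
        )


PHENOTYPE_COLUMNS = [
    "individual_id",
    "pair_id",
    "twin_index",
    "fpg",
    "age",
    "sex",
    "dbp",
    "smoking",
    "drinking",
]


@dataclass
class TwinPhenotypeTable:
    """Per-individual phenotypes for a monozygotic twin cohort.

    One row per individual; every ``pair_id`` appears exactly twice with twin
    indices 1 and 2. FPG is fasting plasma glucose in mmol/L, DBP diastolic
    blood pressure in mmHg; smoking/drinking are never/ever.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"phenotype table lacks columns: {missing}")
        df = df[PHENOTYPE_COLUMNS]
        if df["individual_id"].duplicated().any():
            dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
            raise ValidationError(f"duplicated individual_id {dup!r}")
        sizes = df.groupby("pair_id").size()
        bad = sizes[sizes != 2]
        if len(bad):
            raise ValidationError(
                f"each pair_id needs exactly 2 members; offending: {list(bad.index)}"
            )
        ti = df.groupby("pair_id")["twin_index"].agg(lambda s: set(s))
        for pid, s in ti.items():
            if s != {1, 2}:
                raise ValidationError(f"pair {pid!r} twin_index set {s} != {{1, 2}}")
        if not set(df["sex"]) <= {"male", "female"}:
            bad_sex = sorted(set(df["sex"]) - {"male", "female"})
            raise ValidationError(f"unknown sex codes {bad_sex}")
        for col in ("smoking", "drinking"):
            if not set(df[col]) <= {"never", "ever"}:
                raise ValidationError(f"{col} must be never/ever")
        if (df["fpg"] <= 0).any():
            raise ValidationError("fpg must be positive (mmol/L)")
        self.data = df.reset_index(drop=True)

    @property
    def n_pairs(self) -> int:
        return self.data["pair_id"].nunique()

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data["individual_id"])

    def aligned_to(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Rows reordered to match a methylation matrix's sample columns."""
        df = self.data.set_index("individual_id")
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise ValidationError(f"samples absent from phenotype table: {missing}")
        return df.loc[list(sample_ids)].reset_index()

    def pair_deltas(self, column: str = "fpg") -> pd.Series:
        """Absolute intra-pair difference of a numeric phenotype."""
        wide = self.data.pivot(index="pair_id", columns="twin_index", values=column)
        return (wide[1] - wide[2]).abs()

    def subset_pairs(self, pair_ids: Iterable) -> "TwinPhenotypeTable":
        keep = self.data["pair_id"].isin(set(pair_ids))
        return TwinPhenotypeTable(self.data[keep])


@dataclass
class AnalysisConfig:
    """Thresholds and knobs shared across pipeline stages.

    Defaults mirror the study design: genome-wide significance at FDR < 0.05,
    region significance at corrected p < 0.05, and the causal-classification
    rule |ratio| > 1.5 with the co-twin coefficient change significant at 0.05.
    """

    covariates: tuple = ("age", "sex", "dbp")
    working: str = "exchangeable"
    fdr_threshold: float = 0.05
    # DMR (comb-P style) parameters
    dmr_seed_p: float = 0.05
    dmr_join_dist: int = 500
    acf_max_lag: int = 500
    acf_bin_width: int = 50
    slk_window: int = 500
    dmr_threshold_on: str = "sidak"
    # ICE FALCON parameters
    bootstrap_reps: int = 1000
    seed: int = 0
    ratio_threshold: float = 1.5
    change_alpha: float = 0.05
    # preprocessing
    outlier_rule: str = "none"
    min_mean_beta: float = 0.05
    max_missing: int = 10
    coverage_quantile: float = 0.90
    min_fpg_delta: float = 0.1

    def __post_init__(self):
        for name in ("fdr_threshold", "dmr_seed_p", "change_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.bootstrap_reps < 100:
            raise ValidationError("bootstrap_reps must be >= 100")
        if self.dmr_join_dist <= 0:
            raise ValidationError("dmr_join_dist must be > 0")
        if self.working not in {"exchangeable", "independence"}:
            raise ValidationError(f"unknown working correlation {self.working!r}")
        if self.dmr_threshold_on not in {"sidak", "slk"}:
            raise ValidationError("dmr_threshold_on must be 'sidak' or 'slk'")
        if self.outlier_rule not in {"none", "tukey3iqr"}:
            raise ValidationError("outlier_rule must be 'none' or 'tukey3iqr'")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["covariates"] = list(self.covariates)
        return d
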