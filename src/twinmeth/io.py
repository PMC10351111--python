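"""Readers and writers for the TSV exchange formats.

Methylation tables are wide TSVs (``chrom``, ``pos``, then one column per
sample); phenotype tables carry the named columns of
:data:`~twinmeth.core.PHENOTYPE_COLUMNS`. Gene annotation is read from 4+
column BED (0-based half-open) and converted to 1-based closed intervals.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING_TOKENS,
    CpGSite,
    MethylationMatrix,
    MValueMatrix,
    TwinPhenotypeTable,
    ValidationError,
)

logger = logging.getLogger("twinmeth")

__all__ = [
    "read_methylation_table",
    "read_coverage_table",
    "read_mvalue_table",
    "write_methylation_table",
    "write_mvalue_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "write_results_table",
    "read_gene_bed",
]


def _parse_numeric_block(df: pd.DataFrame, path) -> np.ndarray:
    """Parse sample columns, accepting only NA/NaN/'' as missing."""
    raw = df.astype(str).values
    cleaned = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = raw[i, j].strip()
            if tok in MISSING_TOKENS or tok == "nan":
                cleaned[i, j] = np.nan
                continue
            try:
                cleaned[i, j] = float(tok)
            except ValueError:
                raise ValidationError(
                    f"{path}: line {i + 2}: non-numeric value {tok!r} "
                    f"in column {df.columns[j]!r}"
                ) from None
    return cleaned


def _read_site_table(path) -> tuple[list[CpGSite], np.ndarray, list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["chrom", "pos"]:
        raise ValidationError(f"{path}: header must start with 'chrom\\tpos'")
    sample_ids = list(df.columns[2:])
    try:
        positions = df["pos"].astype(int)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-integer position: {exc}") from None
    sites = [CpGSite(c, p) for c, p in zip(df["chrom"], positions)]
    values = _parse_numeric_block(df[sample_ids], path)

    order = np.array(sorted(range(len(sites)), key=lambda i: sites[i].sort_key()))
    if not np.array_equal(order, np.arange(len(sites))):
        logger.info("%s: sites out of order; sorted by (chrom, pos)", path)
    sites = [sites[i] for i in order]
    return sites, values[order], sample_ids, order


def read_methylation_table(path, dialect: str = "tsv_wide") -> MethylationMatrix:
    """Read a wide beta-value TSV into a :class:`MethylationMatrix`.

    Sites are returned sorted by (chrom, pos); out-of-order input is sorted
    with a logged notice. Missing tokens are ``NA``, ``NaN`` and the empty
    string; any other non-numeric token is an error.
    """
    if dialect != "tsv_wide":
        raise ValidationError(f"unknown dialect {dialect!r}")
    sites, beta, sample_ids, _ = _read_site_table(path)
    return MethylationMatrix(sites=sites, beta=beta, sample_ids=sample_ids)


def read_coverage_table(path, matrix: MethylationMatrix) -> MethylationMatrix:
    """Attach a parallel coverage TSV (same sites/samples) to a matrix."""
    sites, cov, sample_ids, _ = _read_site_table(path)
    if [s.site_id for s in sites] != matrix.site_ids or sample_ids != matrix.sample_ids:
        raise ValidationError(f"{path}: coverage table does not match beta table")
    cov = cov.copy()
    cov[np.isnan(matrix.beta)] = np.nan
    return MethylationMatrix(
        sites=matrix.sites, beta=matrix.beta, sample_ids=sample_ids, coverage=cov
    )


def read_mvalue_table(path) -> MValueMatrix:
    sites, m, sample_ids, _ = _read_site_table(path)
    return MValueMatrix(sites=sites, m=m, sample_ids=sample_ids)


def _write_site_table(sites, values, sample_ids, path) -> None:
    df = pd.DataFrame(values, columns=sample_ids)
    df.insert(0, "pos", [s.pos for s in sites])
    df.insert(0, "chrom", [s.chrom for s in sites])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def write_methylation_table(matrix: MethylationMatrix, path, coverage_path=None) -> None:
    _write_site_table(matrix.sites, matrix.beta, matrix.sample_ids, path)
    if coverage_path is not None:
        if matrix.coverage is None:
            raise ValidationError("matrix has no coverage to write")
        _write_site_table(matrix.sites, matrix.coverage, matrix.sample_ids, coverage_path)


def write_mvalue_table(matrix: MValueMatrix, path) -> None:
    _write_site_table(matrix.sites, matrix.m, matrix.sample_ids, path)


def read_phenotype_table(path) -> TwinPhenotypeTable:
    """Read the per-individual phenotype TSV, enforcing the pairing invariant."""
    df = pd.read_csv(path, sep="\t")
    for col in ("fpg", "age", "dbp"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    if "twin_index" in df.columns:
        df["twin_index"] = df["twin_index"].astype(int)
    return TwinPhenotypeTable(df)


def write_phenotype_table(ph: TwinPhenotypeTable, path) -> None:
    ph.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_results_table(records: Sequence, path) -> None:
    """Write a homogeneous list of result records (dataclasses or dicts) as TSV.

    An empty list still produces a header-only file when the element type is a
    dataclass passed via a DataFrame; with a truly empty plain list there are
    no columns to infer, so an empty DataFrame is written.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    elif len(records) and dataclasses.is_dataclass(records[0]):
        types = {type(r) for r in records}
        if len(types) > 1:
            raise ValidationError(f"heterogeneous record types: {types}")
        df = pd.DataFrame([_flatten_record(r) for r in records])
    else:
        df = pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def _flatten_record(rec) -> dict:
    out = {}
    for f in dataclasses.fields(rec):
        v = getattr(rec, f.name)
        if isinstance(v, CpGSite):
            out["chrom"] = v.chrom
            out["pos"] = v.pos
        else:
            out[f.name] = v
    return out


def read_gene_bed(path) -> pd.DataFrame:
    """Read 4+ column BED (chrom, start, end, symbol) as 1-based closed intervals."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene"],
        comment="#",
    )
    if (df["end"] <= df["start"]).any():
        raise ValidationError(f"{path}: BED intervals must satisfy start < end")
    df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based closed
    df["end"] = df["end"].astype(int)
    return df
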