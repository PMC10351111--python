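"""Published summary statistics bundled as reference data.

These tables come from a reduced-representation bisulfite sequencing EWAS of
fasting plasma glucose in 52 monozygotic Chinese twin pairs: the 30
strongest CpG associations, the 32 significant differentially methylated
regions, and the per-CpG bidirectional causal-inference summaries. They serve
as fixed inputs for the classification, ratio and interval-overlap utilities,
and as worked examples in the documentation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["top_cpg_associations", "dmr_intervals", "causal_inference_rows"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("twinmeth").joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False, na_values=[])


def top_cpg_associations() -> pd.DataFrame:
    """Top 30 CpG-FPG associations: coefficient, p, FDR, nearest gene.

    ``prior_evidence`` marks genes already implicated by earlier studies.
    The gene column uses the string "NA" for unannotated sites, kept verbatim.
    """
    df = _load("top_cpg_associations.tsv")
    return df.astype({"pos": int, "beta_coef": float, "p": float, "fdr": float})


def dmr_intervals() -> pd.DataFrame:
    """32 differentially methylated regions (1-based closed intervals).

    ``n_cpgs`` is the number of CpGs inside each region; ``slk_p`` the
    autocorrelation-corrected combined p-value.
    """
    df = _load("dmr_intervals.tsv")
    return df.astype({"start": int, "end": int, "n_cpgs": int, "slk_p": float})


def causal_inference_rows() -> pd.DataFrame:
    """Per-CpG causal-inference summaries for the top 30 CpGs.

    For each direction (``m2f`` = methylation to FPG, ``f2m`` = the reverse):
    the change in the self coefficient between marginal and joint models with
    its p-value, the same for the co-twin coefficient, and the printed
    (signed) ratio of co-twin to self change. ``flag_*`` columns carry the
    published causal calls per direction.
    """
    df = _load("causal_inference.tsv")
    num = [c for c in df.columns if c.startswith(("m2f_", "f2m_"))]
    return df.astype({c: float for c in num} | {"pos": int})
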