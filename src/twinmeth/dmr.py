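"""Differentially methylated region detection from a per-CpG p-value track.

The procedure follows the combined-p-value (comb-P) recipe: estimate the
spatial autocorrelation of the p-value track in distance bins, smooth each
site's p-value by a Stouffer-Liptak-Kechris (SLK) combination of its
neighbors under that correlation, grow candidate regions from runs of small
adjusted p-values, re-score each region on the raw p-values, and apply a
Sidak correction whose multiplicity is the span ratio of all tested bases to
region bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CpGSite, ValidationError, chrom_sort_key

logger = logging.getLogger("twinmeth")

__all__ = [
    "AcfEstimate",
    "DmrRecord",
    "estimate_acf",
    "slk_adjust",
    "find_candidate_regions",
    "score_region",
    "find_dmrs",
    "count_cpgs_in_regions",
    "region_site_coverage",
]

_PCLIP = 1e-15


def _z_from_p(p: np.ndarray) -> np.ndarray:
    return stats.norm.isf(np.clip(p, _PCLIP, 1.0 - _PCLIP))


@dataclass
class AcfEstimate:
    """Distance-binned autocorrelation of the z-transformed p track.

    Bin i covers distances (edges[i], edges[i+1]] in bp; correlations are
    clipped to [0, 1).
    """

    bin_edges: np.ndarray  # length n_bins + 1, starting at 0
    corr: np.ndarray
    counts: np.ndarray

    def corr_at(self, d) -> np.ndarray:
        """Correlation for integer bp distances (1 at d = 0, 0 beyond range)."""
        d = np.asarray(d)
        idx = np.searchsorted(self.bin_edges, d, side="left") - 1
        out = np.zeros(d.shape, dtype=float)
        inside = (d > 0) & (idx >= 0) & (idx < len(self.corr))
        out[inside] = self.corr[idx[inside]]
        out[d == 0] = 1.0
        return out


def _chrom_blocks(sites: list[CpGSite]) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Per-chromosome (label, site indices, positions), input assumed sorted."""
    blocks = []
    start = 0
    for i in range(1, len(sites) + 1):
        if i == len(sites) or sites[i].chrom != sites[start].chrom:
            idx = np.arange(start, i)
            pos = np.array([sites[j].pos for j in idx])
            blocks.append((sites[start].chrom, idx, pos))
            start = i
    return blocks


def estimate_acf(
    sites: list[CpGSite],
    p: np.ndarray,
    max_lag: int = 500,
    bin_width: int = 50,
) -> AcfEstimate:
    """Pearson correlation of z-scores between same-chromosome site pairs,
    binned by genomic distance up to ``max_lag`` bp.

    Negative bin estimates are clipped to 0 (the SLK covariance must stay
    positive semidefinite in practice); bins with fewer than two pairs get
    correlation 0.
    """
    p = np.asarray(p, dtype=float)
    if len(p) != len(sites):
        raise ValidationError("p-value track length differs from site list")
    z = _z_from_p(p)
    n_bins = int(np.ceil(max_lag / bin_width))
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    pairs_a: list[list[float]] = [[] for _ in range(n_bins)]
    pairs_b: list[list[float]] = [[] for _ in range(n_bins)]
    for _, idx, pos in _chrom_blocks(sites):
        for ai in range(len(idx)):
            bi = ai + 1
            while bi < len(idx) and pos[bi] - pos[ai] <= max_lag:
                d = pos[bi] - pos[ai]
                if d > 0:
                    b = (d - 1) // bin_width
                    pairs_a[b].append(z[idx[ai]])
                    pairs_b[b].append(z[idx[bi]])
                bi += 1
    counts = np.array([len(a) for a in pairs_a])
    if counts.sum() == 0:
        raise ValidationError(
            "no same-chromosome site pairs within max_lag; increase max_lag"
        )
    corr = np.zeros(n_bins)
    for b in range(n_bins):
        if counts[b] >= 2:
            a1 = np.asarray(pairs_a[b])
            b1 = np.asarray(pairs_b[b])
            if a1.std() > 0 and b1.std() > 0:
                corr[b] = np.corrcoef(a1, b1)[0, 1]
    corr = np.clip(corr, 0.0, 0.99)
    return AcfEstimate(bin_edges=edges, corr=corr, counts=counts)


def _slk_combine(z_w: np.ndarray, pos_w: np.ndarray, acf: AcfEstimate) -> float:
    """SLK-combined z for a window: sum(z) / sqrt(1' Sigma 1)."""
    d = np.abs(pos_w[:, None] - pos_w[None, :])
    sigma_sum = acf.corr_at(d).sum()
    return float(z_w.sum() / np.sqrt(sigma_sum))


def slk_adjust(
    sites: list[CpGSite],
    p: np.ndarray,
    acf: AcfEstimate,
    window: int = 500,
) -> np.ndarray:
    """Per-site SLK-adjusted p: combine each site with neighbors within
    +/- ``window`` bp on the same chromosome under the estimated correlation.

    An isolated site keeps its raw p-value (single-element combination).
    """
    p = np.asarray(p, dtype=float)
    z = _z_from_p(p)
    out = np.empty_like(p)
    for _, idx, pos in _chrom_blocks(sites):
        lo = np.searchsorted(pos, pos - window, side="left")
        hi = np.searchsorted(pos, pos + window, side="right")
        for j in range(len(idx)):
            a, b = lo[j], hi[j]
            if b - a == 1:
                out[idx[j]] = p[idx[j]]
            else:
                zc = _slk_combine(z[idx[a:b]], pos[a:b], acf)
                out[idx[j]] = stats.norm.sf(zc)
    return out


def find_candidate_regions(
    sites: list[CpGSite],
    p_adj: np.ndarray,
    seed_p: float = 0.05,
    join_dist: int = 500,
) -> list[np.ndarray]:
    """Maximal runs of sites with adjusted p < seed_p, joining consecutive
    qualifying sites at most ``join_dist`` bp apart on one chromosome.

    Returns lists of site indices; singleton runs are kept at this stage.
    """
    p_adj = np.asarray(p_adj, dtype=float)
    regions: list[np.ndarray] = []
    for _, idx, pos in _chrom_blocks(sites):
        hits = np.flatnonzero(p_adj[idx] < seed_p)
        if hits.size == 0:
            continue
        run = [hits[0]]
        for h in hits[1:]:
            if pos[h] - pos[run[-1]] <= join_dist:
                run.append(h)
            else:
                regions.append(idx[np.array(run)])
                run = [h]
        regions.append(idx[np.array(run)])
    return regions


@dataclass
class DmrRecord:
    """A detected region: 1-based closed interval over its first/last CpG."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    slk_p: float
    sidak_p: float
    direction: str = "NA"  # sign of the mean association inside the region


def score_region(
    region_idx: np.ndarray,
    sites: list[CpGSite],
    p: np.ndarray,
    acf: AcfEstimate,
    total_span_bp: int,
    direction: str = "NA",
) -> DmrRecord:
    """Score one candidate region on the raw p-values.

    ``slk_p`` is the SLK combination of the region's raw p-values under the
    estimated correlation; ``sidak_p`` = 1 - (1 - slk_p)^(total_span /
    region_span) with region span end - start + 1 bp.
    """
    region_idx = np.asarray(region_idx)
    if region_idx.size == 0:
        raise ValidationError("empty region")
    pos = np.array([sites[i].pos for i in region_idx])
    z = _z_from_p(np.asarray(p, dtype=float)[region_idx])
    if region_idx.size == 1:
        slk_p = float(np.asarray(p, dtype=float)[region_idx[0]])
    else:
        slk_p = float(stats.norm.sf(_slk_combine(z, pos, acf)))
    span = int(pos.max() - pos.min() + 1)
    exponent = max(total_span_bp, span) / span
    slk_p = min(max(slk_p, 0.0), 1.0)
    sidak_p = float(1.0 - (1.0 - slk_p) ** exponent)
    sidak_p = min(max(sidak_p, slk_p), 1.0)
    return DmrRecord(
        chrom=sites[region_idx[0]].chrom,
        start=int(pos.min()),
        end=int(pos.max()),
        n_cpgs=int(region_idx.size),
        slk_p=slk_p,
        sidak_p=sidak_p,
        direction=direction,
    )


def total_span(sites: list[CpGSite]) -> int:
    """Sum of per-chromosome extents (bp) of the tested sites."""
    return int(
        sum(pos.max() - pos.min() + 1 for _, _, pos in _chrom_blocks(sites))
    )


def find_dmrs(
    sites: list[CpGSite],
    p: np.ndarray,
    effect_sign: np.ndarray | None = None,
    max_lag: int = 500,
    bin_width: int = 50,
    window: int = 500,
    seed_p: float = 0.05,
    join_dist: int = 500,
    threshold: float | None = 0.05,
    threshold_on: str = "sidak",
) -> list[DmrRecord]:
    """Full pipeline: ACF -> SLK adjustment -> region growth -> scoring.

    ``effect_sign`` (optional, per site) labels each region's direction as
    '+', '-' or 'NA' when the member signs disagree. ``threshold=None``
    returns every candidate region.
    """
    acf = estimate_acf(sites, p, max_lag=max_lag, bin_width=bin_width)
    p_adj = slk_adjust(sites, p, acf, window=window)
    regions = find_candidate_regions(sites, p_adj, seed_p=seed_p, join_dist=join_dist)
    span = total_span(sites)
    records = []
    for idx in regions:
        direction = "NA"
        if effect_sign is not None:
            signs = set(np.sign(np.asarray(effect_sign)[idx]))
            if signs == {1.0}:
                direction = "+"
            elif signs == {-1.0}:
                direction = "-"
        rec = score_region(idx, sites, p, acf, span, direction=direction)
        records.append(rec)
    if threshold is not None:
        key = (lambda r: r.sidak_p) if threshold_on == "sidak" else (lambda r: r.slk_p)
        records = [r for r in records if key(r) < threshold]
    records.sort(key=lambda r: (*chrom_sort_key(r.chrom), r.start))
    return records


def count_cpgs_in_regions(regions, sites: list[CpGSite]) -> np.ndarray:
    """Number of the given CpGs falling inside each region interval
    (matching chromosome, start <= pos <= end)."""
    counts = np.zeros(len(regions), dtype=int)
    for i, r in enumerate(regions):
        chrom, start, end = r.chrom, r.start, r.end
        counts[i] = sum(
            1 for s in sites if s.chrom == chrom and start <= s.pos <= end
        )
    return counts


def region_site_coverage(
    regions_df,
    cpg_df,
    require_gene_concordance: bool = False,
):
    """Cross a region table against a CpG table; count covered CpGs per region.

    Both inputs are DataFrames with 1-based closed coordinates (regions:
    chrom/start/end[/gene]; CpGs: chrom/pos[/gene]). With
    ``require_gene_concordance`` a CpG only counts when both carry the same
    gene symbol — at gene-dense loci the nearest-gene label of a site and of
    a region can legitimately disagree, and concordance restricts the overlap
    to sites the region plausibly annotates.

    Returns the region table with an added ``covered_cpgs`` column, restricted
    to regions covering at least one CpG.
    """
    out = regions_df.copy()
    counts = []
    for _, r in out.iterrows():
        hit = cpg_df[
            (cpg_df["chrom"] == r["chrom"])
            & (cpg_df["pos"] >= r["start"])
            & (cpg_df["pos"] <= r["end"])
        ]
        if require_gene_concordance:
            hit = hit[hit["gene"] == r["gene"]]
        counts.append(len(hit))
    out["covered_cpgs"] = counts
    return out[out["covered_cpgs"] > 0].reset_index(drop=True)
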