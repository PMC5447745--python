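"""SNP-index / Δ(SNP-index) association statistics and region calling.

For a biallelic parental difference, each bulk's SNP-index is the
fraction of its reads carrying the fertile-parent (M) allele:

    SNP_index(aa) = Maa / (Paa + Maa)      (sterile bulk)
    SNP_index(ab) = Mab / (Pab + Mab)      (fertile bulk)
    Δ(SNP-index)  = SNP_index(aa) - SNP_index(ab)

Near a fully linked recessive sterility locus the sterile bulk is fixed
for the P allele and a homozygous-fertile bulk for the M allele, driving
Δ to -1; unlinked loci fluctuate around 0.  |Δ| is smoothed along each
chromosome and runs of markers above a threshold (0.6 by default) are
reported as candidate association regions.

Indices are undefined (NaN), never zero-imputed, below a minimum depth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRegion",
    "snp_index",
    "delta_snp_index",
    "compute_index_table",
    "smooth_delta",
    "call_regions",
    "filter_informative_snps",
    "region_size_mb",
    "span_kb",
    "plot_delta_track",
]

DEFAULT_MIN_DEPTH = 4
DEFAULT_DELTA_THRESHOLD = 0.6
DEFAULT_WINDOW_BP = 100_000
DEFAULT_MIN_MARKERS = 5
DEFAULT_MERGE_GAP_BP = 50_000


def region_size_mb(start: int, end: int) -> float:
    """Region span in megabases, (end - start) / 1e6 to two decimals."""
    return round((end - start) / 1e6, 2)


def span_kb(start: int, end: int) -> int:
    """Interval span in kilobases, rounded to the nearest kb."""
    return round((end - start) / 1000)


@dataclass(frozen=True)
class AssociationRegion:
    """A contiguous run of markers whose smoothed |Δ| exceeds threshold.

    Coordinates are 1-based inclusive marker positions delimiting the run.
    """

    chrom: str
    start: int
    end: int
    n_markers: int
    peak_abs_delta: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("region start must precede end")
        if self.n_markers < 1:
            raise ValueError("region must contain markers")

    @property
    def size_mb(self) -> float:
        return region_size_mb(self.start, self.end)


def snp_index(depth_from_m: int, depth_from_p: int, min_depth: int = DEFAULT_MIN_DEPTH) -> float:
    """Fraction of reads from the M (fertile, HM1-1) parent: M / (P + M).

    Returns NaN when total depth is below ``min_depth`` — shallow sites
    are flagged undefined rather than imputed.
    """
    if depth_from_m < 0 or depth_from_p < 0:
        raise ValueError("read depths must be non-negative")
    total = depth_from_m + depth_from_p
    if total < max(min_depth, 1):
        return math.nan
    return depth_from_m / total


def delta_snp_index(index_aa: float, index_ab: float) -> float:
    """Δ(SNP-index) = index(sterile bulk) - index(fertile bulk).

    Undefined (NaN) whenever either bulk's index is undefined.
    """
    if math.isnan(index_aa) or math.isnan(index_ab):
        return math.nan
    return index_aa - index_ab


def compute_index_table(
    depths: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH
) -> pd.DataFrame:
    """Vectorised per-SNP index table.

    Input columns: ``chrom, pos, Paa, Maa, Pab, Mab``; output adds
    ``index_aa, index_ab, delta`` with NaN where the per-bulk depth is
    below ``min_depth``.
    """
    df = depths.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    for col in ("Paa", "Maa", "Pab", "Mab"):
        if (df[col] < 0).any():
            raise ValueError(f"negative depth in column {col}")
    floor = max(min_depth, 1)
    tot_aa = df["Paa"] + df["Maa"]
    tot_ab = df["Pab"] + df["Mab"]
    with np.errstate(invalid="ignore", divide="ignore"):
        index_aa = np.where(tot_aa >= floor, df["Maa"] / tot_aa, np.nan)
        index_ab = np.where(tot_ab >= floor, df["Mab"] / tot_ab, np.nan)
    out = df.copy()
    out["index_aa"] = index_aa
    out["index_ab"] = index_ab
    out["delta"] = index_aa - index_ab
    return out


def _window_mean_abs(pos: np.ndarray, delta: np.ndarray, window_bp: int, min_markers: int) -> np.ndarray:
    """Centered sliding-window mean of |delta| over +-window_bp/2,
    restricted to markers where delta is defined."""
    defined = ~np.isnan(delta)
    dpos = pos[defined]
    dabs = np.abs(delta[defined])
    csum = np.concatenate([[0.0], np.cumsum(dabs)])
    half = window_bp / 2.0
    lo = np.searchsorted(dpos, pos - half, side="left")
    hi = np.searchsorted(dpos, pos + half, side="right")
    count = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (csum[hi] - csum[lo]) / count
    mean[count < max(min_markers, 1)] = np.nan
    return mean


def _tricube_local_mean(pos: np.ndarray, delta: np.ndarray, span: float) -> np.ndarray:
    """Local regression of |delta| on position with tri-cube weights over
    the nearest ``span`` fraction of defined markers (degree 0)."""
    defined = ~np.isnan(delta)
    dpos = pos[defined].astype(float)
    dabs = np.abs(delta[defined])
    n = dpos.size
    out = np.full(pos.size, np.nan)
    if n == 0:
        return out
    k = max(2, int(np.ceil(span * n)))
    for i, x in enumerate(pos.astype(float)):
        d = np.abs(dpos - x)
        idx = np.argpartition(d, min(k, n) - 1)[: min(k, n)]
        h = d[idx].max()
        w = (1 - (d[idx] / h) ** 3) ** 3 if h > 0 else np.ones(idx.size)
        if w.sum() == 0:
            w = np.ones(idx.size)
        out[i] = float(np.average(dabs[idx], weights=w))
    return out


def smooth_delta(
    points: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_markers: int = 1,
    method: str = "window",
    span: float = 0.1,
) -> pd.DataFrame:
    """Smooth |Δ| along each chromosome.

    ``method="window"`` (default) is a centered sliding-window mean of the
    defined |Δ| values within ±window_bp/2 of each marker; windows holding
    fewer than ``min_markers`` defined markers yield NaN.  ``method="loess"``
    is a tri-cube-weighted local mean over a ``span`` fraction of markers.
    Returns the input with a ``smoothed`` column added.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if points.empty:
        out = points.copy()
        out["smoothed"] = pd.Series(dtype=float)
        return out
    df = points.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    smoothed = np.full(len(df), np.nan)
    for _, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        delta = grp["delta"].to_numpy(dtype=float)
        if method == "window":
            vals = _window_mean_abs(pos, delta, window_bp, min_markers)
        elif method == "loess":
            vals = _tricube_local_mean(pos, delta, span)
        else:
            raise ValueError(f"unknown smoothing method: {method}")
        smoothed[grp.index.to_numpy()] = vals
    out = df.copy()
    out["smoothed"] = smoothed
    return out


def call_regions(
    smoothed: pd.DataFrame,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    min_markers: int = DEFAULT_MIN_MARKERS,
    merge_gap_bp: int = DEFAULT_MERGE_GAP_BP,
) -> list[AssociationRegion]:
    """Call candidate regions from a smoothed |Δ| track.

    Maximal runs of consecutive markers with smoothed value strictly
    above ``delta_threshold`` become regions; runs on one chromosome
    separated by less than ``merge_gap_bp`` are merged; regions with
    fewer than ``min_markers`` markers are dropped.  Region bounds are
    the first and last marker positions of the run (no extension).
    """
    if not (0 < delta_threshold <= 1):
        raise ValueError("delta_threshold must be in (0, 1]")
    regions: list[AssociationRegion] = []
    if smoothed.empty:
        return regions
    df = smoothed.sort_values(["chrom", "pos"], kind="mergesort")
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        val = grp["smoothed"].to_numpy(dtype=float)
        above = np.where(np.nan_to_num(val, nan=-np.inf) > delta_threshold)[0]
        if above.size == 0:
            continue
        # split the above-threshold markers into runs, merging across
        # below-threshold stretches shorter than merge_gap_bp
        runs: list[list[int]] = [[above[0]]]
        for i in above[1:]:
            if i == runs[-1][-1] + 1 or pos[i] - pos[runs[-1][-1]] < merge_gap_bp:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            i0, i1 = run[0], run[-1]
            n = int(i1 - i0 + 1)
            if n < min_markers or pos[i0] >= pos[i1]:
                continue
            peak = float(np.nanmax(val[i0 : i1 + 1]))
            regions.append(
                AssociationRegion(
                    chrom=str(chrom),
                    start=int(pos[i0]),
                    end=int(pos[i1]),
                    n_markers=n,
                    peak_abs_delta=peak,
                )
            )
    return regions


def filter_informative_snps(
    records: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH
) -> pd.DataFrame:
    """Keep SNPs usable for the index statistics.

    Rules, each logged with its removal count: the two parental alleles
    must differ (homozygous-different parents); when parental genotype
    columns (``P_gt``, ``M_gt``, e.g. "A/A") are present, heterozygous
    parents are removed; when parental depth columns (``P_depth``,
    ``M_depth``) are present, each parent must reach ``min_depth``.
    """
    df = records
    n0 = len(df)
    df = df[df["allele_P"] != df["allele_M"]]
    logger.info("filter_informative_snps: %d removed (identical parental alleles)", n0 - len(df))

    for col in ("P_gt", "M_gt"):
        if col in df.columns:
            n0 = len(df)
            hom = df[col].str.split("/").map(lambda a: len(set(a)) == 1)
            df = df[hom]
            logger.info("filter_informative_snps: %d removed (heterozygous %s)", n0 - len(df), col)

    for col in ("P_depth", "M_depth"):
        if col in df.columns:
            n0 = len(df)
            df = df[df[col] >= min_depth]
            logger.info("filter_informative_snps: %d removed (%s < %d)", n0 - len(df), col, min_depth)

    return df.reset_index(drop=True)


def plot_delta_track(
    smoothed: pd.DataFrame,
    path,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    regions: list[AssociationRegion] | None = None,
) -> None:
    """Write a simple per-chromosome Δ(SNP-index) track figure to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(smoothed["chrom"]))
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(8, 1.6 * len(chroms)), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes.ravel(), chroms):
        grp = smoothed[smoothed["chrom"] == chrom]
        ax.plot(grp["pos"] / 1e6, grp["delta"], ".", ms=2, alpha=0.4, color="grey")
        ax.plot(grp["pos"] / 1e6, grp["smoothed"], "-", color="black", lw=1)
        ax.axhline(delta_threshold, color="red", ls="--", lw=0.8)
        ax.axhline(-delta_threshold, color="red", ls="--", lw=0.8)
        for region in regions or []:
            if region.chrom == chrom:
                ax.axvspan(region.start / 1e6, region.end / 1e6, color="orange", alpha=0.3)
        ax.set_ylabel(chrom, rotation=0, ha="right", fontsize=8)
        ax.set_ylim(-1.05, 1.05)
    axes.ravel()[-1].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
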