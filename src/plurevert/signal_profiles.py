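"""Signal aggregation around peak sets.

Composite (metaplot) enrichment profiles, read-density heatmaps with
percentile capping, sliding-window CpG-methylation composites, per-region
binned and mean methylation, CpG density, and the two-sample Mann-Whitney
comparison used to contrast methylation distributions between peak classes.

Methylation values are per-CpG fractions in [0, 1]; windows or regions with
no qualifying CpG propagate as NaN, never as zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from plurevert.config import PipelineConfig
from plurevert.io_formats import (
    CoverageTrack,
    GenomicInterval,
    MethylationRecord,
)

logger = logging.getLogger(__name__)


@dataclass
class CompositeProfile:
    """Across-region signal as a function of offset from region centers.

    ``offsets`` are bin centers in bp relative to the summit/center;
    ``central`` holds the per-bin median (read signal) or mean
    (methylation); ``dispersion`` is the per-bin standard deviation in
    methylation mode; ``n_per_bin`` counts contributing regions.
    """

    offsets: np.ndarray
    central: np.ndarray
    dispersion: np.ndarray | None
    n_regions: int
    n_per_bin: np.ndarray | None = None


@dataclass
class DensityHeatmap:
    matrix: np.ndarray  # regions x bins, capped
    offsets: np.ndarray
    cap_value: float


def _region_matrix(
    centers: Sequence[tuple[str, int, str]],
    track: CoverageTrack,
    halfwidth: int,
    bin_bp: int,
) -> np.ndarray:
    """Per-region per-bin mean depth per million mapped reads.

    A minus-strand region is flipped so its offset axis runs 5'->3'.
    """
    n_bins = 2 * halfwidth // bin_bp
    per_million = track.library_size / 1e6
    mat = np.empty((len(centers), n_bins), dtype=float)
    for i, (chrom, center, strand) in enumerate(centers):
        depths = track.window(chrom, center - halfwidth, center + halfwidth)
        binned = depths.reshape(n_bins, bin_bp).mean(axis=1) / per_million
        mat[i] = binned[::-1] if strand == "-" else binned
    return mat


def _centers(peaks_or_intervals) -> list[tuple[str, int, str]]:
    out = []
    for p in peaks_or_intervals:
        if isinstance(p, GenomicInterval):
            out.append((p.chrom, p.center, p.strand))
        else:  # ConsensusPeak-like: has chrom/summit
            out.append((p.chrom, p.summit, "."))
    return out


def composite_profile(
    peaks,
    track: CoverageTrack,
    halfwidth: int = 2000,
    bin_bp: int = 1,
) -> CompositeProfile:
    """Median library-normalised read depth per offset bin across peaks."""
    centers = _centers(peaks)
    if not centers:
        raise ValueError("empty peak set")
    mat = _region_matrix(centers, track, halfwidth, bin_bp)
    offsets = np.arange(-halfwidth, halfwidth, bin_bp) + (bin_bp - 1) / 2.0
    return CompositeProfile(
        offsets=offsets,
        central=np.median(mat, axis=0),
        dispersion=None,
        n_regions=len(centers),
    )


def density_heatmap(
    peak_sets: Sequence,
    track: CoverageTrack,
    halfwidth: int = 2000,
    bin_bp: int = 10,
    cap_quantile: float = 0.99,
    joint_cap: bool = True,
) -> list[DensityHeatmap]:
    """Read-density matrices (regions x bins) capped at a high percentile.

    ``peak_sets`` is a list of peak lists co-displayed together; the cap is
    the given quantile of the pooled matrix entries across all sets
    (per-set capping with ``joint_cap=False``). Entries above the cap are
    set to the cap; ordering below the cap is untouched.
    """
    if not peak_sets or any(len(ps) == 0 for ps in peak_sets):
        raise ValueError("empty peak set")
    mats = [
        _region_matrix(_centers(ps), track, halfwidth, bin_bp)
        for ps in peak_sets
    ]
    offsets = np.arange(-halfwidth, halfwidth, bin_bp) + (bin_bp - 1) / 2.0
    out = []
    if joint_cap:
        cap = float(np.quantile(np.concatenate([m.ravel() for m in mats]),
                                cap_quantile))
        caps = [cap] * len(mats)
    else:
        caps = [float(np.quantile(m, cap_quantile)) for m in mats]
    for m, cap in zip(mats, caps):
        out.append(DensityHeatmap(np.minimum(m, cap), offsets, cap))
    return out


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def _meth_index(
    meth: Sequence[MethylationRecord], min_cov: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """chrom -> (sorted positions, fractions) for CpGs passing coverage."""
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for r in meth:
        if r.coverage >= min_cov:
            by_chrom.setdefault(r.chrom, []).append((r.pos, r.fraction))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        pos = np.array([p for p, _ in pairs], dtype=np.int64)
        frac = np.array([f for _, f in pairs], dtype=float)
        out[chrom] = (pos, frac)
    return out


def methylation_composite(
    regions: Sequence[GenomicInterval],
    meth: Sequence[MethylationRecord],
    halfwidth: int = 2000,
    window: int = 100,
    slide: int = 25,
    min_cov: int = 3,
) -> CompositeProfile:
    """Sliding-window mean-methylation metaplot across regions.

    Each region is extended to +/- ``halfwidth`` from its center; windows
    of ``window`` bp advance by ``slide`` bp. Per region and window the
    mean of per-CpG fractions (coverage >= ``min_cov``) is taken; windows
    without a qualifying CpG are missing. The profile is the across-region
    mean with +/- 1 SD, ignoring missing windows (per-bin n reported).
    """
    index = _meth_index(meth, min_cov)
    starts = np.arange(-halfwidth, halfwidth - window + 1, slide)
    offsets = starts + window / 2.0
    rows = np.full((len(regions), len(starts)), np.nan)
    for i, region in enumerate(regions):
        center = region.center
        pos_frac = index.get(region.chrom)
        if pos_frac is None:
            continue
        pos, frac = pos_frac
        for j, w0 in enumerate(starts):
            lo = center + int(w0)
            hi = lo + window
            a, b = np.searchsorted(pos, [lo, hi])
            if b > a:
                rows[i, j] = frac[a:b].mean()
        if region.strand == "-":
            rows[i] = rows[i, ::-1]
    n_per_bin = np.sum(~np.isnan(rows), axis=0)
    if n_per_bin.sum() == 0:
        logger.warning("methylation composite: no qualifying CpG anywhere")
    import warnings

    with warnings.catch_warnings():
        # all-missing windows legitimately yield NaN bins
        warnings.simplefilter("ignore", category=RuntimeWarning)
        central = np.nanmean(rows, axis=0)
        dispersion = np.nanstd(rows, axis=0)
    return CompositeProfile(
        offsets=offsets.astype(float),
        central=central,
        dispersion=dispersion,
        n_regions=len(regions),
        n_per_bin=n_per_bin,
    )


def binned_methylation(
    regions: Sequence[GenomicInterval],
    meth: Sequence[MethylationRecord],
    span: int = 5000,
    bin_bp: int = 50,
    min_cov: int = 3,
) -> np.ndarray:
    """Per-region binned mean methylation over a window centred on each region.

    Returns a regions x (span / bin_bp) matrix; bins without a qualifying
    CpG are NaN.
    """
    index = _meth_index(meth, min_cov)
    n_bins = span // bin_bp
    half = span // 2
    mat = np.full((len(regions), n_bins), np.nan)
    for i, region in enumerate(regions):
        pos_frac = index.get(region.chrom)
        if pos_frac is None:
            continue
        pos, frac = pos_frac
        start = region.center - half
        a, b = np.searchsorted(pos, [start, start + span])
        if b == a:
            continue
        bins = (pos[a:b] - start) // bin_bp
        for k in range(n_bins):
            sel = bins == k
            if sel.any():
                mat[i, k] = frac[a:b][sel].mean()
        if region.strand == "-":
            mat[i] = mat[i, ::-1]
    return mat


def mean_region_methylation(
    region: GenomicInterval,
    meth: Sequence[MethylationRecord],
    min_cpgs: int = 1,
    min_cov: int = 3,
    weighted: bool = False,
) -> float:
    """Mean methylation fraction over qualifying CpGs in a region.

    Unweighted mean of per-CpG fractions by default (``weighted=True``
    weights by coverage); NaN if fewer than ``min_cpgs`` CpGs with coverage
    >= ``min_cov`` fall in the region.
    """
    fracs, weights = [], []
    for r in meth:
        if (r.chrom == region.chrom and region.start <= r.pos < region.end
                and r.coverage >= min_cov):
            fracs.append(r.fraction)
            weights.append(r.coverage)
    if len(fracs) < min_cpgs:
        return float("nan")
    if weighted:
        return float(np.average(fracs, weights=weights))
    return float(np.mean(fracs))


# ---------------------------------------------------------------------------
# CpG density
# ---------------------------------------------------------------------------


def cpg_density(
    intervals: Sequence[GenomicInterval],
    genome: Mapping[str, str],
) -> tuple[np.ndarray, dict[str, float]]:
    """CpG dinucleotides per 100 bp for each interval, plus mean/median.

    Counts forward-strand CG dinucleotides whose first base lies within the
    half-open interval (CpG is its own reverse complement, so one strand
    suffices).
    """
    densities = np.empty(len(intervals))
    for i, iv in enumerate(intervals):
        seq = genome.get(iv.chrom)
        if seq is None or iv.end > len(seq):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} outside genome"
            )
        sub = seq[iv.start : min(iv.end + 1, len(seq))]
        count = sum(
            1 for k in range(min(len(sub) - 1, len(iv)))
            if sub[k : k + 2] == "CG"
        )
        densities[i] = 100.0 * count / len(iv)
    summary = {
        "mean": float(np.mean(densities)) if len(densities) else float("nan"),
        "median": float(np.median(densities)) if len(densities) else float("nan"),
    }
    return densities, summary


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------


def _u_statistic(ranks_a: np.ndarray, n1: int) -> float:
    return float(ranks_a.sum() - n1 * (n1 + 1) / 2.0)


def compare_distributions(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For combined sample size at most 20 the null distribution of U is
    enumerated exactly over all group assignments of the pooled values
    (midranks, so ties are handled); the two-sided p is
    2 * min(P(U <= u), P(U >= u)), capped at 1. Larger samples use the
    tie-corrected normal approximation. Returns (U for the first sample,
    two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks[:n1], n1)
    if n1 + n2 <= 20:
        n_le = n_ge = total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks[list(combo)], n1)
            total += 1
            if u <= u_obs + 1e-9:
                n_le += 1
            if u >= u_obs - 1e-9:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
    return u_obs, float(min(p, 1.0))
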