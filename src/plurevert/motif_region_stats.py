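"""PWM motif scanning with exact p-values and region-overlap association.

A position count matrix becomes a log-odds score against a background
base composition; the exact null distribution of window scores over
i.i.d. background words is computed by dynamic programming on a
discretised score lattice, which converts the per-window p-value cutoff
(default 1e-4) into a score threshold. Scanning both strands of peak
regions yields a binary peaks x motifs presence matrix, per-class motif
enrichment, and positional-preference profiles of hit offsets from peak
centers. Association between two genomic region sets is scored by a
permutation test that relocates query regions uniformly within their own
chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from plurevert.config import PipelineConfig
from plurevert.io_formats import GenomicInterval

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}

# score lattice granularity, in bits
SCORE_GRANULARITY = 1e-3


@dataclass
class MotifModel:
    """A PWM with pseudocounted probabilities and a background model."""

    motif_id: str
    counts: np.ndarray  # L x 4, A C G T order
    pseudocount: float = 0.1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be L x 4")
        if self.counts.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        if ((self.counts + self.pseudocount) <= 0).any():
            raise ValueError("column counts must be > 0 after pseudocount")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        c = self.counts + self.pseudocount
        return c / c.sum(axis=1, keepdims=True)

    @property
    def log_odds_bits(self) -> np.ndarray:
        """Per-position per-base log2(p_motif / p_background)."""
        return np.log2(self.probabilities / self.background)

    @property
    def lattice_scores(self) -> np.ndarray:
        """Log-odds rounded to the integer score lattice."""
        return np.rint(self.log_odds_bits / SCORE_GRANULARITY).astype(np.int64)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


def score_distribution(motif: MotifModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of lattice scores of i.i.d. background words.

    Returns (integer lattice scores, probabilities), computed by
    convolving the per-position score distributions.
    """
    lat = motif.lattice_scores
    bg = motif.background
    # point mass at score 0, integer offset tracked separately
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(len(motif)):
        pos_lo = int(lat[j].min())
        pos_hi = int(lat[j].max())
        pos = np.zeros(pos_hi - pos_lo + 1)
        for b in range(4):
            pos[lat[j, b] - pos_lo] += bg[b]
        cur = np.convolve(cur, pos)
        cur_lo += pos_lo
    scores = np.arange(cur_lo, cur_lo + len(cur))
    keep = cur > 0
    return scores[keep], cur[keep]


def motif_pvalue_threshold(
    motif: MotifModel, alpha: float = 1e-4
) -> tuple[float, int | None]:
    """Smallest score whose background tail probability is below alpha.

    Returns (threshold in bits, threshold on the integer lattice). When no
    attainable score is rare enough the motif can never produce a hit and
    the threshold is +inf (lattice threshold None, logged).
    """
    scores, pmf = score_distribution(motif)
    tail = np.cumsum(pmf[::-1])[::-1]  # P(score >= s)
    below = np.flatnonzero(tail < alpha)
    if below.size == 0:
        logger.info("motif %s too degenerate for alpha=%g; no hits possible",
                    motif.motif_id, alpha)
        return float("inf"), None
    t = int(scores[below[0]])
    return t * SCORE_GRANULARITY, t


@dataclass
class MotifHit:
    peak_id: str
    motif_id: str
    offset: int  # window center - peak center, forward orientation
    strand: str
    score_bits: float
    p_value: float


@dataclass
class MotifHitMatrix:
    presence: pd.DataFrame  # peaks x motifs, 0/1
    hits: list[MotifHit]


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int64)
    for b, i in _CODE.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8)
              == ord(b)] = i
    return codes


def _window_scores(codes: np.ndarray, lattice: np.ndarray) -> np.ndarray:
    """Lattice score of every window; windows containing non-ACGT get -inf."""
    L = lattice.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = lattice[np.arange(L), safe].sum(axis=1).astype(float)
    scores[~valid] = -np.inf
    return scores


def scan_motifs(
    regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    motifs: Sequence[MotifModel],
    alpha: float = 1e-4,
    region_ids: Sequence[str] | None = None,
) -> MotifHitMatrix:
    """Scan both strands of each region for motif occurrences.

    A window is a hit when its log-odds score meets the motif's
    alpha-level threshold from :func:`motif_pvalue_threshold`. The binary
    presence entry is 1 iff the region has at least one hit; per-hit
    records carry the signed offset of the window center from the region
    center (forward-strand orientation), strand, score and the exact
    p-value of the score. Regions shorter than the motif simply yield no
    hits.
    """
    if region_ids is None:
        region_ids = [f"region_{i}" for i in range(len(regions))]
    hits: list[MotifHit] = []
    presence = pd.DataFrame(
        0, index=list(region_ids), columns=[m.motif_id for m in motifs],
        dtype=np.int8,
    )
    for motif in motifs:
        _, t_lat = motif_pvalue_threshold(motif, alpha)
        if t_lat is None:
            continue
        scores, pmf = score_distribution(motif)
        tail = np.cumsum(pmf[::-1])[::-1]
        lat = motif.lattice_scores
        rc_lat = lat[::-1, ::-1]  # reverse-complement motif
        L = len(motif)
        for region, rid in zip(regions, region_ids):
            seq = genome[region.chrom][region.start:region.end]
            codes = _encode(seq)
            center = (region.start + region.end) // 2
            for strand, mat in (("+", lat), ("-", rc_lat)):
                ws = _window_scores(codes, mat)
                for i in np.flatnonzero(ws >= t_lat):
                    s = ws[i]
                    p = float(tail[np.searchsorted(scores, s)])
                    win_center = region.start + int(i) + L // 2
                    hits.append(MotifHit(rid, motif.motif_id,
                                         win_center - center, strand,
                                         float(s) * SCORE_GRANULARITY, p))
                    presence.at[rid, motif.motif_id] = 1
    return MotifHitMatrix(presence=presence, hits=hits)


def motif_set_enrichment(
    hit_matrix: MotifHitMatrix,
    peak_classes: Mapping[str, str],
) -> pd.DataFrame:
    """Per-motif per-class enrichment odds ratio and Fisher p with BH q.

    For each (motif, class) a 2x2 table contrasts in-class peaks with and
    without the motif against out-of-class peaks; BH correction runs
    across motifs within each class. Motifs absent from every peak are
    skipped (logged).
    """
    presence = hit_matrix.presence
    labels = pd.Series({p: peak_classes[p] for p in presence.index
                        if p in peak_classes})
    if labels.empty:
        raise ValueError("no peak has a class label")
    classes = sorted(labels.unique())
    rows = []
    for cls in classes:
        in_cls = labels.index[labels == cls]
        out_cls = labels.index[labels != cls]
        motif_rows = []
        for motif_id in presence.columns:
            col = presence[motif_id]
            if col.sum() == 0:
                continue
            a = int(col.loc[in_cls].sum())
            b = len(in_cls) - a
            c = int(col.loc[out_cls].sum())
            d = len(out_cls) - c
            odds, p = stats.fisher_exact([[a, b], [c, d]],
                                         alternative="two-sided")
            motif_rows.append((motif_id, cls, a, len(in_cls), c,
                               len(out_cls), float(odds), float(p)))
        if motif_rows:
            pvals = [r[-1] for r in motif_rows]
            _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
            rows.extend(r + (float(q),) for r, q in zip(motif_rows, qvals))
    skipped = [m for m in presence.columns if presence[m].sum() == 0]
    if skipped:
        logger.info("skipped %d motifs with no hits anywhere", len(skipped))
    return pd.DataFrame(
        rows,
        columns=["motif_id", "peak_class", "hits_in_class", "n_in_class",
                 "hits_out_class", "n_out_class", "odds_ratio", "fisher_p",
                 "q_value"],
    )


def positional_preference(
    hit_matrix: MotifHitMatrix,
    motif_id: str,
    peak_ids: Sequence[str] | None = None,
    bandwidth: float = 10.0,
    grid_step: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Kernel-smoothed density of absolute best-hit offsets from peak center.

    The best (highest-scoring) hit per peak enters the profile. Returns
    (grid of absolute offsets, density, mode) where the mode is the grid
    point of maximum density, or None when there are no hits.
    """
    hits = [h for h in hit_matrix.hits if h.motif_id == motif_id
            and (peak_ids is None or h.peak_id in set(peak_ids))]
    if not hits:
        return np.empty(0), np.empty(0), None
    best: dict[str, MotifHit] = {}
    for h in hits:
        if h.peak_id not in best or h.score_bits > best[h.peak_id].score_bits:
            best[h.peak_id] = h
    offsets = np.array([abs(h.offset) for h in best.values()], dtype=float)
    grid = np.arange(0, offsets.max() + 3 * bandwidth + grid_step, grid_step)
    diff = grid[:, None] - offsets[None, :]
    density = np.exp(-0.5 * (diff / bandwidth) ** 2).sum(axis=1)
    density /= density.sum() * grid_step
    mode = float(grid[int(np.argmax(density))])
    return grid, density, mode


# ---------------------------------------------------------------------------
# permutation region-overlap association
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    observed: int
    perm_mean: float
    perm_sd: float
    z: float  # nan when perm_sd == 0
    empirical_p: float
    n_permutations: int


def _merge_intervals(ivs: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out = [list(pairs[0])]
        for s, e in pairs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=np.int64)
    return merged


def _count_overlaps(
    starts: np.ndarray, ends: np.ndarray, merged: np.ndarray
) -> np.ndarray:
    """Boolean per query: does [start, end) intersect any merged interval?"""
    if merged.size == 0:
        return np.zeros(starts.shape, dtype=bool)
    idx = np.searchsorted(merged[:, 0], ends, side="left") - 1
    hit = idx >= 0
    safe = np.clip(idx, 0, len(merged) - 1)
    return hit & (merged[safe, 1] > starts)


def region_association(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> AssociationResult:
    """Permutation z-score for overlap between two region sets.

    The statistic is the number of ``set_a`` regions overlapping at least
    one ``set_b`` region. Each permutation relocates every ``set_a``
    region uniformly at random within its own chromosome, preserving its
    length (self-overlap between relocated regions is allowed). The
    z-score standardises the observed count against the permutation
    distribution; the empirical p is (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if not set_a:
        raise ValueError("set_a is empty")
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    for iv in set_a:
        if iv.chrom not in chrom_sizes or iv.end > chrom_sizes[iv.chrom]:
            raise ValueError(f"region {iv} outside genome bounds")
    merged_b = _merge_intervals(set_b)
    rng = np.random.default_rng(seed)

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in set_a:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    observed = 0
    perm_counts = np.zeros(n_perm, dtype=np.int64)
    for chrom, ivs in by_chrom.items():
        starts = np.array([iv.start for iv in ivs])
        lengths = np.array([len(iv) for iv in ivs])
        merged = merged_b.get(chrom, np.empty((0, 2), dtype=np.int64))
        observed += int(_count_overlaps(starts, starts + lengths, merged).sum())
        max_start = chrom_sizes[chrom] - lengths  # inclusive upper bound
        rand_starts = rng.integers(0, max_start + 1,
                                   size=(n_perm, len(ivs)))
        overl = _count_overlaps(rand_starts, rand_starts + lengths, merged)
        perm_counts += overl.sum(axis=1)
    mean = float(perm_counts.mean())
    sd = float(perm_counts.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    p = float((1 + np.count_nonzero(perm_counts >= observed)) / (n_perm + 1))
    return AssociationResult(observed, mean, sd, z, p, n_perm)


def row_normalized_scores(z_by_category: Mapping[str, float]) -> dict[str, float]:
    """Divide each category's z-score by the row maximum (as in association
    heatmaps comparing one region set against several categories)."""
    zmax = max(z_by_category.values())
    if zmax == 0:
        raise ValueError("row maximum is zero; cannot normalise")
    return {k: v / zmax for k, v in z_by_category.items()}
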