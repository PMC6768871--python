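"""Consensus OCT4 peak building, occupancy quantification and dynamics classes.

Summit calls from all conditions are merged into fixed-width consensus
regions; each region's occupancy per condition is an RPKM derived from the
maximum pileup depth in the region; peaks changing at least ``fold_cutoff``
between differentiation timepoints are dynamic; and occupancy at 0 h, 96 h
and the OSKM re-induction condition classifies each locus as
pluripotency-exclusive, pluripotency-reaccessed, differentiation-associated
or static.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from plurevert.config import COND_0H, COND_48H, COND_96H, COND_DOX, PipelineConfig
from plurevert.io_formats import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    PeakSummit,
)

logger = logging.getLogger(__name__)

# dynamics class labels
PLURI_EXCLUSIVE = "pluripotency_exclusive"
PLURI_REACCESSED = "pluripotency_reaccessed"
PLURI_OTHER = "pluripotency_other"
DIFFERENTIATION = "differentiation"
STATIC_BOUND = "static_bound"
STATIC_UNBOUND = "static_unbound"

CLASS_LABELS = (
    PLURI_EXCLUSIVE, PLURI_REACCESSED, PLURI_OTHER,
    DIFFERENTIATION, STATIC_BOUND, STATIC_UNBOUND,
)


@dataclass
class ConsensusPeak:
    """A merged binding site with a fixed-width region around its summit."""

    chrom: str
    summit: int
    region: GenomicInterval
    members: list[tuple[str, int, float]]  # (sample_id, summit_pos, score)
    intensity: dict[str, float] = field(default_factory=dict)
    label: str | None = None
    is_dynamic: bool | None = None
    peak_id: str = ""

    def bound(self, condition: str, rpkm_threshold: float) -> bool:
        """Discrete binding call: occupancy at or above the RPKM threshold."""
        return self.intensity[condition] >= rpkm_threshold


@dataclass(frozen=True)
class GeneAssignment:
    peak_id: str
    gene_id: str
    distance_bp: int


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def build_consensus_peaks(
    summits: Iterable[PeakSummit],
    config: PipelineConfig | None = None,
) -> list[ConsensusPeak]:
    """Merge summits within 1 bp of each other into consensus peaks.

    Summits on the same chromosome whose positions differ by at most 1 bp
    are chained transitively into one group. The consensus summit is the
    score-weighted average of member positions (rounded to the nearest
    base, halves away from zero); if every member score is zero the
    unweighted mean is used. The region extends ``region_halfwidth_bp``
    outwards on both sides. The result is independent of input order.
    """
    config = config or PipelineConfig()
    half = config.region_halfwidth_bp
    pool = sorted(summits, key=lambda s: (s.chrom, s.summit_pos, s.sample_id, s.score))
    peaks: list[ConsensusPeak] = []
    group: list[PeakSummit] = []

    def flush() -> None:
        if not group:
            return
        scores = np.array([m.score for m in group])
        positions = np.array([m.summit_pos for m in group], dtype=float)
        if scores.sum() > 0:
            summit = _round_half_away(float(np.average(positions, weights=scores)))
        else:
            logger.info(
                "all-zero scores in merge group at %s:%d; unweighted mean",
                group[0].chrom, group[0].summit_pos,
            )
            summit = _round_half_away(float(positions.mean()))
        region = GenomicInterval(group[0].chrom, max(0, summit - half), summit + half)
        peaks.append(
            ConsensusPeak(
                chrom=group[0].chrom,
                summit=summit,
                region=region,
                members=[(m.sample_id, m.summit_pos, m.score) for m in group],
            )
        )

    for s in pool:
        if group and (s.chrom != group[-1].chrom or s.summit_pos - group[-1].summit_pos > 1):
            flush()
            group = []
        group.append(s)
    flush()
    peaks.sort(key=lambda p: (p.chrom, p.summit))
    for i, p in enumerate(peaks):
        p.peak_id = f"peak_{i:06d}"
    logger.info("merged %d summits into %d consensus peaks",
                len(pool), len(peaks))
    return peaks


def quantify_peak_intensity(
    peaks: Sequence[ConsensusPeak],
    track: CoverageTrack,
    condition: str,
    config: PipelineConfig | None = None,
) -> None:
    """Attach per-condition RPKM occupancy to each peak (in place).

    The read count is the maximum per-base pileup depth within the peak
    region (``intensity_mode='sum'`` uses the total instead), normalised by
    the nominal region length in kb and the library size in millions.
    Regions running past the chromosome end are clipped for the depth query
    but normalised by the nominal length.
    """
    config = config or PipelineConfig()
    length_kb = 2 * config.region_halfwidth_bp / 1000.0
    lib_millions = track.library_size / 1e6
    for p in peaks:
        chrom_len = len(track.depth.get(p.chrom, ()))
        if p.region.end > chrom_len:
            logger.debug("region %s:%d-%d clipped to chromosome end %d",
                         p.chrom, p.region.start, p.region.end, chrom_len)
        depths = track.window(p.chrom, p.region.start, p.region.end)
        reads = int(depths.max()) if config.intensity_mode == "max" else int(depths.sum())
        p.intensity[condition] = reads / (length_kb * lib_millions)


def call_dynamic_peaks(
    peaks: Sequence[ConsensusPeak],
    conditions: Sequence[str] = (COND_0H, COND_48H, COND_96H),
    config: PipelineConfig | None = None,
) -> list[ConsensusPeak]:
    """Flag peaks with >= fold_cutoff occupancy change between any two
    differentiation timepoints; returns the dynamic subset.

    A pseudocount (``dynamic_pseudocount`` RPKM) on both sides keeps the
    ratio defined at zero occupancy. The cutoff is inclusive.
    """
    config = config or PipelineConfig()
    eps = config.dynamic_pseudocount
    dynamic = []
    for p in peaks:
        for c in conditions:
            if c not in p.intensity:
                raise KeyError(
                    f"peak {p.peak_id} has no intensity for condition {c!r}"
                )
        vals = np.array([p.intensity[c] for c in conditions]) + eps
        p.is_dynamic = bool(vals.max() / vals.min() >= config.fold_cutoff)
        if p.is_dynamic:
            dynamic.append(p)
    logger.info("%d of %d peaks dynamic (fold >= %g over %s)",
                len(dynamic), len(peaks), config.fold_cutoff, list(conditions))
    return dynamic


def classify_peak_dynamics(
    peaks: Sequence[ConsensusPeak],
    config: PipelineConfig | None = None,
) -> dict[str, list[ConsensusPeak]]:
    """Assign each peak its occupancy-dynamics class (in place).

    Binding is discretised at ``rpkm_threshold`` (inclusive) in each of
    0 h, 96 h and the re-induction (48 h + dox) condition:

    * bound at 0 h and 96 h -> ``static_bound``
    * unbound at both -> ``static_unbound``
    * bound at 96 h only -> ``differentiation``
    * bound at 0 h only -> pluripotency set, sub-split on the dox
      condition: re-bound under ectopic OSKM -> ``pluripotency_reaccessed``,
      not re-bound -> ``pluripotency_exclusive``, dox occupancy missing ->
      ``pluripotency_other``.
    """
    config = config or PipelineConfig()
    thr = config.rpkm_threshold
    by_class: dict[str, list[ConsensusPeak]] = {c: [] for c in CLASS_LABELS}
    for p in peaks:
        for c in (COND_0H, COND_96H):
            if c not in p.intensity:
                raise KeyError(
                    f"peak {p.peak_id} has no intensity for condition {c!r}"
                )
        b0 = p.bound(COND_0H, thr)
        b96 = p.bound(COND_96H, thr)
        if b0 and b96:
            p.label = STATIC_BOUND
        elif not b0 and not b96:
            p.label = STATIC_UNBOUND
        elif b96:
            p.label = DIFFERENTIATION
        else:  # bound at 0 h only: the pluripotency set
            if COND_DOX not in p.intensity:
                p.label = PLURI_OTHER
            elif p.bound(COND_DOX, thr):
                p.label = PLURI_REACCESSED
            else:
                p.label = PLURI_EXCLUSIVE
        by_class[p.label].append(p)
    for label in CLASS_LABELS:
        logger.info("class %s: %d peaks", label, len(by_class[label]))
    return by_class


def venn_counts(
    sets: Mapping[str, set[str]],
    universe: set[str] | None = None,
) -> dict[tuple[str, ...], int]:
    """Counts for the 7 disjoint regions of a 3-set Venn diagram.

    ``sets`` maps three set names to peak-id sets. Keys of the result are
    sorted tuples of the set names whose exclusive intersection the count
    describes. Counts sum to the size of the union.
    """
    if len(sets) != 3:
        raise ValueError("venn_counts requires exactly three sets")
    names = sorted(sets)
    union = set().union(*sets.values())
    if universe is not None:
        outside = union - universe
        if outside:
            raise ValueError(f"ids outside the universe: {sorted(outside)[:5]}")
    counts: dict[tuple[str, ...], int] = {}
    for mask in range(1, 8):
        included = [names[i] for i in range(3) if mask & (1 << i)]
        excluded = [names[i] for i in range(3) if not mask & (1 << i)]
        region = set.intersection(*(sets[n] for n in included))
        for n in excluded:
            region -= sets[n]
        counts[tuple(included)] = len(region)
    assert sum(counts.values()) == len(union)
    return counts


def assign_nearest_gene(
    peaks: Sequence[ConsensusPeak],
    genes: Sequence[GeneModel],
) -> dict[str, GeneAssignment]:
    """Nearest protein-coding gene by |summit - TSS|, no distance bound.

    Ties break to the lexicographically smallest gene_id. Peaks on
    chromosomes without a protein-coding gene are left unassigned (logged).
    """
    coding = [g for g in genes if g.biotype == "protein_coding"]
    if not coding:
        raise ValueError("gene set contains no protein_coding gene")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in coding:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.tss, g.gene_id))
    out: dict[str, GeneAssignment] = {}
    n_unassigned = 0
    for p in peaks:
        glist = by_chrom.get(p.chrom)
        if not glist:
            n_unassigned += 1
            continue
        tss = np.array([g.tss for g in glist])
        dists = np.abs(tss - p.summit)
        best = dists.min()
        candidates = [g for g, d in zip(glist, dists) if d == best]
        gene = min(candidates, key=lambda g: g.gene_id)
        out[p.peak_id] = GeneAssignment(p.peak_id, gene.gene_id, int(best))
    if n_unassigned:
        logger.info("%d peaks on gene-free chromosomes left unassigned",
                    n_unassigned)
    return out


def annotate_features(
    peaks: Sequence[ConsensusPeak],
    tss_set: Sequence[tuple[str, int]],
    cpg_islands: Sequence[GenomicInterval],
    config: PipelineConfig | None = None,
) -> dict[str, dict[str, bool]]:
    """Per-peak flags: TSS-proximal (< tss_proximal_bp) and CGI-overlapping."""
    config = config or PipelineConfig()
    trees: dict[str, IntervalTree] = {}
    for iv in cpg_islands:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in tss_set:
        tss_by_chrom.setdefault(chrom, [])
        tss_by_chrom[chrom].append(pos)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    flags: dict[str, dict[str, bool]] = {}
    for p in peaks:
        cgi = bool(
            p.chrom in trees and trees[p.chrom].overlap(p.region.start, p.region.end)
        )
        proximal = False
        positions = tss_by_chrom.get(p.chrom)
        if positions is not None and len(positions):
            i = np.searchsorted(positions, p.summit)
            nearest = min(
                abs(int(positions[j]) - p.summit)
                for j in (i - 1, i) if 0 <= j < len(positions)
            )
            proximal = nearest < config.tss_proximal_bp
        flags[p.peak_id] = {"tss_proximal": proximal, "cgi_overlap": cgi}
    return flags
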