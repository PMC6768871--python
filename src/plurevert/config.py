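"""Pipeline configuration.

Every fixed analysis constant (binding threshold, fold cutoffs, window
geometries, significance cutoffs) lives here as a config default rather than
a hard-coded literal, so each stage can report the values it actually used
and alternative settings can be explored from a single text file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

# Condition labels used throughout the occupancy-dynamics analysis: samples
# taken at 0, 48 and 96 h of differentiation, plus the re-induction sample
# (48 h of differentiation followed by 48 h of ectopic OSKM expression).
COND_0H = "0h"
COND_48H = "48h"
COND_96H = "96h"
COND_DOX = "48h+dox"
DIFF_CONDITIONS = (COND_0H, COND_48H, COND_96H)
ALL_CONDITIONS = (COND_0H, COND_48H, COND_96H, COND_DOX)


@dataclass
class PipelineConfig:
    """All tunable analysis constants with their default values.

    Attributes
    ----------
    rpkm_threshold:
        Peak-occupancy RPKM at or above which a locus is called bound
        in a condition (discrete binding events).
    fold_cutoff:
        Minimum fold change in peak intensity between any two
        differentiation timepoints for a peak to be called dynamic.
    dynamic_pseudocount:
        RPKM pseudocount added to both sides of the peak fold-change
        ratio so ratios are defined at zero intensity.
    region_halfwidth_bp:
        Half-width of the fixed consensus peak region; summits are
        extended outwards by this many bp in each direction.
    composite_halfwidth_bp:
        Half-width of the window around peak summits for composite
        (metaplot) profiles and density heatmaps.
    heatmap_bin_bp:
        Column width of read-density heatmaps.
    heatmap_cap_quantile:
        Quantile at which heatmap signal is capped to remove outliers.
    meth_window_bp / meth_slide_bp:
        Sliding-window geometry for methylation composite profiles.
    meth_min_coverage:
        Minimum read coverage for a CpG to enter any methylation
        statistic.
    meth_span_bp / meth_bin_bp:
        Window span and bin width for per-region binned methylation.
    gfp_control_threshold_fraction:
        A pixel is GFP-positive if its intensity is strictly above this
        fraction of the undifferentiated-control reference intensity.
    fate_gfp_low / fate_gfp_high:
        Terminal GFP+ area-fraction cut points for the four-way colony
        fate classification.
    motif_p_threshold:
        Per-position motif-match p-value below which a window counts as
        a motif occurrence.
    expr_fold_cutoff / expr_q_cutoff / expr_min_fpkm:
        Dynamic-gene criteria: minimum fold change, FDR q-value cutoff
        and minimum expression of the higher member of the comparison.
    kmeans_k_min / kmeans_k_max:
        Range of k scanned when choosing the trajectory-cluster count by
        silhouette.
    n_permutations:
        Default permutation count for the region-association test.
    tss_proximal_bp:
        Distance below which a peak is TSS-proximal.
    intensity_mode:
        "max" uses the maximum per-base pileup in the peak region as the
        read count entering RPKM; "sum" uses the total.
    weighted_region_methylation:
        If True, region mean methylation weights CpGs by coverage
        instead of averaging per-CpG fractions.
    random_seed:
        Seed for all stochastic steps (k-means restarts, permutations).
    """

    rpkm_threshold: float = 3.0
    fold_cutoff: float = 2.0
    dynamic_pseudocount: float = 0.1
    region_halfwidth_bp: int = 300
    composite_halfwidth_bp: int = 2000
    heatmap_bin_bp: int = 10
    heatmap_cap_quantile: float = 0.99
    meth_window_bp: int = 100
    meth_slide_bp: int = 25
    meth_min_coverage: int = 3
    meth_span_bp: int = 5000
    meth_bin_bp: int = 50
    gfp_control_threshold_fraction: float = 0.20
    fate_gfp_low: float = 0.2
    fate_gfp_high: float = 0.8
    motif_p_threshold: float = 1e-4
    expr_fold_cutoff: float = 2.0
    expr_q_cutoff: float = 0.05
    expr_min_fpkm: float = 1.0
    kmeans_k_min: int = 2
    kmeans_k_max: int = 20
    n_permutations: int = 1000
    tss_proximal_bp: int = 2000
    intensity_mode: str = "max"
    weighted_region_methylation: bool = False
    library_size_override: dict = field(default_factory=dict)
    random_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "rpkm_threshold",
            "fold_cutoff",
            "region_halfwidth_bp",
            "composite_halfwidth_bp",
            "heatmap_bin_bp",
            "meth_window_bp",
            "meth_slide_bp",
            "meth_min_coverage",
            "gfp_control_threshold_fraction",
            "motif_p_threshold",
            "expr_fold_cutoff",
            "expr_min_fpkm",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be > 0")
        if not (2 <= self.kmeans_k_min <= self.kmeans_k_max):
            raise ValueError("k range must satisfy 2 <= k_min <= k_max")
        if self.intensity_mode not in ("max", "sum"):
            raise ValueError("intensity_mode must be 'max' or 'sum'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a flat key/value YAML file.

        Unknown keys raise, so typos in a config file fail loudly.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
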