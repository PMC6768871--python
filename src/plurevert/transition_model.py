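"""Colony-reversion quantification and transition-time estimation.

Colonies re-seeded after increasing durations of differentiation either
revert to a NANOG/GFP-positive pluripotent state or fail to; the fraction of
GFP-positive colony area, normalised to undifferentiated controls, falls
with differentiation time along a sigmoid. This module implements:

* GFP pixel thresholding against an undifferentiated-control reference and
  normalisation of colony fractions to the control,
* the decile-grouped sigmoid estimator of the transition time (the
  differentiation duration at which the fitted GFP+ fraction crosses 0.5),
* colony fate classification into four terminal outcomes,
* (segmented) log-linear doubling-rate estimation of GFP reporter signal.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from plurevert.config import PipelineConfig

logger = logging.getLogger(__name__)

FATE_GFP_POSITIVE = "gfp_positive"
FATE_GFP_MIXED = "gfp_mixed"
FATE_GFP_NEG_AB_POS = "gfp_neg_ab_pos"
FATE_GFP_NEG_AB_NEG = "gfp_neg_ab_neg"
FATES = (FATE_GFP_POSITIVE, FATE_GFP_MIXED, FATE_GFP_NEG_AB_POS,
         FATE_GFP_NEG_AB_NEG)


@dataclass
class TransitionFit:
    """One decile group's fitted decreasing 4-parameter logistic.

    f(t) = b + (a - b) / (1 + exp((t - t0) / s)), s > 0.
    ``t_half`` is the time where f equals 0.5 on the normalised scale,
    defined only when 0.5 lies strictly between the curve's extremes over
    the fitted time range.
    """

    group_id: int
    a: float
    b: float
    t0: float
    s: float
    sse: float
    converged: bool
    t_half: float | None = None


@dataclass
class TransitionEstimate:
    condition: str
    t_half_by_decile: dict[int, float]
    median_h: float
    iqr: tuple[float, float]
    fits: list[TransitionFit]


@dataclass(frozen=True)
class FateCall:
    colony_id: str
    fate: str


def sigmoid(t: np.ndarray, a: float, b: float, t0: float, s: float) -> np.ndarray:
    """Decreasing logistic from upper plateau ``a`` to lower plateau ``b``."""
    return b + (a - b) / (1.0 + np.exp((np.asarray(t, dtype=float) - t0) / s))


# ---------------------------------------------------------------------------
# pixel-level quantification
# ---------------------------------------------------------------------------


def gfp_positive_fraction(
    pixel_intensities: np.ndarray,
    control_reference: float,
    config: PipelineConfig | None = None,
) -> float:
    """Fraction of RFP-segmented pixels strictly above the GFP threshold.

    The threshold is ``gfp_control_threshold_fraction`` (default 20%) of the
    undifferentiated-control reference intensity. Pixels exactly at the
    threshold count as negative.
    """
    config = config or PipelineConfig()
    px = np.asarray(pixel_intensities, dtype=float)
    if px.size == 0:
        raise ValueError("colony has zero RFP-segmented area")
    threshold = config.gfp_control_threshold_fraction * control_reference
    return float(np.count_nonzero(px > threshold) / px.size)


def normalize_to_control(
    fractions: np.ndarray, control_fractions: np.ndarray
) -> np.ndarray:
    """Divide each GFP+ fraction by the median of the 0 h control fractions.

    Values may exceed 1; no clipping is applied.
    """
    ref = float(np.median(np.asarray(control_fractions, dtype=float)))
    if ref == 0:
        raise ValueError("control median is zero; cannot normalise")
    return np.asarray(fractions, dtype=float) / ref


# ---------------------------------------------------------------------------
# sigmoid fitting
# ---------------------------------------------------------------------------

_BOUNDS_LO = np.array([0.5, -0.1, -np.inf, 1e-6])
_BOUNDS_HI = np.array([1.5, 0.5, np.inf, 50.0])


def fit_sigmoid(
    times: np.ndarray,
    fractions: np.ndarray,
    group_id: int = 0,
) -> TransitionFit:
    """Least-squares fit of the decreasing 4-parameter logistic.

    Bounds: a in [0.5, 1.5], b in [-0.1, 0.5], t0 within the observed time
    range, s in (0, 50]. A fixed multi-start grid places t0 at the
    quartiles of the time range; the start with the lowest SSE wins, ties
    to the smallest t0, making the fit deterministic. ``t_half`` is solved
    analytically from the fitted parameters.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct times to fit a sigmoid")
    if not np.all(np.isfinite(y)):
        raise ValueError("fractions must be finite")
    tmin, tmax = float(t.min()), float(t.max())
    lo = _BOUNDS_LO.copy()
    hi = _BOUNDS_HI.copy()
    lo[2], hi[2] = tmin, tmax

    def residuals(p: np.ndarray) -> np.ndarray:
        return sigmoid(t, *p) - y

    best: tuple[float, float, np.ndarray] | None = None  # (sse, t0_start, params)
    converged = False
    for q in (0.25, 0.5, 0.75):
        t0_start = tmin + q * (tmax - tmin)
        x0 = np.array([1.0, 0.0, t0_start, 5.0])
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi))
        except Exception:  # pragma: no cover - defensive
            continue
        if not res.success:
            continue
        converged = True
        sse = float(np.sum(res.fun**2))
        key = (sse, t0_start)
        if best is None or key < (best[0], best[1]):
            best = (sse, t0_start, res.x)
    if best is None:
        return TransitionFit(group_id, np.nan, np.nan, np.nan, np.nan,
                             np.inf, converged=False)
    a, b, t0, s = (float(v) for v in best[2])
    fit = TransitionFit(group_id, a, b, t0, s, best[0], converged=True)
    f_lo, f_hi = sigmoid(np.array([tmax]), a, b, t0, s)[0], \
        sigmoid(np.array([tmin]), a, b, t0, s)[0]
    if min(f_lo, f_hi) < 0.5 < max(f_lo, f_hi) and b < 0.5 < a:
        fit.t_half = float(t0 + s * np.log((a - b) / (0.5 - b) - 1.0))
    else:
        logger.debug("group %d: fitted curve does not cross 0.5", group_id)
    return fit


def decile_groups(values: np.ndarray) -> np.ndarray:
    """Group index (1..10) of each observation by within-sample rank.

    Observation with rank r (1-based, ties broken by order after a stable
    sort) of n falls in group g iff its percentile 100*r/n lies in
    ((g-1)*10, g*10]. Every observation lands in exactly one group.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    groups = np.ceil(10.0 * ranks / n).astype(int)
    return np.clip(groups, 1, 10)


def estimate_transition(
    colonies: pd.DataFrame,
    condition: str,
    config: PipelineConfig | None = None,
    min_converged: int = 5,
) -> TransitionEstimate:
    """Decile-grouped sigmoid estimate of the reversion transition time.

    ``colonies`` must have columns ``differentiation_time_h`` and
    ``fraction`` (normalised GFP+ fraction), with replicates already
    pooled. At each differentiation timepoint observations are ranked and
    split into per-10th-percentile groups; group means over time form ten
    curves, each fitted with :func:`fit_sigmoid`; the estimate is the
    median (and 25th/75th percentile) of the converged half-crossing times.
    """
    config = config or PipelineConfig()
    required = {"differentiation_time_h", "fraction"}
    if not required <= set(colonies.columns):
        raise ValueError(f"colonies table needs columns {sorted(required)}")
    df = colonies.copy()
    df["decile"] = 0
    for t, idx in df.groupby("differentiation_time_h").groups.items():
        vals = df.loc[idx, "fraction"].to_numpy()
        df.loc[idx, "decile"] = decile_groups(vals)
    group_means = (
        df.groupby(["decile", "differentiation_time_h"])["fraction"]
        .mean()
        .reset_index()
    )
    fits: list[TransitionFit] = []
    for g in range(1, 11):
        sub = group_means[group_means["decile"] == g]
        if len(sub) < 4:
            continue
        fits.append(
            fit_sigmoid(
                sub["differentiation_time_h"].to_numpy(),
                sub["fraction"].to_numpy(),
                group_id=g,
            )
        )
    t_halves = {f.group_id: f.t_half for f in fits
                if f.converged and f.t_half is not None}
    if len(t_halves) < min_converged:
        raise RuntimeError(
            f"only {len(t_halves)} decile fits crossed 0.5 "
            f"(need >= {min_converged}); collect more data"
        )
    vals = np.array(sorted(t_halves.values()))
    estimate = TransitionEstimate(
        condition=condition,
        t_half_by_decile=t_halves,
        median_h=float(np.median(vals)),
        iqr=(float(np.percentile(vals, 25)), float(np.percentile(vals, 75))),
        fits=fits,
    )
    logger.info("condition %s: median transition %.1f h, IQR %.1f-%.1f h",
                condition, estimate.median_h, *estimate.iqr)
    return estimate


# ---------------------------------------------------------------------------
# colony fate classification
# ---------------------------------------------------------------------------


def classify_colony_gfp(
    mean_gfp: float, background_distribution: np.ndarray
) -> str:
    """GFP-positive iff mean colony GFP is strictly above the background max."""
    bg = np.asarray(background_distribution, dtype=float)
    if bg.size == 0:
        raise ValueError("background distribution is empty")
    return ("gfp_positive_colony" if mean_gfp > bg.max()
            else "gfp_negative_colony")


def classify_fate(
    colony_id: str,
    terminal_gfp_fraction: float,
    antibody: str,
    config: PipelineConfig | None = None,
) -> FateCall | None:
    """Assign one of four terminal fate outcomes.

    Rule cascade on terminal GFP+ area fraction g and NANOG antibody
    status: g >= 0.8 -> uniformly reporter-positive; 0.2 <= g < 0.8 with
    antibody+ -> mixed; g < 0.2 with antibody+ -> reporter-silent but
    NANOG+; otherwise reporter- and antibody-negative. Colonies without an
    antibody call are excluded (returns None, logged).
    """
    config = config or PipelineConfig()
    g = terminal_gfp_fraction
    lo, hi = config.fate_gfp_low, config.fate_gfp_high
    if antibody not in ("positive", "negative"):
        logger.info("colony %s: antibody status missing; fate undetermined",
                    colony_id)
        return None
    if g >= hi:
        fate = FATE_GFP_POSITIVE
    elif g >= lo:
        if antibody == "positive":
            fate = FATE_GFP_MIXED
        else:
            logger.warning(
                "colony %s: intermediate GFP (%.2f) but antibody-negative",
                colony_id, g,
            )
            fate = FATE_GFP_NEG_AB_NEG
    elif antibody == "positive":
        fate = FATE_GFP_NEG_AB_POS
    else:
        fate = FATE_GFP_NEG_AB_NEG
    return FateCall(colony_id, fate)


def classify_fates(
    colonies: pd.DataFrame, config: PipelineConfig | None = None
) -> list[FateCall]:
    """Fate-call every colony from its terminal assay timepoint."""
    config = config or PipelineConfig()
    calls = []
    for colony_id, sub in colonies.groupby("colony_id"):
        terminal = sub.loc[sub["assay_time_h"].idxmax()]
        g = terminal["gfp_pos_px"] / terminal["rfp_area_px"]
        call = classify_fate(str(colony_id), float(g),
                             str(terminal["antibody"]), config)
        if call is not None:
            calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# doubling-rate estimation
# ---------------------------------------------------------------------------


@dataclass
class DoublingFit:
    """Log-linear fit of GFP+ pixel growth within one time window."""

    start_h: float
    end_h: float
    slope_log2_per_h: float
    doubling_time_h: float | None  # None when slope <= 0
    n_points: int


def _ols_doubling(t: np.ndarray, log2n: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, log2n, 1)
    return float(slope), float(intercept)


def fit_window(times: np.ndarray, counts: np.ndarray) -> DoublingFit:
    t = np.asarray(times, dtype=float)
    n = np.asarray(counts, dtype=float)
    keep = n > 0
    if np.count_nonzero(~keep):
        logger.info("excluding %d zero-count points from doubling fit",
                    int(np.count_nonzero(~keep)))
    t, n = t[keep], n[keep]
    if len(t) < 3:
        raise ValueError("need >= 3 positive points per window")
    slope, _ = _ols_doubling(t, np.log2(n))
    # slopes at float-precision level are flat series, not growth
    doubling = 1.0 / slope if slope > 1e-12 else None
    return DoublingFit(float(t.min()), float(t.max()), slope, doubling, len(t))


def estimate_doubling(
    times: np.ndarray,
    counts: np.ndarray,
    windows: Sequence[tuple[float, float]] | None = None,
    n_breakpoints: int = 2,
) -> list[DoublingFit]:
    """Per-window GFP doubling times from log2 pixel counts.

    With explicit ``windows`` (closed intervals in hours) each is fitted by
    OLS of log2 counts on time; doubling time is 1/slope. Without windows a
    segmented fit searches all breakpoint pairs on the observed times
    (each segment >= 3 points, exhaustive, minimum total SSE) and returns
    one fit per segment.
    """
    t = np.asarray(times, dtype=float)
    n = np.asarray(counts, dtype=float)
    if windows is not None:
        return [
            fit_window(t[(t >= lo) & (t <= hi)], n[(t >= lo) & (t <= hi)])
            for lo, hi in windows
        ]
    keep = n > 0
    t, n = t[keep], n[keep]
    y = np.log2(n)
    m = len(t)
    if m < 3 * (n_breakpoints + 1):
        raise ValueError("too few points for the requested segmentation")
    order = np.argsort(t)
    t, y = t[order], y[order]

    def seg_sse(i: int, j: int) -> float:
        slope, intercept = np.polyfit(t[i:j], y[i:j], 1)
        return float(np.sum((y[i:j] - slope * t[i:j] - intercept) ** 2))

    if n_breakpoints == 0:
        cuts: tuple[int, ...] = ()
    else:
        best_sse = np.inf
        cuts = ()
        # breakpoints are indices where a new segment starts
        for combo in itertools.combinations(range(3, m - 2), n_breakpoints):
            ok = all(b - a >= 3 for a, b in zip((0,) + combo, combo + (m,)))
            if not ok:
                continue
            sse = sum(seg_sse(a, b) for a, b in zip((0,) + combo, combo + (m,)))
            if sse < best_sse - 1e-12:
                best_sse = sse
                cuts = combo
    fits = []
    for a, b in zip((0,) + cuts, cuts + (m,)):
        fits.append(fit_window(t[a:b], 2.0 ** y[a:b]))
    return fits
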