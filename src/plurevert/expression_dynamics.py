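"""Dynamic-gene calling, trajectory clustering and gene-set overlap tests.

Genes changing significantly between any two differentiation timepoints
(fold change >= 2, q < 0.05, expression >= 1 FPKM in that comparison) are
"dynamic"; their Z-scored trajectories are clustered by k-means, with k
chosen by the silhouette score over a scanned range, and when three
clusters emerge they are named early (decreasing), intermediate (transient
bump) and late (increasing) from centroid shape. OSKM responsiveness
applies the same criteria to time-matched -dox/+dox comparisons. Overlaps
between gene sets are scored by the hypergeometric upper tail and Fisher's
exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from plurevert.config import PipelineConfig

logger = logging.getLogger(__name__)

CLUSTER_EARLY = "early"
CLUSTER_INTERMEDIATE = "intermediate"
CLUSTER_LATE = "late"


@dataclass
class TrajectoryCluster:
    labels: dict[str, str]  # gene_id -> cluster label
    centroids: dict[str, np.ndarray]  # label -> Z-scored mean trajectory
    timepoints: list
    chosen_k: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class OverlapResult:
    overlap: int
    size_a: int
    size_b: int
    universe: int
    hypergeom_p: float
    log10_hypergeom_p: float
    odds_ratio: float
    fisher_p: float


def _effective_fold(fold: np.ndarray) -> np.ndarray:
    """Fold change as a magnitude >= 1, direction-agnostic."""
    fold = np.asarray(fold, dtype=float)
    with np.errstate(divide="ignore"):
        return np.maximum(fold, np.where(fold > 0, 1.0 / fold, np.inf))


def call_dynamic_genes(
    expr: pd.DataFrame,
    comparisons: pd.DataFrame,
    sample_meta: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> set[str]:
    """Genes with a significant change between some pair of timepoints.

    A gene is dynamic iff some differentiation-timepoint comparison has
    q < ``expr_q_cutoff``, fold change >= ``expr_fold_cutoff`` (in either
    direction), and the more expressed member of the pair averages at
    least ``expr_min_fpkm``.

    ``expr`` is genes x samples FPKM; ``sample_meta`` (indexed by sample)
    needs ``timepoint`` and ``dox`` columns; ``comparisons`` holds gene,
    cond_a, cond_b, fold_change (mean_b / mean_a), q_value rows for the
    -dox differentiation course.
    """
    config = config or PipelineConfig()
    if comparisons.empty:
        raise ValueError("no comparison records supplied")
    group_mean = _group_means(expr, sample_meta)
    dynamic: set[str] = set()
    cmp = comparisons.copy()
    cmp["eff_fold"] = _effective_fold(cmp["fold_change"].to_numpy())
    for row in cmp.itertuples(index=False):
        if row.q_value >= config.expr_q_cutoff:
            continue
        if row.eff_fold < config.expr_fold_cutoff:
            continue
        try:
            m = max(group_mean.at[row.gene, row.cond_a],
                    group_mean.at[row.gene, row.cond_b])
        except KeyError as exc:
            raise ValueError(
                f"comparison references unknown gene/condition: {exc}"
            ) from exc
        if m >= config.expr_min_fpkm:
            dynamic.add(row.gene)
    logger.info("%d of %d genes called dynamic", len(dynamic), expr.shape[0])
    return dynamic


def _group_means(expr: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Mean FPKM per (gene, condition); condition = '<timepoint>[+dox]'."""
    tp = sample_meta["timepoint"].map(
        lambda t: f"{t:g}" if isinstance(t, (int, float, np.floating)) else str(t)
    )
    dox = sample_meta["dox"] if "dox" in sample_meta else pd.Series(
        False, index=sample_meta.index
    )
    cond = tp + np.where(dox.astype(bool), "+dox", "")
    return expr.T.groupby(cond.loc[expr.columns].values).mean().T


def trajectory_matrix(
    expr: pd.DataFrame, sample_meta: pd.DataFrame, genes: set[str]
) -> tuple[np.ndarray, list[str], list]:
    """Z-scored per-gene mean trajectory over -dox timepoints.

    Constant genes (zero variance) are excluded with a log entry.
    """
    meta = sample_meta.loc[expr.columns]
    no_dox = meta.index[~meta.get("dox", pd.Series(False, index=meta.index)).astype(bool)]
    sub = expr.loc[sorted(genes), no_dox]
    tp = meta.loc[no_dox, "timepoint"]
    means = sub.T.groupby(tp.values).mean().T
    timepoints = sorted(means.columns)
    means = means[timepoints]
    mat = means.to_numpy(dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    if np.count_nonzero(~keep):
        logger.info("excluding %d constant-trajectory genes from clustering",
                    int(np.count_nonzero(~keep)))
    z = (mat[keep] - mu[keep]) / sd[keep]
    return z, list(means.index[keep]), timepoints


def cluster_trajectories(
    expr: pd.DataFrame,
    sample_meta: pd.DataFrame,
    dynamic_genes: set[str],
    config: PipelineConfig | None = None,
    silhouette_subsample: int = 2000,
) -> TrajectoryCluster:
    """k-means clustering of Z-scored trajectories with silhouette-chosen k.

    For each k in the configured range, k-means runs with a fixed seed and
    10 restarts; the k maximising the mean Euclidean silhouette (computed
    on at most ``silhouette_subsample`` genes) wins. When the chosen k is
    3, clusters are named by centroid shape (time of centroid maximum:
    earliest -> early, latest -> late, middle -> intermediate); otherwise
    generic labels c1..ck are used with a warning.
    """
    config = config or PipelineConfig()
    z, gene_ids, timepoints = trajectory_matrix(expr, sample_meta, dynamic_genes)
    n = len(gene_ids)
    k_max = min(config.kmeans_k_max, n - 1)
    if n < config.kmeans_k_min + 1:
        raise ValueError("too few dynamic genes to cluster")
    rng = np.random.default_rng(config.random_seed)
    sil_idx = (np.sort(rng.choice(n, silhouette_subsample, replace=False))
               if n > silhouette_subsample else np.arange(n))
    silhouettes: dict[int, float] = {}
    models: dict[int, KMeans] = {}
    for k in range(config.kmeans_k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=config.random_seed)
        labels = km.fit_predict(z)
        sub_labels = labels[sil_idx]
        if len(np.unique(sub_labels)) < 2:
            silhouettes[k] = -1.0
        else:
            silhouettes[k] = float(silhouette_score(z[sil_idx], sub_labels))
        models[k] = km
    chosen_k = max(silhouettes, key=lambda k: (silhouettes[k], -k))
    km = models[chosen_k]
    labels = km.labels_
    centroids = km.cluster_centers_
    if chosen_k == 3:
        argmaxes = centroids.argmax(axis=1)
        # order clusters by when their centroid peaks; ties by initial level
        order = sorted(range(3), key=lambda c: (argmaxes[c], -centroids[c, 0]))
        name_of = {order[0]: CLUSTER_EARLY, order[1]: CLUSTER_INTERMEDIATE,
                   order[2]: CLUSTER_LATE}
    else:
        logger.warning("silhouette chose k=%d != 3; using generic labels",
                       chosen_k)
        name_of = {c: f"c{c + 1}" for c in range(chosen_k)}
    label_map = {g: name_of[c] for g, c in zip(gene_ids, labels)}
    centroid_map = {name_of[c]: centroids[c] for c in range(chosen_k)}
    logger.info("chosen k=%d (silhouette %.3f)", chosen_k,
                silhouettes[chosen_k])
    return TrajectoryCluster(
        labels=label_map,
        centroids=centroid_map,
        timepoints=timepoints,
        chosen_k=chosen_k,
        silhouette_by_k=silhouettes,
    )


def call_responsive(
    comparisons: pd.DataFrame,
    timepoint,
    expr: pd.DataFrame | None = None,
    sample_meta: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> dict[str, str]:
    """OSKM responsiveness at one timepoint from -dox/+dox comparisons.

    Applies the dynamic-gene thresholds to the time-matched -dox (cond_a)
    vs +dox (cond_b) comparison; direction comes from the fold-change
    sign: fold > 1 means induced by OSKM, fold < 1 repressed.
    """
    config = config or PipelineConfig()
    tp = str(timepoint)
    sel = comparisons[
        (comparisons["cond_a"] == tp) & (comparisons["cond_b"] == tp + "+dox")
    ]
    if sel.empty:
        raise ValueError(f"no -dox/+dox comparison records at {timepoint!r}")
    group_mean = (_group_means(expr, sample_meta)
                  if expr is not None and sample_meta is not None else None)
    out: dict[str, str] = {}
    eff = _effective_fold(sel["fold_change"].to_numpy())
    for row, eff_fold in zip(sel.itertuples(index=False), eff):
        responsive = (row.q_value < config.expr_q_cutoff
                      and eff_fold >= config.expr_fold_cutoff)
        if responsive and group_mean is not None:
            m = max(group_mean.at[row.gene, row.cond_a],
                    group_mean.at[row.gene, row.cond_b])
            responsive = m >= config.expr_min_fpkm
        if not responsive:
            out[row.gene] = "unresponsive"
        else:
            out[row.gene] = "induced" if row.fold_change > 1 else "repressed"
    return out


def overlap_test(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> OverlapResult:
    """Hypergeometric and Fisher's-exact association of two gene sets.

    The hypergeometric p is the upper tail P(X >= overlap) of drawing
    |A| items from a universe containing |B| successes. The Fisher test is
    two-sided on the 2x2 membership table; the odds ratio is the sample
    (cross-product) ratio.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    k = len(set_a & set_b)
    p_hyper = float(stats.hypergeom.sf(k - 1, n, len(set_b), len(set_a)))
    p_hyper = min(p_hyper, 1.0)
    both = k
    a_only = len(set_a) - k
    b_only = len(set_b) - k
    neither = n - len(set_a | set_b)
    table = [[both, a_only], [b_only, neither]]
    odds, p_fisher = stats.fisher_exact(table, alternative="two-sided")
    return OverlapResult(
        overlap=k,
        size_a=len(set_a),
        size_b=len(set_b),
        universe=n,
        hypergeom_p=p_hyper,
        log10_hypergeom_p=float(np.log10(p_hyper)) if p_hyper > 0 else -np.inf,
        odds_ratio=float(odds),
        fisher_p=float(p_fisher),
    )
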