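"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one class of input the pipeline consumes — a small
mammalian-like genome with CpG islands, condition-specific TF-binding
pileups with five planted occupancy-dynamics classes, colony-reversion
time courses following a decreasing logistic, expression time courses with
four trajectory archetypes, per-CpG methylation with class-dependent
means, and motif instances embedded at controlled offsets — and returns
the emitted records together with a :class:`SyntheticTruth` that tests use
for parameter recovery.

All generators are pure functions of their arguments and a seed: the same
seed yields byte-identical output files. Child random streams are derived
from the global seed through fixed spawn keys, so adding a generator never
shifts the streams of existing ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from plurevert.config import (
    ALL_CONDITIONS,
    COND_0H,
    COND_48H,
    COND_96H,
    COND_DOX,
    PipelineConfig,
)
from plurevert.io_formats import (
    CoverageTrack,
    GenomicInterval,
    MethylationRecord,
    PeakSummit,
)
from plurevert.peak_dynamics import (
    DIFFERENTIATION,
    PLURI_EXCLUSIVE,
    PLURI_REACCESSED,
    STATIC_BOUND,
    STATIC_UNBOUND,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"

# fixed spawn keys: one independent random stream per generator
_STREAMS = {
    "genome": 0,
    "peaks": 1,
    "colonies": 2,
    "expression": 3,
    "methylation": 4,
    "motifs": 5,
}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator-specific stream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized alongside the generated data."""

    peaks: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    colonies: pd.DataFrame | None = None
    methylation_means: dict = field(default_factory=dict)
    motif_placements: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def generate_genome(
    seed: int,
    chrom_sizes: Mapping[str, int],
    n_cpg_islands: int = 10,
    cpg_depletion: float = 0.8,
    island_gc: float = 0.6,
) -> tuple[dict[str, str], list[GenomicInterval]]:
    """A random genome with depleted CpG background and CpG islands.

    Background bases are ~25% each, with CpG dinucleotides thinned to
    roughly one fifth of the i.i.d. expectation (the mammalian-like
    depletion). Islands are 500-2000 bp stretches with elevated G+C and no
    CpG depletion, giving observed/expected CpG well above 0.6.
    """
    for chrom, size in chrom_sizes.items():
        if size < 10_000:
            raise ValueError(f"chromosome {chrom} shorter than 10 kb")
    rng = child_rng(seed, "genome")
    genome: dict[str, str] = {}
    codes: dict[str, np.ndarray] = {}
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        seq = rng.integers(0, 4, size=size)
        # thin CpG dinucleotides: replace the G of most CG pairs
        cg = np.flatnonzero((seq[:-1] == 1) & (seq[1:] == 2))
        kill = cg[rng.random(len(cg)) < cpg_depletion] + 1
        seq[kill] = np.array([0, 1, 3])[rng.integers(0, 3, size=len(kill))]
        codes[chrom] = seq
    # islands: non-overlapping intervals with CpG-rich sequence
    islands: list[GenomicInterval] = []
    total = sum(chrom_sizes.values())
    if n_cpg_islands * 2000 > 0.3 * total:
        raise ValueError("island count infeasible for genome size")
    chroms = sorted(chrom_sizes)
    probs = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(islands) < n_cpg_islands:
        attempts += 1
        if attempts > 100 * max(1, n_cpg_islands):
            raise RuntimeError("could not place CpG islands without overlap")
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        length = int(rng.integers(500, 2001))
        start = int(rng.integers(0, chrom_sizes[chrom] - length))
        if any(start < e and s < start + length for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, start + length))
        islands.append(GenomicInterval(chrom, start, start + length))
        gc_half = island_gc / 2
        at_half = (1 - island_gc) / 2
        codes[chrom][start : start + length] = rng.choice(
            4, size=length, p=[at_half, gc_half, gc_half, at_half]
        )
    islands.sort()
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    for chrom in chroms:
        genome[chrom] = base_arr[codes[chrom]].tobytes().decode()
    return genome, islands


# ---------------------------------------------------------------------------
# peak landscape
# ---------------------------------------------------------------------------

# per-class truth: which conditions carry a binding-level pileup
_CLASS_OCCUPANCY: dict[str, dict[str, bool]] = {
    PLURI_EXCLUSIVE: {COND_0H: True, COND_48H: True, COND_96H: False,
                      COND_DOX: False},
    PLURI_REACCESSED: {COND_0H: True, COND_48H: False, COND_96H: False,
                       COND_DOX: True},
    DIFFERENTIATION: {COND_0H: False, COND_48H: False, COND_96H: True,
                      COND_DOX: False},
    STATIC_BOUND: {COND_0H: True, COND_48H: True, COND_96H: True,
                   COND_DOX: True},
    STATIC_UNBOUND: {COND_0H: False, COND_48H: False, COND_96H: False,
                     COND_DOX: False},
}

# background depth per condition; libraries differ up to ~3-fold so that
# normalisation is actually exercised
_COND_DEPTH = {COND_0H: 5, COND_48H: 11, COND_96H: 7, COND_DOX: 14}


def generate_peak_landscape(
    genome: Mapping[str, str],
    n_per_class: Mapping[str, int] | int,
    seed: int,
    snr: float = 10.0,
    config: PipelineConfig | None = None,
    pileup_sd_bp: float = 80.0,
) -> tuple[dict[str, list[PeakSummit]], dict[str, CoverageTrack], SyntheticTruth]:
    """Summits and coverage per condition with five planted dynamics classes.

    Each planted peak emits a Gaussian fragment pileup (sd ~80 bp around
    its summit) in the conditions where its class is bound, with expected
    maximum RPKM twice the binding threshold when bound and half the
    threshold when unbound; a constant background depth per condition sets
    library sizes apart by more than 2-fold. Peak heights carry
    multiplicative noise of relative sd 1/snr. Summit calls get a 0/+1 bp
    positional jitter per condition so consensus merging has real work to
    do; unbound-everywhere peaks appear as a single weak (spurious) summit
    call in the 0 h sample so they enter the consensus universe.
    """
    config = config or PipelineConfig()
    rng = child_rng(seed, "peaks")
    if isinstance(n_per_class, int):
        n_per_class = {c: n_per_class for c in _CLASS_OCCUPANCY}
    unknown = set(n_per_class) - set(_CLASS_OCCUPANCY)
    if unknown:
        raise ValueError(f"unknown peak classes: {sorted(unknown)}")

    chroms = sorted(genome)
    sizes = {c: len(genome[c]) for c in chroms}
    total = sum(sizes.values())
    # with max-pileup RPKM and a flat background, the background RPKM is
    # fixed by geometry alone: depth / (0.6 kb x depth*G/1e6) = 1e6/(0.6*G);
    # the genome must be large enough that background stays below the
    # unbound occupancy target
    length_kb = 2 * config.region_halfwidth_bp / 1000.0
    background_rpkm = 1e6 / (length_kb * total)
    unbound_rpkm = 0.5 * config.rpkm_threshold
    if background_rpkm >= unbound_rpkm:
        raise ValueError(
            f"genome of {total} bp gives background {background_rpkm:.2f} "
            f"RPKM >= unbound target {unbound_rpkm:.2f}; use a genome of "
            f"at least {int(1e6 / (length_kb * unbound_rpkm)) + 1} bp"
        )
    min_sep = 4 * config.region_halfwidth_bp  # 2x region width
    margin = 2 * config.region_halfwidth_bp + 400

    # place summits with minimum separation, bounded retries
    n_total = sum(n_per_class.values())
    positions: list[tuple[str, int]] = []
    probs = np.array([sizes[c] for c in chroms], dtype=float) / total
    attempts = 0
    while len(positions) < n_total:
        attempts += 1
        if attempts > 200 * max(1, n_total):
            raise RuntimeError("could not place peaks with required spacing")
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        pos = int(rng.integers(margin, sizes[chrom] - margin))
        if any(c == chrom and abs(p - pos) < min_sep for c, p in positions):
            continue
        positions.append((chrom, pos))

    labels = [c for c in sorted(n_per_class) for _ in range(n_per_class[c])]
    rng.shuffle(labels)

    # approximate library sizes from the constant background alone
    approx_lib = {cond: _COND_DEPTH[cond] * total for cond in ALL_CONDITIONS}
    bound_rpkm = 2.0 * config.rpkm_threshold

    depth = {cond: {c: np.full(sizes[c], _COND_DEPTH[cond], dtype=np.int64)
                    for c in chroms} for cond in ALL_CONDITIONS}
    summits: dict[str, list[PeakSummit]] = {c: [] for c in ALL_CONDITIONS}
    truth_rows = []
    span = int(4 * pileup_sd_bp)
    offsets = np.arange(-span, span + 1)
    shape = np.exp(-0.5 * (offsets / pileup_sd_bp) ** 2)

    for i, ((chrom, pos), label) in enumerate(zip(positions, labels)):
        row = {"peak_id": f"true_{i:05d}", "chrom": chrom, "summit": pos,
               "true_class": label}
        for cond in ALL_CONDITIONS:
            bound = _CLASS_OCCUPANCY[label][cond]
            lib_m = approx_lib[cond] / 1e6
            bg_rpkm = _COND_DEPTH[cond] / (length_kb * lib_m)
            target = bound_rpkm if bound else unbound_rpkm
            height_rpkm = max(0.0, target - bg_rpkm)
            noise = max(0.1, 1.0 + rng.normal(0.0, 1.0 / snr))
            height = height_rpkm * length_kb * lib_m * noise
            pileup = np.rint(height * shape).astype(np.int64)
            lo = pos - span
            depth[cond][chrom][lo : lo + len(pileup)] += pileup
            row[f"bound_{cond}"] = bound
            row[f"rpkm_{cond}"] = target if height_rpkm > 0 else bg_rpkm
            if bound:
                # 0/+1 bp jitter: calls from different conditions stay
                # within 1 bp so they always merge into one consensus peak
                jitter = int(rng.integers(0, 2))
                summits[cond].append(
                    PeakSummit(chrom, pos + jitter, float(height), cond)
                )
        if label == STATIC_UNBOUND:
            # spurious weak call so the locus enters the consensus set
            summits[COND_0H].append(PeakSummit(chrom, pos, 1.0, COND_0H))
        truth_rows.append(row)

    tracks = {
        cond: CoverageTrack(depth=depth[cond]) for cond in ALL_CONDITIONS
    }
    for cond in summits:
        summits[cond].sort(key=lambda s: (s.chrom, s.summit_pos))
    truth = SyntheticTruth(peaks=pd.DataFrame(truth_rows))
    logger.info("planted %d peaks across %d classes",
                n_total, len(n_per_class))
    return summits, tracks, truth


def match_peaks_to_truth(
    peaks, truth: SyntheticTruth, tolerance_bp: int = 3
) -> pd.DataFrame:
    """Pair consensus peaks with planted peaks by nearest summit.

    Returns a frame with peak_id, true peak id, true class and the
    assigned label (if present). Unmatched peaks raise, since every
    consensus peak in a synthetic landscape must trace to a planted one.
    """
    tp = truth.peaks
    rows = []
    for p in peaks:
        sub = tp[tp["chrom"] == p.chrom]
        d = (sub["summit"] - p.summit).abs()
        j = d.idxmin()
        if d.loc[j] > tolerance_bp:
            raise ValueError(
                f"consensus peak at {p.chrom}:{p.summit} matches no "
                f"planted peak within {tolerance_bp} bp"
            )
        rows.append({"peak_id": p.peak_id, "true_id": tp.loc[j, "peak_id"],
                     "true_class": tp.loc[j, "true_class"],
                     "label": p.label})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# colony reversion time courses
# ---------------------------------------------------------------------------


def generate_colony_timecourse(
    midpoint_hours: float,
    slope: float = 5.0,
    n_replicates: int = 3,
    n_fields: int = 4,
    timepoints: Sequence[float] = tuple(range(0, 97, 4)),
    noise_sd: float = 0.05,
    fate_mixture: Mapping[str, float] | None = None,
    seed: int = 0,
    condition: str = "minus_dox",
    rfp_area_px: int = 10_000,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-colony GFP+ fractions along a decreasing logistic.

    One colony per (timepoint, replicate, field). The colony's normalised
    GFP+ fraction at differentiation time t is
    ``clip(1 / (1 + exp((t - midpoint) / slope)) + N(0, noise_sd), 0, 1)``.
    The table follows the colony CSV schema with a single terminal assay
    row per colony; the terminal antibody status follows the planted fate.
    Without an explicit ``fate_mixture`` the fate is implied by the noisy
    terminal fraction (>= 0.8 uniformly reporter-positive, 0.2-0.8 mixed,
    below 0.2 antibody-positive in 30% of colonies); with a mixture, fates
    are drawn from it and the terminal fraction is redrawn within the
    fate's band.
    """
    if len(timepoints) == 0:
        raise ValueError("timepoint list is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if any(t < 0 or t > 96 for t in timepoints):
        raise ValueError("timepoints must lie within [0, 96] h")
    if fate_mixture is not None and not np.isclose(
        sum(fate_mixture.values()), 1.0
    ):
        raise ValueError("fate_mixture must sum to 1")
    rng = child_rng(seed, "colonies")
    rows = []
    truth_rows = []
    fate_bands = {
        "gfp_positive": (0.85, 1.0),
        "gfp_mixed": (0.25, 0.75),
        "gfp_neg_ab_pos": (0.0, 0.15),
        "gfp_neg_ab_neg": (0.0, 0.15),
    }
    i = 0
    for t in timepoints:
        expected = 1.0 / (1.0 + np.exp((t - midpoint_hours) / slope))
        for rep in range(n_replicates):
            for fld in range(n_fields):
                frac = float(np.clip(
                    expected + rng.normal(0.0, noise_sd) if noise_sd > 0
                    else expected, 0.0, 1.0,
                ))
                if fate_mixture is not None:
                    fates = sorted(fate_mixture)
                    fate = fates[rng.choice(
                        len(fates), p=[fate_mixture[f] for f in fates]
                    )]
                    lo, hi = fate_bands[fate]
                    frac = float(rng.uniform(lo, hi))
                else:
                    if frac >= 0.8:
                        fate = "gfp_positive"
                    elif frac >= 0.2:
                        fate = "gfp_mixed"
                    else:
                        fate = ("gfp_neg_ab_pos" if rng.random() < 0.3
                                else "gfp_neg_ab_neg")
                antibody = ("negative" if fate == "gfp_neg_ab_neg"
                            else "positive")
                colony_id = f"col_{condition}_{i:05d}"
                rows.append({
                    "colony_id": colony_id,
                    "condition": condition,
                    "differentiation_time_h": float(t),
                    "assay_time_h": 96.0,
                    "rfp_area_px": rfp_area_px,
                    "gfp_pos_px": int(round(frac * rfp_area_px)),
                    "mean_gfp": round(frac, 6),
                    "antibody": antibody,
                })
                truth_rows.append({
                    "colony_id": colony_id,
                    "differentiation_time_h": float(t),
                    "true_fraction": expected,
                    "true_fate": fate,
                    "true_midpoint_h": midpoint_hours,
                    "replicate": rep,
                    "field": fld,
                })
                i += 1
    table = pd.DataFrame(rows)
    truth = SyntheticTruth(colonies=pd.DataFrame(truth_rows))
    return table, truth


# ---------------------------------------------------------------------------
# expression time courses
# ---------------------------------------------------------------------------

EXPR_CLASSES = ("early", "intermediate", "late", "flat")


def _trajectory(label: str, t: np.ndarray) -> np.ndarray:
    """Relative expression level (0.05..1) of one archetype over time."""
    if label == "early":
        return 0.05 + 0.95 / (1.0 + np.exp((t - 30.0) / 8.0))
    if label == "intermediate":
        return 0.05 + 0.95 * np.exp(-0.5 * ((t - 48.0) / 15.0) ** 2)
    if label == "late":
        return 0.05 + 0.95 / (1.0 + np.exp(-(t - 60.0) / 8.0))
    if label == "flat":
        return np.full_like(t, 0.6, dtype=float)
    raise ValueError(f"unknown expression class {label!r}")


def generate_expression(
    n_genes_per_class: Mapping[str, int] | int = 500,
    timepoints: Sequence[float] = (0.0, 24.0, 48.0, 72.0, 96.0),
    n_replicates: int = 3,
    noise_cv: float = 0.15,
    seed: int = 0,
    base_fpkm: float = 30.0,
    dox_fold: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """FPKM matrix, per-comparison statistics, sample metadata and truth.

    Genes follow one of four archetypes: early (decreasing logistic),
    intermediate (transient mid-course bump), late (increasing logistic)
    or flat. Replicate FPKMs are log-normal around the archetype with the
    given coefficient of variation. Per-comparison fold changes and
    Benjamini-Hochberg q-values come from a two-sample Welch test on
    log-FPKM replicates, computed for every pair of timepoints; when
    ``dox_fold`` maps classes to an OSKM-response fold, matched +dox
    samples and time-matched -dox/+dox comparisons are emitted too.
    """
    from itertools import combinations

    from scipy import stats as sps
    from statsmodels.stats.multitest import multipletests

    if n_replicates < 2:
        raise ValueError("need >= 2 replicates for q-values")
    if isinstance(n_genes_per_class, int):
        n_genes_per_class = {c: n_genes_per_class for c in EXPR_CLASSES}
    rng = child_rng(seed, "expression")
    t = np.asarray(sorted(timepoints), dtype=float)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))

    gene_rows = []
    data = {}
    conditions = [(f"{tp:g}", tp, False) for tp in t]
    if dox_fold is not None:
        conditions += [(f"{tp:g}+dox", tp, True) for tp in t]
    samples = [(f"{cname}_r{r+1}", cname, tp, dox)
               for cname, tp, dox in conditions
               for r in range(n_replicates)]

    i = 0
    for label in EXPR_CLASSES:
        for _ in range(n_genes_per_class.get(label, 0)):
            gene_id = f"gene_{i:05d}"
            level = base_fpkm * float(rng.lognormal(0.0, 0.5))
            traj = level * _trajectory(label, t)
            per_cond = {}
            for cname, tp, dox in conditions:
                mean = traj[np.searchsorted(t, tp)]
                if dox and dox_fold is not None:
                    mean = mean * dox_fold.get(label, 1.0)
                per_cond[cname] = mean
            vals = []
            for sname, cname, tp, dox in samples:
                noisy = (per_cond[cname]
                         * float(rng.lognormal(0.0, sigma))
                         if noise_cv > 0 else per_cond[cname])
                vals.append(noisy)
            data[gene_id] = vals
            gene_rows.append({"gene_id": gene_id, "true_class": label})
            i += 1

    expr = pd.DataFrame.from_dict(
        data, orient="index", columns=[s[0] for s in samples]
    )
    sample_meta = pd.DataFrame(
        {"timepoint": [s[2] for s in samples],
         "dox": [s[3] for s in samples],
         "replicate": [int(s[0].rsplit("_r", 1)[1]) for s in samples]},
        index=[s[0] for s in samples],
    )
    # condition name used in comparisons = f"{tp:g}" (+ "+dox")
    cond_cols: dict[str, list[str]] = {}
    for sname, cname, tp, dox in samples:
        cond_cols.setdefault(cname, []).append(sname)

    def compare(cond_a: str, cond_b: str) -> pd.DataFrame:
        xa = np.log2(expr[cond_cols[cond_a]].to_numpy() + 0.1)
        xb = np.log2(expr[cond_cols[cond_b]].to_numpy() + 0.1)
        tstat, p = sps.ttest_ind(xa, xb, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        fold = ((expr[cond_cols[cond_b]].mean(axis=1) + 0.1)
                / (expr[cond_cols[cond_a]].mean(axis=1) + 0.1))
        return pd.DataFrame({
            "gene": expr.index, "cond_a": cond_a, "cond_b": cond_b,
            "fold_change": fold.to_numpy(), "q_value": q,
        })

    frames = [compare(f"{a:g}", f"{b:g}") for a, b in combinations(t, 2)]
    if dox_fold is not None:
        frames += [compare(f"{tp:g}", f"{tp:g}+dox") for tp in t]
    comparisons = pd.concat(frames, ignore_index=True)
    truth = SyntheticTruth(genes=pd.DataFrame(gene_rows))
    return expr, comparisons, sample_meta, truth


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

# class-mean methylation defaults: reaccessed targets stay focally
# hypomethylated while exclusive targets re-methylate with the genome
DEFAULT_CLASS_MEANS = {"reaccessed": 0.39, "exclusive": 0.69}
BACKGROUND_METH_MEAN = 0.8


def cpg_positions(genome: Mapping[str, str]) -> dict[str, np.ndarray]:
    """0-based start positions of CG dinucleotides per chromosome."""
    out = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        out[chrom] = np.flatnonzero((arr[:-1] == ord("C"))
                                    & (arr[1:] == ord("G")))
    return out


def generate_methylation(
    genome: Mapping[str, str],
    region_sets: Mapping[str, Sequence[GenomicInterval]],
    class_means: Mapping[str, float] | None = None,
    coverage_mean: float = 10.0,
    background_mean: float = BACKGROUND_METH_MEAN,
    seed: int = 0,
) -> tuple[list[MethylationRecord], SyntheticTruth]:
    """Per-CpG coverage and methylated counts with class-dependent means.

    Every CG dinucleotide in the genome yields a record with coverage
    ~ Poisson(coverage_mean) and methylated ~ Binomial(coverage, m), where
    m is the class mean of the first region set containing the CpG and the
    background mean elsewhere.
    """
    class_means = dict(class_means or DEFAULT_CLASS_MEANS)
    for name, m in list(class_means.items()) + [("background", background_mean)]:
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"class mean {name}={m} outside [0, 1]")
    rng = child_rng(seed, "methylation")
    records: list[MethylationRecord] = []
    positions = cpg_positions(genome)
    for chrom in sorted(positions):
        pos = positions[chrom]
        means = np.full(len(pos), background_mean)
        for set_name in region_sets:
            m = class_means[set_name]
            for iv in region_sets[set_name]:
                if iv.chrom != chrom:
                    continue
                sel = (pos >= iv.start) & (pos < iv.end)
                means[sel] = np.where(
                    means[sel] == background_mean, m, means[sel]
                )
        cov = rng.poisson(coverage_mean, size=len(pos))
        meth = rng.binomial(cov, means)
        records.extend(
            MethylationRecord(chrom, int(p), int(c), int(k))
            for p, c, k in zip(pos, cov, meth)
        )
    truth = SyntheticTruth(
        methylation_means={**class_means, "background": background_mean}
    )
    return records, truth


# ---------------------------------------------------------------------------
# motif embedding
# ---------------------------------------------------------------------------


def embed_motifs(
    genome: Mapping[str, str],
    peaks: Sequence,  # ConsensusPeak-like: chrom, summit, region, peak_id
    consensus_by_motif: Mapping[str, str],
    placement_plan: Sequence[tuple[str, str, int]] | None = None,
    seed: int = 0,
    offset_mean: float = 20.0,
    offset_sd: float = 10.0,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Write motif consensus sequences into peak regions.

    ``placement_plan`` lists (peak_id, motif_id, offset-from-summit)
    triples; with ``None`` an empty plan is used (genome unchanged).
    Convenience: :func:`default_placement_plan` builds the characteristic
    plan placing one instance per peak at N(+/-offset_mean, offset_sd) bp
    from the summit. Instances go on either strand with equal probability;
    the motif is centred on summit+offset and must lie inside the peak
    region.
    """
    rng = child_rng(seed, "motifs")
    plan = list(placement_plan or [])
    mutable = {c: bytearray(s.encode()) for c, s in genome.items()}
    by_id = {p.peak_id: p for p in peaks}
    rows = []
    comp = str.maketrans("ACGT", "TGCA")
    for peak_id, motif_id, offset in plan:
        peak = by_id[peak_id]
        word = consensus_by_motif[motif_id]
        L = len(word)
        start = peak.summit + int(offset) - L // 2
        if start < peak.region.start or start + L > peak.region.end:
            raise ValueError(
                f"placement of {motif_id} at offset {offset} falls outside "
                f"the region of {peak_id}"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = word if strand == "+" else word.translate(comp)[::-1]
        mutable[peak.chrom][start : start + L] = inserted.encode()
        rows.append({"peak_id": peak_id, "motif_id": motif_id,
                     "offset": int(offset), "strand": strand})
    truth = SyntheticTruth(motif_placements=pd.DataFrame(
        rows, columns=["peak_id", "motif_id", "offset", "strand"]
    ))
    return {c: b.decode() for c, b in mutable.items()}, truth


def default_placement_plan(
    peaks: Sequence,
    motif_id: str,
    seed: int = 0,
    offset_mean: float = 20.0,
    offset_sd: float = 10.0,
) -> list[tuple[str, str, int]]:
    """One placement per peak at a signed offset of N(+/-mean, sd) bp."""
    rng = child_rng(seed, "motifs")
    plan = []
    for p in peaks:
        sign = 1 if rng.random() < 0.5 else -1
        offset = int(round(rng.normal(sign * offset_mean, offset_sd)))
        plan.append((p.peak_id, motif_id, offset))
    return plan


# ---------------------------------------------------------------------------
# toy PWM set and full-study simulation
# ---------------------------------------------------------------------------


def toy_pwm_set() -> dict[str, np.ndarray]:
    """Six strong position count matrices (lengths 8-12) for fixtures.

    Deterministic: a dominant consensus base per column (count 50) over a
    background of 1, consensus words chosen to be mutually dissimilar.
    The first motif's consensus is the canonical octamer-factor binding
    word so planted-motif tests read naturally.
    """
    words = {
        "OCT4_like": "ATGCAAAT",
        "SOX_like": "AACAATGG",
        "KLF_like": "GGGGTGGGG",
        "MYC_like": "CACGTGGT",
        "GATA_like": "AGATAAGATA",
        "CTCF_like": "CCGCGNGGNGGCAG".replace("N", "A")[:12],
    }
    base_index = {b: i for i, b in enumerate(BASES)}
    pwms = {}
    for motif_id, word in words.items():
        mat = np.ones((len(word), 4))
        for j, b in enumerate(word):
            mat[j, base_index[b]] = 50.0
        pwms[motif_id] = mat
    return pwms


def simulate_all(
    seed: int,
    out_dir,
    config: PipelineConfig | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    n_cpg_islands: int = 6,
    n_per_class: int = 8,
    n_genes_per_class: int = 60,
    transition_midpoints: Mapping[str, float] | None = None,
) -> None:
    """Generate every pipeline input plus ground truth under ``out_dir``.

    Writes a genome FASTA (with embedded motif instances in
    reaccessed-class peaks), CpG-island BED, per-condition summit
    narrowPeak and coverage bedGraph files, a methylation TSV, expression
    matrix / comparison / sample tables, colony CSVs for the -dox and
    +dox reversion conditions, a JASPAR-style PWM file, and ``truth/``
    TSVs. Deterministic: the same seed yields byte-identical files.
    """
    import json
    from pathlib import Path

    from plurevert import io_formats as iof
    from plurevert import peak_dynamics as pk

    config = config or PipelineConfig()
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    chrom_sizes = dict(chrom_sizes or {"chr1": 600_000, "chr2": 600_000})
    midpoints = dict(transition_midpoints
                     or {"minus_dox": 25.0, "plus_dox": 53.0})

    genome, islands = generate_genome(seed, chrom_sizes, n_cpg_islands)
    summits, tracks, peak_truth = generate_peak_landscape(
        genome, n_per_class, seed=seed, config=config
    )

    # consensus regions over the planted landscape, for motif embedding and
    # methylation region sets
    all_summits = [s for lst in summits.values() for s in lst]
    peaks = pk.build_consensus_peaks(all_summits, config)
    matched = match_peaks_to_truth(peaks, peak_truth)
    class_of = dict(zip(matched["peak_id"], matched["true_class"]))
    reaccessed = [p for p in peaks
                  if class_of.get(p.peak_id) == PLURI_REACCESSED]
    exclusive = [p for p in peaks
                 if class_of.get(p.peak_id) == PLURI_EXCLUSIVE]

    pwms = toy_pwm_set()
    consensus_by_motif = {
        mid: "".join(BASES[j] for j in mat.argmax(axis=1))
        for mid, mat in pwms.items()
    }
    plan = default_placement_plan(reaccessed, "OCT4_like", seed=seed)
    genome, motif_truth = embed_motifs(
        genome, peaks, consensus_by_motif, plan, seed=seed
    )

    region_sets = {
        "reaccessed": [p.region for p in reaccessed],
        "exclusive": [p.region for p in exclusive],
    }
    meth, meth_truth = generate_methylation(genome, region_sets, seed=seed)

    expr, comparisons, sample_meta, expr_truth = generate_expression(
        n_genes_per_class, seed=seed
    )

    iof.write_fasta(genome, out / "genome.fa")
    iof.write_bed(islands, out / "cpg_islands.bed")
    for cond in ALL_CONDITIONS:
        tag = cond.replace("+", "_")
        iof.write_peak_summits(summits[cond], out / f"summits_{tag}.narrowPeak")
        iof.write_coverage(tracks[cond], out / f"coverage_{tag}.bedGraph")
    iof.write_methylation_table(meth, out / "methylation.tsv")
    iof.write_pwms(pwms, out / "pwms.jaspar")
    expr.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
    comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    sample_meta.to_csv(out / "sample_meta.tsv", sep="\t",
                       index_label="sample")

    colony_truths = []
    for condition, midpoint in sorted(midpoints.items()):
        table, ctruth = generate_colony_timecourse(
            midpoint, seed=seed, condition=condition
        )
        table.to_csv(out / f"colonies_{condition}.csv", index=False)
        colony_truths.append(ctruth.colonies)

    peak_truth.peaks.to_csv(out / "truth" / "peaks.tsv", sep="\t",
                            index=False)
    expr_truth.genes.to_csv(out / "truth" / "genes.tsv", sep="\t",
                            index=False)
    pd.concat(colony_truths, ignore_index=True).to_csv(
        out / "truth" / "colonies.tsv", sep="\t", index=False
    )
    motif_truth.motif_placements.to_csv(
        out / "truth" / "motif_placements.tsv", sep="\t", index=False
    )
    with open(out / "truth" / "methylation_means.json", "w") as fh:
        json.dump(meth_truth.methylation_means, fh, sort_keys=True, indent=1)
    logger.info("wrote synthetic study to %s", out)
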