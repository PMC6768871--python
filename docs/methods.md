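# Methods

This note documents the statistical models and procedures implemented in
`plurevert`, the defaults they use, the design choices that were genuinely
open, and what the synthetic-data generators do and do not emulate.

## Coordinate and format conventions

All in-memory coordinates are 0-based half-open; BED-family files are read
and written in their native 0-based half-open convention, so untouched
records round-trip bit-identically. narrowPeak summits are
`start + column-10 offset`; the column-7 signalValue is taken as the
summit score (peak callers put either a score or a pileup height there;
the consensus-building step only needs relative weights). bedGraph is the
canonical coverage input — the package has no alignment-file dependency —
and its library size defaults to the total signal mass
(Σ depth × interval length), overridable when the true mapped-read count
is known. Every analysis constant is a field of `PipelineConfig`
(YAML-serialisable), never a hard-coded literal, and each stage logs its
input counts, filter survivors and the config values used.

## Consensus peaks and occupancy dynamics

Summits from all conditions whose positions lie within 1 bp of each other
are chained transitively (single linkage) into one group; the consensus
summit is the score-weighted mean position, rounded to the nearest base
with halves away from zero, and the consensus region is summit ± 300 bp.
Single-linkage chaining is a choice — the merge rule does not itself
dictate a grouping for chains — made because the weighted-average step
presupposes one region containing all member summits; on ≤200-summit
instances the result is verified against a brute-force union–find over
the "within 1 bp" relation, and merging is idempotent and independent of
input order. Groups whose scores are all zero fall back to the unweighted
mean (logged), not an error.

Occupancy per condition is `RPKM = max per-base depth in the 600-bp
region / (0.6 kb × library size in millions)`. Using the *maximum* pileup
rather than the read total makes the value robust to region-width choices;
a config flag (`intensity_mode="sum"`) selects total-count quantification
instead. Regions clipped at a chromosome end are still normalised by the
nominal 0.6 kb so values stay comparable.

A peak is **dynamic** when its occupancy changes ≥2-fold between any two
differentiation timepoints (0/48/96 h). A pseudocount of 0.1 RPKM on both
sides keeps ratios defined at zero occupancy; the cutoff is inclusive.
Binding is discretised at ≥3 RPKM (inclusive), and classes follow from
binding at 0 h, 96 h, and 48 h + dox: bound/unbound at both ends →
static; bound at 96 h only → differentiation-associated; bound at 0 h
only → pluripotency set, sub-split by the re-induction condition into
*reaccessed* (re-bound under ectopic OSKM) and *exclusive* (not
re-bound), with *pluripotency_other* reserved for peaks whose dox
occupancy is unavailable. Nearest-gene assignment considers
protein-coding genes only, minimises |summit − TSS| with no distance
bound, and breaks ties to the lexicographically smallest gene id.

## Transition-time estimation

The reversion assay yields, for each differentiation duration t, a
population of per-colony GFP⁺ area fractions (normalised to the median of
undifferentiated 0 h controls; values may exceed 1 and are not clipped).
Replicates are pooled. At each timepoint the observations are ranked and
split into ten per-10th-percentile groups — grouping by rank matches
percentiles across timepoints, so group g traces the g-th decile of the
population over time. Each group's mean-fraction curve is fitted by
bounded least squares to the decreasing four-parameter logistic

    f(t) = b + (a − b) / (1 + exp((t − t₀)/s)),

with a ∈ [0.5, 1.5], b ∈ [−0.1, 0.5], t₀ within the observed time range,
s ∈ (0, 50] h. The fit is deterministic: a fixed multi-start grid places
t₀ at the quartiles of the time range and the lowest-SSE start wins (ties
to the smallest start). The transition time of a group is the time where
the *fitted fraction equals 0.5* — solved analytically as
`t₀ + s·ln((a−b)/(0.5−b) − 1)` — which coincides with t₀ only when
a + b = 1; it is defined only when 0.5 lies strictly between the curve's
extremes over the fitted range. The condition-level estimate is the
median and 25th/75th percentile of the converged group transition times;
fewer than 5 usable groups is an error rather than a silent wide
estimate. The estimator is exactly shift-equivariant on noiseless data
and recovers planted midpoints of 25 h and 53 h with |bias| ≤ 3 h at
noise sd 0.05 (20 seeds; see `tests/test_acceptance.py`).

Pixel-level quantification uses a strictly-above rule: a pixel is GFP⁺
when its intensity exceeds 20% of the undifferentiated-control reference
(the control's median colony intensity). Both the 20% factor and the
strictness are conventions (config-controlled); the boundary case is
pinned by tests.

Colony **fate classification** automates a four-way call that was done
by eye in comparable experiments, using terminal GFP⁺ area fraction g and
NANOG antibody status: g ≥ 0.8 → uniformly reporter-positive; 0.2 ≤ g <
0.8 and antibody⁺ → mixed; g < 0.2 and antibody⁺ → reporter-silent
NANOG⁺; otherwise double-negative. The 0.2/0.8 cut points are config
values, not claims about the original manual criteria; intermediate-GFP
antibody-negative colonies are classed double-negative and logged as
unusual.

**Doubling rates** come from OLS of log₂ GFP⁺ pixel counts on time;
doubling time = 1/slope, undefined (not clamped) when the slope is ≤ 0 at
float precision. Zero counts are excluded with a log entry. The
three-phase structure of reporter activation (flat lag → rapid switch →
log-linear expansion) is recovered by an exhaustive two-breakpoint search
over observed timepoints (≥3 points per segment, minimum total SSE) —
exact, deterministic, and O(m²) fits for m samples, which is trivial at
the ≤100-point scale of imaging series.

## Expression dynamics

A gene is dynamic when some timepoint pair shows q < 0.05, fold ≥ 2 (in
either direction), and ≥1 FPKM in the more expressed member of that
comparison ("minimum expression in that comparison" is read as the max of
the two group means). Per-comparison fold changes and q-values are taken
as *input* — differential-expression testing of real data is out of
scope — and the synthetic generator supplies them from a Welch test on
log-FPKM replicates with Benjamini–Hochberg correction per comparison.

Dynamic-gene trajectories (per-gene Z-scored means over the -dox course;
constant genes excluded with a log entry) are clustered by k-means (fixed
seed, 10 restarts) for k = 2..20; the chosen k maximises the mean
Euclidean silhouette, computed on a ≤2000-gene subsample because
silhouette is O(n²) (the final fit uses all genes). When k = 3 the
clusters are named from centroid shape — ordered by the time of the
centroid maximum: earliest → *early*, latest → *late*, middle →
*intermediate* — otherwise generic labels are kept and a warning issued.

Gene-set overlap uses the hypergeometric upper tail P(X ≥ overlap) and
Fisher's exact test on the 2×2 table with the sample odds ratio. The
universe is the caller's choice (the analyses here default to all genes
in the matrix); enumeration-based oracles pin the exact tail for N ≤ 20.

## Signal and methylation profiles

Composite profiles are across-peak medians of per-million-normalised
depth in uniform bins over summit ± 2 kb; heatmaps use 10-bp bins and are
capped at the 99th percentile computed jointly across co-displayed peak
sets (per-set capping by flag); capping is monotone and order-preserving
below the cap. Methylation composites slide a 100-bp window by 25 bp
across region-center ± 2 kb; per window and region the mean of per-CpG
fractions is taken over CpGs with ≥3× coverage, windows without a
qualifying CpG stay missing (NaN) — never coerced to zero — and the
across-region mean ± 1 SD ignores missing windows with per-bin n
reported. Region mean methylation is the *unweighted* mean of per-CpG
fractions (each CpG one vote; coverage weighting by flag), missing below
1 qualifying CpG. CpG density counts forward-strand CG dinucleotide
starts within the half-open interval (CpG is its own reverse complement)
per 100 bp. Reversing a region's strand flips its profile axis and
nothing else.

The Mann–Whitney comparison enumerates the exact null over all group
assignments of pooled midranks when the combined n is ≤ 20 (so ties are
handled and identical samples give p = 1 exactly), with
2·min(lower, upper tail) capped at 1 as the two-sided p; larger samples
use the tie-corrected normal approximation, which agrees with the exact
branch to < 0.01 at n = 10 + 10.

## Motif statistics

PWMs (pseudocount 0.1, uniform background by default) are scored as
per-position log₂ odds, discretised to a 1e-3-bit lattice. The exact null
distribution of window scores over i.i.d. background words is the
convolution of the per-position score distributions — O(L·range) instead
of 4^L — and equals exhaustive enumeration to ≤1e-6 for L ≤ 8. The hit
threshold is the smallest score whose tail probability is < 1e-4
(per-window, uncorrected, matching per-position scanning semantics); a
motif too degenerate to ever reach that level scans to zero hits with a
log entry — under a uniform background this includes every motif shorter
than 7 bp, whose best word already has p = 4⁻ᴸ > 1e-4. Both strands are
scanned (the reverse strand via the reverse-complement matrix); offsets
are recorded relative to the region center in forward orientation, and
presence is binary per (peak, motif). Positional preference smooths the
absolute offsets of each peak's best hit with a 10-bp Gaussian kernel and
reports the mode. Observed hit rates on random sequence sit within 3
binomial SDs of the nominal (L_scan − L_motif + 1) × 1e-4 per strand once
the deterministic undershoot of the discrete threshold is accounted for.

Region association re-implements permutation overlap testing as uniform
within-chromosome relocation of the query set (lengths preserved,
self-overlap allowed): the statistic is the number of query regions
overlapping the reference set, z standardises it against the permutation
distribution, and the empirical p is (1 + #{perm ≥ obs})/(n_perm + 1),
never zero. This is an emulation of circular-randomisation association
scores: the compatibility surface is the z-score contract, not numerical
parity with any particular implementation. The z-score is a meaningful
±3-banded quantity only when the expected overlap count is large enough
to be approximately normal (tens, not tenths); for sparse sets the
empirical p is the honest summary.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (parameters, seed); identical seeds
give byte-identical files. Child streams derive from the global seed via
fixed spawn keys, so adding a generator never shifts existing streams.

* **Genome** — i.i.d. bases with CG dinucleotides thinned ~5-fold
  (mammalian-like depletion); islands of 500–2000 bp with 60% G+C and no
  depletion (observed/expected CpG ≈ 1, island CpG density >3× the
  background). No repeats, no isochores, no chromatin context.
* **Peak landscape** — five occupancy classes over four conditions
  (exclusive 1/1/0/0 at 0/48/96 h/dox, reaccessed 1/0/0/1,
  differentiation 0/0/1/0, static bound/unbound), Gaussian pileups
  (sd 80 bp) at twice the binding threshold when bound and half when
  unbound, multiplicative height noise 1/SNR, flat per-condition
  backgrounds giving ≥2-fold library-size spread, and 0/+1 bp summit
  jitter across conditions (kept within the 1-bp merge radius so each
  planted peak yields exactly one consensus peak). Unbound-everywhere
  loci enter via a weak spurious 0 h call. Because occupancy is the
  *maximum* pileup over a flat background of depth d in a genome of G bp,
  the background RPKM is fixed at 1e6/(0.6·G) regardless of d; the
  generator refuses genomes too small to keep background below the
  unbound target (≥ ~1.2 Mb at default thresholds). Coverage is emitted
  directly as pileup — no reads, fragments or duplicates are simulated.
* **Colony time courses** — per-colony fractions
  clip(1/(1 + exp((t − m)/s)) + N(0, σ), 0, 1) with slope s = 5 h and
  truncated-Gaussian noise σ = 0.05 by default; the noise model is a
  modeling choice (no pixel-level imaging is simulated, and colony tables
  are emitted at the already-quantified level). Fates follow the terminal
  fraction, or a caller-supplied mixture for fate-recovery tests.
* **Expression** — archetypes: early = decreasing logistic (midpoint
  30 h), intermediate = Gaussian bump at 48 h (sd 15 h), late =
  increasing logistic (midpoint 60 h), flat; per-gene log-normal base
  levels around 30 FPKM, log-normal replicate noise at CV 0.15, five
  timepoints over 0–96 h, three replicates. The Welch-plus-BH comparison
  stand-in replaces the out-of-scope external DE tool only inside the
  generator; analysis stages consume q-values agnostically.
* **Methylation** — per-CpG coverage ~ Poisson(10), methylated ~
  Binomial(coverage, m) with class means 0.39 (reaccessed) / 0.69
  (exclusive) and 0.8 elsewhere; the defaults mirror the reported
  epiblast contrast between the two peak classes and are config, not
  assumptions. No spatial autocorrelation between neighbouring CpGs.
* **Motifs** — PWM consensus words written at planted offsets (default
  N(±20 bp, sd 10) from reaccessed-peak summits), random strand.

Passing the recovery suites therefore shows that the estimators invert
their own generative models at realistic noise — not that they are robust
to everything real data contains (fragment-length artefacts, copy-number
bias, bisulfite conversion errors, segmentation drift, batch effects).

## Problem sizes

The test and acceptance runs use desk-scale instances chosen to exercise
every code path with comfortable statistical margins: 0.4–2 Mb genomes,
25–200 peaks, 240–2000 genes, 12 colonies × 25 timepoints per condition,
20 seeds per recovery estimate, and 100–1000 permutations. All scale
linearly (quadratically for the silhouette subsample and the segmented
fit) if larger instances are needed.
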