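# Methods

This note documents the models and procedures implemented in `dynfnc`, the
assumptions and parameter choices behind them, what the synthetic-data
generator does and does not emulate, and the numerical conventions fixed
where the underlying methodology leaves freedom.

## Pipeline model

The analysis treats a resting-state cohort as draws from a
switching-covariance process. Each subject's brain activity is summarized
by n = K₁ + K₂ network time courses (K₁ gray-matter, K₂ white-matter
networks); at any time the inter-network covariance is one of ks recurring
configurations ("states"), and subjects differ in which states they occupy,
for how long, and — in the case/control comparison — in the strength of
specific network-pair couplings within specific states. The pipeline
estimates, in order: the network partition, the window length that best
resolves the group contrast, the windowed connectivity itself, the state
centroids and per-window state labels, subject-specific versions of the
states, and group-level temporal and edge statistics.

### Network derivation

Static FC is the Pearson correlation of ROI time courses over the full
scan, computed per subject per tissue and averaged across subjects. ROIs
are clustered by K-means on the rows of the average FC matrix (each row is
an ROI's connectivity profile). Correlation distance is realized as squared
Euclidean distance on row-standardized profiles, which reproduces the
ranking of 1 − Pearson; initialization is k-means++, and the best of
`n_replications` runs by distortion is kept. The replication seed stream is
prefix-stable, so increasing the replication count can only improve (never
worsen) the kept distortion.

The number of networks is selected by Dice cross-validation. The published
description of this procedure is ambiguous about how folds, chunks, and the
binary cs×cs×nf tensor combine; the implementation here is: each of `nf`
folds clusters the full ROI set with an independent initialization stream
*and an independent random ROI presentation order*; each fold yields a
co-clustering adjacency matrix; ROI indices are randomly permuted and split
into chunks of size `cs`; for every unordered chunk pair the cs×cs
adjacency sub-blocks are compared across all unordered fold pairs with the
Dice overlap (cells on the ROI self-diagonal excluded); the grand mean is
the stability at K. The per-fold ROI reordering matters on idealized
fixtures: equal-size planted blocks make many merge solutions exactly
equivalent, and without reordering, floating-point tie-breaking in
best-of-replications K-means picks the *same* merge in every fold, making
an ambiguous K look perfectly stable. Randomizing the presentation order
breaks these ties honestly; a K whose solution is genuinely unique (the
planted count) still reaches Dice 1.0.

Because clustering similarity drifts downward as K grows, the selected K is
the highest *interior local maximum* of the mean Dice curve, falling back
to the global argmax when no interior peak exists. Defaults follow the
study scale: candidate K 5–20, nf = 8, cs = 30, 50 replications for
selection and 100 for the final partition.

### Window-length selection

Group discriminability is measured by the Fisher discriminant ratio of
per-subject mean dFNC-STD (mean over all connections) between the control
group and the pooled patient groups:

J = (μ_HC − μ_TLE)² / (σ²_HC + σ²_TLE).

The literal difference-of-variances form (unsquared numerator,
σ²_HC − σ²_TLE in the denominator) is available as `variant="literal"`; it
can be negative and is not exchange-antisymmetric, so the canonical form —
consistent with reading J as a between/within variance ratio — is the
default. Sample (ddof = 1) variances are used. A zero denominator with
unequal means returns +inf with a warning; an all-zero J profile is flagged
non-discriminative. The default grid is 10–100 TR in steps of 5, selection
by the same local-peak rule.

### Windowed FNC

Rectangular (boxcar) windows with step 1 TR and no taper; w = ⌊(T − L)/step⌋ + 1
windows. Within each window the network-pair Pearson correlations are
Fisher z-transformed; correlations are clipped to |r| ≤ 1 − 1e−7 first so
degenerate windows map to large finite z rather than ±inf. Each window is
vectorized as the row-major upper triangle, m = n(n−1)/2 entries. Age and
sex are regressed out per edge by pooled OLS on [intercept, age, sex], with
each subject's covariates repeated over its windows (window-level rather
than subject-mean regression; the alternative is not distinguishable from
the published description). Residuals are returned plus the fitted value at
the mean covariates, so every edge's grand mean is preserved. dFNC-STD is
the sample (ddof = 1) standard deviation across windows.

### State clustering

Windows from all subjects are pooled, ignoring temporal order, and
clustered by K-means under cosine distance (true cosine on mean-uncentered
vectors). Centroids are arithmetic means of member windows and are *not*
re-normalized to unit length, and assignment uses cosine distance to those
raw-mean centroids; empty clusters are re-seeded at the worst-fit point.
Best of `n_replications` (default 50) by summed cosine distortion. The
number of states is chosen from the within/between distance ratio (mean
cosine distance to own centroid over mean pairwise centroid distance) at
the point of maximum curvature — the largest discrete second difference —
over candidates 2–15. A curve whose relative range is below 30% of its
height is flagged as having no clear elbow (genuinely clustered pools show
drops of most of the curve's height; a single-Gaussian pool moves ~13%).

### Dual regression

Two least-squares steps with no intercept, exactly as the model equations
are written: Yᵀ = Sᵀβ₁ gives the temporal dynamics β₁ (k×w), then
Y = β₁ᵀβ₂ gives the subject-specific states β₂ (k×m). Both steps use
`lstsq`, returning the minimal-norm solution with a warning under rank
deficiency. β₁ rows are not variance-normalized between steps, and no
demeaning is applied by default (a `demean` switch exists). Group states
are entrywise means of β₂ within groups.

A caution documented because it is measurable on synthetic data: β₂ is a
regression estimate, and when windows mix states (window length comparable
to or exceeding the dwell time), group differences planted on one edge leak
at a low level (~10–20% of the planted effect) onto edges that share a
network with it, through group-differential window weighting in the second
step. Realistic between-subject variability keeps this leakage well below
the detection threshold at cohort sizes of tens of subjects.

### Temporal statistics

For a subject with w windows there are w − 1 consecutive pairs. The joint
transition matrix divides the ordered-pair counts by w − 1 (entries sum to
1 exactly on integer counts); the conditional matrix divides each count by
the number of times the source state appears among the first w − 1 frames,
so visited rows sum to 1 exactly; unvisited-source rows are all-zero and
flagged. Group conditional matrices average over the subjects that visited
each source row, with the support count reported. Frame occupancy pools a
group's windows. The state-changing probability is the fraction of
consecutive pairs that switch state; it equals 1 − trace(joint), an
identity the tests assert. Group averaging is over per-subject conditional
matrices (not pooled counts), keeping each subject's weight equal.

### Group comparisons

Per edge, a two-sample t-test compares groups on static FNC, dFNC-STD, and
each state's β₂ row; Welch (unequal variances) is the default because group
sizes are generally unequal, with the Student variant behind a flag. Edges
with zero variance in both groups get t = 0, p = 1 when means agree.
Benjamini–Hochberg step-up adjustment is applied *within* each test context
(one state, or sFNC, or dFNC-STD), not pooled across contexts, matching
per-figure correction practice; significance is strict (adjusted p < q,
default q = 0.05), and directions are labelled by the sign of
mean(TLE) − mean(HC).

## Synthetic cohorts

The generator produces, per subject: a first-order Markov latent state
sequence at TR resolution (uniform off-diagonal mass, self-transition
probability 1 − 1/dwell); one independent band-limited innovation stream
per state (frequency-domain masking of white noise to the passband,
default 0.01–0.15 Hz at TR = 0.802 s), whitened over that state's own
timepoints so the realized covariance within a state's frames *equals* the
state's correlation matrix rather than merely matching it in expectation —
the state covariance is imposed at the window scale; network signals mixed
through the symmetric PSD square root of the active state's matrix (a local
perturbation of a state stays local in the symmetric root, unlike in a
Cholesky factor); and ROI signals equal to their network's signal plus
independent band-limited ROI noise (`noise_sd`, default 0.5). Group effects
are additive Fisher-z shifts on chosen (group, state, edge) triples;
covariate effects add age/sex terms on edge z-values; optional subject
state jitter adds N(0, σ²) z-perturbations to every edge of every state,
modelling idiosyncratic between-subject connectivity. Any shifted matrix
that turns indefinite is eigenvalue-clipped back to a correlation matrix (a
warning fires if a systematic, non-jitter shift had to be repaired by more
than 0.01, because a repair redistributes planted effects).

Defaults mirror the study conditions: 361 timepoints at TR 0.802 s,
passband 0.01–0.15 Hz, 45-TR windows at step 1, and a mean dwell of 27
windows, which yields state-changing probabilities near 0.035 — the scale
reported for real cohorts. Ground truth (ROI→network maps, per-timepoint
and window-aligned modal state labels, z-scale state centroids, the group
effect table) is returned alongside the cohort and serializes to JSON.

What the generator does **not** emulate: hemodynamic convolution, scanner
drift and head motion, physiological noise, spatial autocorrelation between
neighbouring ROIs, non-Markov dwell distributions, and amplitude
differences between networks. Tests passing on these cohorts therefore
demonstrate that the estimators recover the statistical structure they
target — not that real fMRI satisfies that structure.

Two helper constructions matter for planted-recovery experiments.
`make_state_correlations` draws rank-2-plus-ridge random correlation
matrices, resampled until pairwise off-diagonal correlations stay below
0.3; with `fixed_norm=True` each network's factor loadings sit on a sphere,
bounding every state's minimum eigenvalue below by ridge/(2 + ridge)
(exactly 0.5 at the default ridge 2). Since a z-shift s moves a correlation
by at most 2·tanh(s/2), shifts up to 0.5 are then guaranteed to leave every
shifted state positive definite for every seed — planted effects are
realized exactly, never blurred by PSD repair. `zero_edges` orthogonalizes
the loadings of designated (vertex-disjoint) network pairs so their
baseline correlation is zero in every state, making the realized shift
uniform across planted edges. `effect_recovery_config` assembles the
standard recovery experiment: 25 + 25 subjects, two runs' worth of
timepoints (722; per-state frame counts ~T/ks bound the attainable β₂
precision), dwell 60 windows, subject jitter 0.15, and ±0.5 z-shifts on
five disjoint edges (three up, two down) of the last state.

## Numerical conventions

- Row-major upper-triangle vectorization; edges named `<NetA>-<NetB>` with
  GM networks ordered before WM and i < j; 0-based indices internally,
  1-based state/network names (`GM1`, `WM4`, state 1…) in all outputs.
- Correlation clipping at 1 − 1e−7 before atanh; sample (ddof = 1)
  variances and standard deviations throughout.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; every fitted pipeline is
  bit-identical under a repeated seed.
- K-means ties (equal distortion) resolve to the earliest replication in
  the seed stream; assignment labels are canonicalized by first occurrence.
- Top-fraction edge selection uses a ceiling count, ranks by absolute
  value, keeps the sign, and breaks ties by edge index.

## Problem sizes

The test suite and the acceptance script run the method on compact cohorts
chosen to keep each planted feature comfortably recoverable: 60 + 40 ROIs
in 6 + 4 networks (45 edges), 20-subject cohorts at 200 timepoints for
state recovery, 50-subject cohorts at 722 timepoints for effect recovery,
and 200-replicate calibration runs at 231 edges (the edge count of a
22-network parcellation). These sizes were picked as the smallest at which
the phenomena of interest are unambiguous.

## Known limitations

- The Dice-stability procedure is an interpretation of an ambiguous
  published description; the chunked fold-pair comparison reproduces the
  stated tensor shape, but other readings exist.
- Whether folds partition ROIs, subjects, or replications in the original
  procedure is unstated; this implementation clusters the full average FC
  per fold with independent randomization.
- Cosine K-means with raw-mean centroids is one consistent reading of
  "cosine distance" clustering; spherical K-means (re-normalized centroids)
  would differ slightly.
- The elbow rule (maximum curvature) operationalizes a criterion the
  methodology literature leaves loose ("where distortion becomes low");
  the full ratio profile is always reported so a user can override.
- Dual regression's cross-edge leakage under heavy window mixing (above)
  means β₂-based edge tests should be read with the window-to-dwell ratio
  in mind.
- The motion-exclusion hook (`mean_fd` + threshold) is a pre-filter flag
  only; no motion correction of any kind is performed.
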