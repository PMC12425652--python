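# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind gtsdm, in the spirit of a package vignette: what is
computed, under which assumptions, and what the synthetic experiments do
and do not demonstrate.

## The estimator

MaxEnt treats presence-only modelling as density estimation: the fitted
object is a probability distribution over the background sample,
`P(x) ∝ exp(λ·f(x))`, chosen to maximise the presence log-likelihood
subject to an L1 penalty.  We penalise the **mean** presence
log-likelihood,

    ℓ(λ) = (1/m) Σ_presence λ·f(x_i) − log Σ_background exp(λ·f(b)) − Σ_j β_j|λ_j|,

because the conventional default penalty schedule
`β_j = rm · β_class(m) · s_j / √m` is calibrated against the per-presence
likelihood; applying it to the summed likelihood would weaken the penalty
by a factor of m and the regularisation multiplier would lose its
practical effect on sparsity.  (The maximiser is identical to the
sum-likelihood form with penalties scaled by m.)  `β_class` interpolates
(10, 30, 100) → (1.0, 0.2, 0.05) for linear/quadratic features and
(0, 10, 17) → (0.65, 0.5, 0.25) for categorical indicators, clamped at the
ends; `s_j` is the feature's standard deviation over the background
design.  Features are linear and quadratic transforms of continuous
covariates min-max scaled to [0, 1] using background bounds (quadratics
are squares of the scaled value), plus one 0/1 indicator per declared
categorical level.  Hinge, product and threshold features are deliberately
out of scope — the package targets deliberately simple response shapes.
Projection outside the training range is clamped to [0, 1] by default.

### Solver

The penalised objective is concave.  The solver is an active-set
(orthant-wise) Newton method: features whose KKT residual exceeds the
penalty join the working set, a damped Newton step is taken in the orthant
fixed by the coefficient signs (coordinates crossing zero are truncated to
exactly zero), and a backtracking proximal-gradient step serves as
fallback.  Every accepted step increases the objective; near the optimum,
where objective improvements fall below float resolution, a full Newton
step is accepted when it halves the KKT residual instead.  Convergence is
declared at a KKT residual of 1e-6 on the mean-likelihood gradient
(features and gradients are O(1) on this scale); typical fits end around
1e-9 in 30–100 iterations.  Ties and degeneracies: constant layers are
dropped from the expansion with a warning; with all penalties zero the
method reduces to damped Newton and may legitimately fail to converge
under complete separation, in which case the results object is returned
with `converged=False` and a warning.  Raw predictions cap the exponent
at 700 so that projection far outside the training envelope saturates
instead of overflowing.

### Output scales

Raw output is the Gibbs density normalised over the training background
(sums to one there, to ~1e-16 in practice).  The cloglog transform
`1 − exp(−e^{H} · raw)`, with H the entropy of the training distribution,
maps scores monotonically into (0, 1) and is the default presentation
scale; thresholds in the validation tables live on it.  All rank-based
statistics (AUC, OR.10p) are identical under either scale.

## Data preparation

Cleaning removes records that are off the raster or on nodata, on excluded
land-cover codes (open water and similar), outside an optional known-range
polygon, and duplicates within a raster cell — the earliest-dated record
(then lowest input index) survives, a deterministic, auditable rule.
Analogue augmentation appends a related species' records inside the study
extent (tagged `analogue`, original records win cell ties) — used when a
rare species has too few records for stable validation statistics; record
bookkeeping in reports deliberately excludes augmented records so that
modelled = database − removed always holds.  The study extent is the union
of 50 km discs (cell centre test) around the cleaned records, intersected
with valid data; background points are uniform over extent cells with
uniform within-cell position.  Coordinates are planar metres throughout;
no geodesic buffering or reprojection is attempted.

## Cross-validation, tuning, selection

Checkerboard1 assigns points to two bins by block parity; blocks are
`aggregation_factor` cells on a side, anchored at the raster origin (no
random offset, favouring reproducibility).  The aggregation factor is not
dictated by the analysis design; the default is 10 (1 km blocks at 100 m
resolution) and is recorded in every run manifest.  The tuning grid
crosses feature classes {L, Q, LQ} with multipliers 1–5 (15 candidates);
each candidate is fitted per training bin and on all data.  OR.10p uses
the ceiling convention: the threshold drops the ⌈n/10⌉ lowest-scoring
training presences and omission is the fraction of withheld presences
strictly below it.  Sequential selection minimises mean OR.10p, breaking
ties by mean validation AUC, then smaller rm, then L < Q < LQ — the last
two tie-breaks are package conventions favouring simpler models and are
logged.  AICc is computed from the full-data fit with the likelihood
standardised over the background sample (all candidates share it, so the
comparison is fair and raster-free) and flagged undefined when
n ≤ ncoef + 1; the pipeline logs whether AICc and the sequential rule
agree.

## Ground-truthing

Trap surveys provide per-trap presence/absence per species.  Each trap is
scored by the model prediction at its containing cell; records are *not*
deduplicated by cell, matching how such surveys are analysed (several
traps can share one raster cell and each contributes).  AUC uncertainty on
the independent data is a seeded 1,000-replicate stratified bootstrap over
records — the "±" on the independent AUC is labelled as such in outputs.
The TSS threshold is the maxSSS rule (maximise sensitivity + specificity
over observed scores, smallest qualifying threshold on ties) computed on
the independent data itself; thresholding on training data instead is
available as an option, and the mild circularity of the default is noted
here deliberately.  The ΔAUC comparison (cross-validation minus
independent) uses a configurable ±0.02 equivalence band for its
qualitative category.

## Null models

Each iteration trains a model with the real configuration on random
localities and evaluates it against the *real* withheld occurrences and
background, per checkerboard fold, averaging folds exactly as the real
statistic does.  Two subtleties matter and are easy to get wrong:

1. **Null localities are confined to the training fold's blocks.**  The
   real training data live only in training-bin blocks; letting null
   models see withheld-area environments narrows the null distribution
   artificially (measured central-90% coverage for a signal-free species
   drops from ~0.89 to ~0.63).

2. **Fold-mean placement is anti-conservative.**  The two real fold AUCs
   are strongly coupled — by fold-swap symmetry both reduce to the same
   chance alignment between the two folds' environmental tilts — whereas a
   null iteration averages two independent fits, so the real fold-mean has
   up to twice the null variance.  The package therefore records per-fold
   null and real AUCs alongside the fold means; `significance()` reports
   the fold-mean placement (the aggregate a study reports) by default and
   the per-fold placement on request.  The per-fold comparison is
   exchangeable under no signal: measured coverage of the central 90% is
   0.887 over 600 placements, against an ideal of ~0.89 for 100-null
   empirical intervals.

Failed null fits are resampled once, then recorded and excluded; the
empirical p uses the add-one correction (1 + #{null ≥ real}) / (B + 1).

## The synthetic-data generator

Continuous covariates are Gaussian white noise convolved with an isotropic
Gaussian kernel (scale = `smoothness` cells) and affinely mapped to the
requested mean and standard deviation; the categorical layer bins an
independent smooth field into equal-frequency classes.  This reproduces
the one property the analysis depends on — spatial autocorrelation — but
not any particular covariance family, cross-covariate correlation
structure, anisotropy, or the heavy-tailed distributions of real climate
layers.  The default scene is 100×100 cells at 100 m with six continuous
layers and one 15-level categorical layer, mirroring the seven-predictor
setting the pipeline targets.

Virtual species define suitability as `link(α + η)` on standardised
covariates (L: linear terms, Q: squares, LQ: both, plus optional
categorical effects), with the intercept solved by monotone root-finding
so mean suitability equals the target prevalence to 1e-6, and occupancy
drawn once per cell.  Presence-only records sample occupied cells
∝ occupancy × bias with uniform within-cell jitter, so downstream
cell-assignment logic is exercised on continuous coordinates.  Trap
surveys place traps uniformly in site polygons and detect independently
per trap with per-method probabilities.  Detection probabilities for
funnel (0.5) and pitfall (0.7) traps are free parameters, not estimates —
capture rates for the real taxa are essentially unknown — and the survey
model has no trap saturation, no behavioural interaction between
neighbouring traps, and no false presences.

### Frozen experiment conditions

The simulation experiments fix, once:

* **Strong-signal species**: linear coefficients (2.5, −1.5, 0, 0, 0, 0)
  on standardised covariates, prevalence 0.10 — a habitat specialist of
  the kind the real analysis targets.  Recovery of this species (500
  presences, fc=L, rm=1) yields cosine similarity ≈ 0.99 between fitted
  and rescaled true coefficients and cross-validation AUC ≈ 0.87.
* **Sampling bias**: effort ∝ exp(2.5 · z) of a covariate that does *not*
  drive the species.  Environmentally structured effort is the mechanism
  by which heterogeneous databases mislead validation; a bias field
  statistically independent of all covariates is unlearnable by the model
  and produces no cross-vs-independent gap (we verified both).  With this
  bias the mean gap over 20 replicates is ≈ +0.10 to +0.14; with unbiased
  training it is ≈ −0.03 to −0.01 (slightly negative because true-absence
  negatives are easier to rank than background, which contains occupied
  cells).
* **Problem sizes**: experiments run on 60–80-cell-square landscapes with
  2,000 background points, 100–500 presences and 100 null iterations —
  small enough that the full experiment battery completes in about a
  minute, large enough that every statistical structure of the full-scale
  analysis (fold geometry, penalty regime, class imbalance) is present.

Passing these experiments shows the machinery is correct and calibrated on
data satisfying its assumptions.  It does not show that real occurrence
databases meet those assumptions — real bias is not a smooth function of
one covariate, real detection varies with weather and season, and real
covariates carry measurement error at unknown scales.

## Known limitations

* No geodesic geometry; inputs must share one planar metric frame.
* No hinge/product/threshold features, sample-bias grids, or cumulative
  output scale.
* AICc uses the background sample as its standardisation support rather
  than the full raster; absolute AICc values are therefore not comparable
  across different background samples (rankings within one run are).
* The independent-AUC bootstrap resamples records, ignoring spatial
  dependence between traps in the same cell or site; its "±" understates
  uncertainty when records cluster heavily.
* Raster I/O is the ESRI ASCII grid text format (one file per layer plus a
  JSON manifest); GeoTIFF is not read or written.
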