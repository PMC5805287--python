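# Methods

This note documents the modelling choices behind `ewnn`: the network and
its evolutionary training, the ensemble pruning procedure, the synthetic
data generators, the numerical conventions, and the limitations we know
about. It describes what the code computes; every number quoted here is
produced by the test suite or the scripts in this repository.

## The wavelet network

Each hidden unit ("wavelon") owns a fixed number of *input slots*. A slot
carries a feature index, a connection switch c ∈ {0,1}, an input weight
w ∈ [−1,1], a dilation α ∈ [0,1], an unbounded translation β and a
rotation R ∈ [−1,1]. The slot count defaults to the feature count but may
differ — with more features than slots the wavelon reads a subset, and
with fewer, slots may repeat a feature, stacking several wavelet factors
of the same coordinate. For the active slots the argument is
z = (w·x − β)/max(α, 10⁻³) and the rotation is realised as a cyclic shear
between consecutive active arguments, z′ₙ = zₙ + Rₙ·z_succ(n) (identity
when a single slot is active). The wavelon response is the product of the
wavelet function over its active slots; a wavelon with no active slot, or
with its activity bit cleared, contributes exactly 0, so pruned structure
is genuinely silent.

Choices worth flagging:

* **Wavelet forms.** Morlet `cos(5t)·e^{−t²/2}` (carrier 5, the common
  choice), Mexican hat `(1−t²)·e^{−t²/2}`, first Gaussian derivative
  `−t·e^{−t²/2}`, Haar (1 on [0,½), −1 on [½,1), 0 elsewhere). The
  heterogeneous four-function set is the default for mammography-style
  runs; clinical runs use a homogeneous Mexican-hat network.
* **Rotation realisation.** The cyclic shear is one defensible reading of
  "rotation" for a product-form multidimensional wavelet. It is isolated
  inside `wavelets.wavelon_responses` so an alternative (e.g. Givens
  rotations) can be swapped in without touching anything else.
* **Dilation floor.** α is initialised uniformly on [0,1] and may reach 0;
  the forward pass divides by max(α, 10⁻³), keeping every output finite.
  The floor value is far below any dilation that survives selection in
  practice, so it acts as a guard, not a prior.
* **Decision rule.** Targets are encoded 0/1, fitness includes the mean
  squared error of the raw output against those targets, and
  classification thresholds the raw output at 0.5 (boundary to class 1).
  Threshold and targets are consistent by construction; no calibration
  step exists.
* **Shortcuts and bias** are evolvable genes in [−1,1], mutated under the
  same continuous-gene rule as the wavelon parameters.

## Phase I: the (μ+λ) evolution strategy

Populations are sorted by training accuracy (descending) with MSE as the
tie-break (ascending) and insertion order as the final, stable tie-break;
the μ best of parents-plus-offspring survive, so the best record never
worsens. Offspring are produced by mutation only (no crossover), assigning
offspring to parents round-robin.

Mutation is per-gene and independent at rate 1%: continuous genes receive
a relative U(−10%, +10%) perturbation and are clamped back to range
(translations excepted — they are unbounded by design, since the useful
translation scale tracks the data scale and features are standardized); a
gene sitting exactly at 0 instead receives a small additive
U(−0.01, 0.01) kick so it can leave zero; binary genes invert; categorical
genes (slot feature index, wavelet identity) resample uniformly among the
*other* options. The 10% magnitude is our quantification of "perturb by a
small percentage"; it trades locality against traversal speed and is
exposed as `mutation_magnitude`.

The cross-validation harness standardizes features once on the full
training portion (not per fold): per-fold scalers would leave the pooled
genomes of different folds living in different input spaces, which breaks
the Phase II pooling. The cost is a mild information leak *within* the
training portion's folds; the held-out test set plays no part in the
scaler. Folds are stratified by class and grouped by patient when patient
identifiers exist, so no individual ever appears on both sides of a fold;
fitness is evaluated on the fold-train split only and the fold-validation
split is touched once per run to report the pooled networks' validation
accuracy. Per-run seeds derive from the master seed and the (fold, run)
pair through `numpy.random.SeedSequence`, so any single run can be
reproduced in isolation and identical master seeds give bit-identical
pools.

Reference-scale settings are 2000 generations, 50 runs per fold and
10-fold cross-validation with (1+25) or (3+20) strategies; tests and the
worked example run reduced budgets (tens of generations to 200, 2–3 folds,
3–10 runs) chosen so the full pipeline remains a minutes-scale
computation, and state their sizes explicitly.

## Phase II: pruning by genetic algorithm

An ensemble is a bit mask over a pool; combination is strict-majority
voting among the *active* classifiers (k in the majority rule is the
active-subset size — under pool-size semantics a heavily pruned ensemble
could never reach a majority), with even splits falling to the control
class. The (3+25) GA maximises F(mask) = ½·(mean individual training
accuracy of active members + ensemble training accuracy); the empty mask
is assigned fitness 0 rather than raising, which keeps the search total
and drives it away from degeneracy. Bit mutation defaults to independent
per-bit inversion at 1% (inversion changes membership, which is the point
of pruning); a literal position-swap operator is available behind
`mutation="swap"`. Ties in fitness prefer fewer active classifiers,
favouring compact ensembles. Initial masks are i.i.d. Bernoulli(½). The
test set is read exactly once, after the final generation, to score the
winning mask — a property the test suite asserts with an access-counting
wrapper.

On pools small enough to enumerate (≤20), `enumerate_best_fitness`
provides a brute-force oracle; the acceptance suite checks that the GA
with restarts attains the enumerated optimum on a pool of 8.

## Metrics conventions

The positive class is the **control** class: TP counts controls classified
as control, FP counts diseased samples classified as control. An explicit
`positive_class` argument restores the conventional orientation.
Sensitivity/specificity with a zero denominator are carried as NaN and
printed "-"; MCC with a vanishing denominator factor is defined as 0.
Patient aggregation labels an individual diseased iff strictly more than
half of their records are predicted diseased (ties → control). Reports
print percentages to one decimal place. Fold-averaged and pooled-count
summaries can differ when test folds are tiny; `TwoPhaseResults` reports
fold means and exposes the per-fold confusions for pooled alternatives.

## Synthetic data

* **Two-spiral benchmark.** For i = 0…P−1, φ = iπ/16 and
  r = 6.5·(104−i)/104; class 0 is (r·sinφ, r·cosφ) and class 1 its exact
  negation, 97 points per spiral by default, optional Gaussian jitter.
  Noiseless generation is deterministic and seed-independent.
* **Clinical generator.** Emulates repeated-measurement clinical studies:
  each patient receives a class label (diseased fraction =
  `class_balance`), a latent per-patient mean drawn from a class-shifted
  Gaussian, and records equal to that mean plus independent noise.
  Variances are split so every feature has unit total variance, the
  diseased shift is `effect_size` standard deviations on every feature,
  and the correlation between two records of one patient equals
  `within_patient_corr`. Defaults (40 patients × 26 records × 26 features,
  balance ½, effect 1 SD, correlation ½) mirror the shape of the
  speech-recording Parkinson's datasets at a moderate, realistic
  separability; tests that need near-separable or null data set the effect
  size explicitly.

What the generator does *not* model: non-Gaussian marginals, heterogeneous
per-feature effect sizes, feature–feature correlation beyond the shared
patient latent, varying record counts per patient, label noise. Passing
tests therefore demonstrate correctness of the machinery and the
qualitative ensemble-over-individual pattern, not clinical performance on
real data.

## Known limitations

* **Two-spiral separability.** With at most two active Morlet wavelons
  under the shear-coupling realisation, we have not been able to reach
  100% training accuracy on the 194-point two-spiral task — not with the
  evolution strategy at its full multi-restart budget (best ≈ 0.69), nor
  with much stronger multi-start gradient-based fits of the same
  architecture constrained to the genome's parameter ranges (best
  ≈ 0.84). The obstruction appears structural: a perfect spiral separator
  needs radial/angular nonlinearity of the form sin(θ + πr), while a
  product of Gaussian-enveloped cosines of affine functionals is a
  constrained plane-wave sum whose usable oscillation is bounded by its
  envelope. The corresponding acceptance test is kept at the full stated
  budget and currently fails; a different multidimensional wavelon
  realisation might close the gap, which is why the rotation code is
  isolated behind a single function.
* Evolution at reference scale (10 folds × 50 runs × 2000 generations) is
  embarrassingly parallel across runs but this package executes runs
  serially; per-run determinism is the contract, scheduling is the
  caller's business.
* Binary classification only; no probability calibration, no ROC/AUC, no
  multiclass generalisation of the metrics.
* The harness reads delimited text only; no image processing or upstream
  feature extraction.
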