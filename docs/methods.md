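# Methods

## The classifier

The PNN is a Parzen-window density classifier. For a query x, each class i
gets a kernel-density estimate from its training samples X_ij:

    Φ_ij = exp(−‖x − X_ij‖² / σ_i²),    s_i = (1/n_i) Σ_j Φ_ij

and the predicted class is argmax_i s_i (winner-take-all with unit output
weights). Two deliberate departures from the textbook Parzen estimator:

- The kernel exponent uses **σ² in the denominator, not 2σ²**, and carries no
  normalization constant. Both are absorbed into σ's scale: the σ the
  annealer reports is √2 times the textbook bandwidth, and dropping the
  (2π)^{d/2}σ^d normalizer is harmless for classification only because σ_i is
  shared within each class and the summation layer divides by n_i. With
  per-class σ the missing σ^d factor does bias the comparison between classes
  relative to a true density ratio; this is an inherent property of the
  method being implemented, not corrected here.
- **Equal class priors** are implicit in the per-class averaging. After SMOTE
  rebalancing to 1:1 this coincides with the training prevalence.

Prediction compares the classes through a log-domain shift (the global
maximum kernel exponent is subtracted before exponentiation). This changes
nothing at ordinary bandwidths and makes the σ → 0 limit exact: the classifier
degenerates to 1-nearest-neighbor instead of collapsing to an all-zero tie.
The literal Φ_ij and s_i values are still reported unshifted in `PNNOutput`.
Ties (exactly equal class scores) go to the first class in model order — the
negative class — so predictions are deterministic.

## Fitness and the anneal

The annealer minimizes the **resubstitution error**: the PNN is built from the
training set and scores that same training set, each sample against the full
model including its own pattern unit. Leave-one-out is deliberately not used;
it is the procedure as specified, and its known consequence — σ → 0 achieves
zero training error by memorization — is exactly why the validation guard
exists. When the best-by-training-error σ scores below `val_threshold`
(default 0.85) on the held-out validation split, the entire anneal restarts
from a fresh random σ₀ ~ Uniform(bounds), up to `max_restarts` (10) times, and
the σ with the highest validation accuracy seen is returned.

Annealing schedule: exponential cooling t_k = α·t_{k−1} from T₀ = 100 with
`count_per_temp` Metropolis moves per temperature (accept a worsening move
with probability exp(−Δf/t)), stopping when t < t_min. The neighborhood law is
a clipped Gaussian step on both coordinates, standard deviation
`neighbor_scale` (0.1) of the bound range — standard continuous-SA practice on
a box domain. Defaults: α = 0.95, t_min = 1e−3, σ ∈ (1e−3, 10), 1000 moves per
temperature. `Count` is interpreted as per-temperature (the loop structure
re-zeroes the counter after each anneal step).

Because the kernel depends on σ only through a scale, the pairwise
squared-distance matrices are precomputed once per training set and each
fitness evaluation reduces to exponentials over fixed matrices; a full anneal
on a ~200-sample training set costs well under a second at the desk-scale
budget below.

**Problem sizes.** The pipeline default (`pipeline.desk_scale_sa`) cools
faster than the single-run default — α = 0.9, 50 moves per temperature,
stop at t = 0.1, ≈ 3,300 evaluations per repeat — so the full 20-repeat
protocol completes in minutes. The error landscape here is a small set of
plateaus (error rates are multiples of 1/N), which a short anneal explores
adequately; the long schedule is available whenever a single model is being
trained (`sapnn train` defaults to it).

## SMOTE

Classic SMOTE with k = 5 neighbors (k is not prescribed by the source method;
5 is the classic default), balancing the minority class to a configurable
ratio (default 1:1) of the majority. Oversampling is applied **after**
splitting, to the training rows only; rebalancing before the split leaks
synthetic copies of validation/test information into training, and the
original procedure is ambiguous on the order. The literal
rebalance-everything-first reading is available via `smote_before_split` for
comparison. If k exceeds the minority size − 1 it is clipped with a warning.

## SD scoring and subset selection

Features are discretized by equal-width binning (default 10 bins over
[min, max], maximum value into the last bin, constant columns to bin 0); the
binning rule is not prescribed by the source method and equal-width is the
simplest defensible choice, recorded in the config. Probabilities in SD are
empirical relative frequencies; empty cells contribute zero. SD ≥ 1 always
(SD − 1 is a χ²-like dependence excess), with equality when the bin
distribution is identical in every class.

Scores are computed on the (SMOTE-augmented) training rows only — selection
is part of training. The subset search is a **nested top-k sweep** along the
SD ranking (k = 1..k_max, default 20), scored by validation accuracy of a
fixed-σ PNN (σ = 0.1; the factory is injectable); running the full anneal for
every candidate k would multiply the cost ~20-fold for little benefit at
these sample sizes. Ties break toward the lower frequency in the ranking and
the smaller k in the sweep, so the selected feature vector is deterministic.

## Evaluation protocol

Monte-Carlo cross-validation: per repeat, a stratified 60/20/20 split (per
class, floor(fraction·n) rows to validation and test, slack to training —
training receives the rounding remainder, consistent with its 60% share),
seeded `base_seed + r` for r = 0..19. SEN/SPE/ACC are computed on the test
split with the metastatic class positive and averaged over repeats. An
undefined metric (an empty class in a tiny test set) is reported as NaN with
a warning rather than silently dropped. Baseline comparators are thin
adapters over scikit-learn (MLP for the back-propagation network, SVC, kNN,
LDA/QDA/GaussianNB for the discriminant-analysis family); the shared-σ
Gaussian-kernel density classifier doubles as the RBF-network baseline, which
it is mathematically. Only the sweep/reporting logic is bespoke.

## Synthetic data

The generator emulates what the method assumes about real cohorts: two
smooth per-class spectra (logistic-in-log-frequency curves — permittivity
falling ~57 → ~20 across 50 MHz–4 GHz, conductivity rising ~0.42 → ~1.9 S/m),
the positive class elevated by `class_effect` (default 10%, optionally
confined to a band), a per-sample log-normal scale factor (sd 0.05,
emulating specimen-to-specimen magnitude variation that is common-mode across
frequency) and i.i.d. relative Gaussian noise per frequency (sd 0.02). The
default cohort is 41 positive vs 178 negative — the measured cohort's
imbalance. The default grid is 50–4000 MHz at 50 MHz (80 points); the
full-resolution 1-MHz grid (3,951 points) is available behind a flag since
nothing in the method depends on grid density.

What this does **not** emulate: physically calibrated dispersion models
(Cole–Cole/Debye), frequency-correlated noise, probe-contact artifacts,
patient-level clustering (multiple nodes per patient), or temperature
dependence. Passing tests therefore demonstrate that the pipeline recovers
planted structure under its own assumptions — not clinical performance, which
can only be established on measured data.

## Numerical choices and degenerate inputs

- Frequencies match grid columns within 1e−6 MHz (printed-decimal tolerance).
- Feature values are used unscaled by default (the method does not
  normalize); a z-score option exists on the classifier input path but is off.
- SMOTE requires ≥ 2 minority rows; single-class inputs are errors, not
  warnings.
- Splits require ≥ 3 samples per class; smaller classes raise a named error.
- All stochastic components (generator, SMOTE, splits, anneal) draw from
  `numpy.random.default_rng` seeded explicitly; identical configuration and
  seed reproduce bit-identical datasets, σ traces and report files.

## Known limitations

- The resubstitution fitness makes the anneal's training error a biased
  (optimistic) quantity; only the validation guard and the untouched test
  split give honest numbers.
- With strongly overlapping classes the guard may exhaust its restarts below
  threshold; the result is then the best validation performer, flagged via
  `threshold_met=False`.
- Two-class only at the pipeline level; the network itself is written for m
  classes but is untested beyond two.
- Equal-width discretization is sensitive to outliers in a column; robust
  binning (quantile) was considered and rejected to keep the scoring rule
  exactly the simple one stated.
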