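# Methods

This package quantifies an adulterant's mass fraction in milk-powder-like
matrices from near-infrared (NIR) spectra. Its core is an ensemble of small
1-D fully-convolutional regressors whose input wavelengths are sampled from a
learned importance distribution — either the weight-magnitude profile of a
dense "attention" network (AM-ECNN) or the absolute regression coefficients
of a PLS model (RC-ECNN). This note documents the model, its assumptions, the
parameters that matter, the synthetic data the package is validated on, and
the numerical choices made where the design was open.

## Problem setting and preprocessing

Input data are `n_samples x m` absorbance-derived spectra on a uniform
wavelength grid (nominally 900–1700 nm at 2.8 nm steps, so m = 286) with a
per-sample adulterant concentration in mass-fraction percent. Two standard
chemometric preprocessing steps precede all modeling:

1. **Trimming** to 1000–1600 nm (closed interval). The first and last
   ~100 nm of this detector range are dominated by instrument noise.
2. **Savitzky–Golay first derivative**, window 9, polynomial order 2, for
   baseline correction and smoothing. Edge points are handled by fitting the
   local polynomial on the one-sided window (`mode="interp"`), so the number
   of wavelengths m is unchanged by preprocessing — which keeps the
   importance-profile bookkeeping aligned with the data columns. The
   derivative is scaled by the grid step (units: a.u. per nm); any constant
   scale here is absorbed by the per-wavelength standardization inside model
   fitting, so this choice is cosmetic.

Targets enter the networks through an affine map from the training-target
range onto [0.1, 0.9], because every regressor ends in a sigmoid. The
interior interval (rather than [0, 1]) keeps training targets away from
sigmoid saturation, where gradients vanish. The inverse map never clamps, so
predictions may extrapolate beyond the training range.

## The convolutional sub-model

Each sub-model sees `nw` wavelengths (default 30) of one sample as a short
1-channel sequence and applies, three times:

    batch-norm -> conv(16 filters, kernel 5, stride 1, same padding) -> LeakyReLU

followed by a single affine output node over the flattened 16 x nw feature
map and a sigmoid. The LeakyReLU uses the divisor parameterization
g(x) = x for x > 0, x/a otherwise, with a = 10 (slope 0.1). There is no
pooling and no stride above 1 — with a few dozen input variables those
operations discard information — and no hidden fully-connected layer, which
keeps the parameter count at 3 conv banks + 16·nw + 1 output weights.

Training is full-batch Adam on the mean squared error in scaled-target
space, learning rate 1e-4, 2000 iterations by default (2500 is appropriate
for sharp-band data at full fidelity; both are configurable). The calibration
sets here are ~100 samples, so mini-batching has no benefit. Batch-norm uses
batch statistics during training and exponentially averaged running
statistics (momentum 0.9) at inference, so a prediction never depends on the
rest of the batch. Weight initialization is fan-in-scaled Gaussian, seeded;
initialization diversity across sub-models is intentional — it is one of the
instabilities the ensemble averages away.

The networks are implemented directly in NumPy with hand-written gradients
(convolution as an im2col matrix product; analytic batch-norm backward).
The backward pass is verified against central finite differences in float64,
and the forward pass against an independent loop-based evaluation of the
layer equations. Training computes in float32 by default (configurable to
float64), which roughly halves the wall time at no practical cost for these
problem sizes.

## Wavelength importance and probabilistic selection

A dense network (m inputs → 64 → 16 → 1 sigmoid, LeakyReLU hidden
activations) is trained on the full preprocessed training set. The attention
indicator is the column-wise sum of absolute first-layer weights,

    T_b = Σ_i |W[i, b]|,   b = 1..m,

normalized to a probability distribution T_nor = T / ΣT. Each sub-model's
nw wavelengths are drawn from T_nor **without replacement** (sequential
draws, renormalizing after each pick) and used in ascending spectral order,
so the convolution axis stays physically meaningful. Sampling — rather than
picking the top-nw wavelengths — is the accuracy/diversity compromise at the
heart of the method: informative bands are chosen often, but every
wavelength keeps a nonzero chance, so sub-models differ.

**Training regime for the attention network.** The indicator is only useful
if learned structure dominates |W|. Two defaults follow from that
requirement, and they differ from the sub-model training regime on purpose:

* The first layer is initialized near zero (scale 1e-3). With the usual
  fan-in initialization, the random starting magnitudes are an order of
  magnitude larger than anything training adds, and T is flat.
* The optimizer is plain full-batch gradient descent (lr 2.0, 2000
  iterations). Adaptive per-coordinate methods normalize step sizes, so
  uninformative wavelengths accumulate |W| as fast as informative ones and
  the profile again flattens. With plain SGD, |W| grows in proportion to how
  consistently a wavelength's gradient points in one direction, which is
  exactly the signal the indicator wants. On a test design where only 5 of
  200 channels carry signal, these defaults put >5x the uniform probability
  mass on the informative channels; the Adam/fan-in regime is
  indistinguishable from uniform.

Both choices are configurable; no regularization is applied (only weight
magnitudes are consumed, so mild overfitting is harmless).

The RC variant replaces the attention profile by the normalized absolute
regression coefficients of a NIPALS PLS1 model fit on standardized X and
centered y, with the component count chosen by internal 5-fold CV over 3–25
(capped by the rank bound min(n−1, m)). Zero-variance columns get unit SD
during standardization; they are inert after centering.

## Ensemble construction and diagnostics

Given a training set, `fit_ensemble`:

1. trains the selector profile on all training samples and wavelengths;
2. for each of `n_submodels` (default 50): draws nw wavelengths from the
   profile and a uniform-random ⌊rs·n_train⌋-sample training subset
   (without replacement, minimum 2); the complement is that sub-model's
   validation set;
3. trains the sub-model on its subset;
4. predicts by the unweighted mean of the sub-model predictions.

Everything is seeded: sub-model i's draws and initialization derive from
`SeedSequence(seed, spawn_key=(i,))`, so enlarging the ensemble never
perturbs existing members.

Two diagnostics guide the choice of (rs, nw):

* **RMSEV** — root mean squared error pooled over all (sub-model, held-out
  validation sample) pairs: the accuracy of individual sub-models.
* **MSDV** — for each sample held out by at least two sub-models, the
  population SD of their predictions, averaged over such samples: the
  diversity of the ensemble. (The mean-over-samples-of-per-sample-SD reading
  is used; a sample validated by fewer than two sub-models has no spread and
  is excluded.)

A good operating point keeps RMSEV near its plateau while retaining nonzero
MSDV; rs = 0.6 and nw = 30 are the defaults. `grid_search` tabulates both
diagnostics over an (rs, nw) grid; the operating point is chosen by
inspection, not automatically.

**When does increasing nw help?** Only while wavelengths are limiting. On
the synthetic presets whose dilution signal reaches every channel — and
whenever the selector profile is sharply concentrated — ten selected
wavelengths already saturate sub-model accuracy, and raising nw only
enlarges the output layer (16·nw weights against ~54 training samples), so
RMSEV and MSDV *worsen* with nw there. The classical decline of both
diagnostics with nw appears in the wavelength-limiting regime: sparse
informative bands and imperfect (e.g. uniform) selection, where small
subsets can starve for signal. The trend tests run in that regime; the
reversal elsewhere is a property of the data conditions, not of the
implementation. The overfitting cost of large nw is also why the default
stays at a modest 30.

## Evaluation protocol

Final accuracy is measured by external 10-fold cross-validation: shuffle
(seeded), partition, fit on 9/10 of the samples with *all* statistics —
standardization, target scaling, importance profiles, component counts —
computed inside the training partitions, and score the held-out partition by

* RMSEP = root mean squared prediction error (percent),
* R² = 1 − SS_res/SS_tot on the test fold (prediction R²; can be negative),
* RPD = SD(y_test)/RMSEP with the population SD (divisor n); reported as
  +inf for a perfect fold, and folds with constant targets are flagged and
  excluded from the R²/RPD aggregates.

Aggregates are the mean ± SD over folds. Hyper-parameter selection uses a
separate internal 5-fold CV within each training set (`internal_cv_optimize`,
first-in-grid tie-break); for the expensive CNN-family models the optimized
setting from the first external fold may be reused across folds.

The method interface is a plain callable `(trainset, X_test, seed) ->
predictions`; test targets are never passed in, so target leakage is
excluded structurally (and asserted by a corruption test).

`selection_comparison` reproduces the sub-model-level selector experiment:
within each external fold it trains matched cohorts of sub-models on *all*
training samples (rs = 1 for this experiment) with nw = 25 wavelengths drawn
either from the attention profile or uniformly, and returns each sub-model's
test RMSE for histogram comparison.

## Synthetic data: what it emulates and what it does not

The original study's spectra were never deposited, so the package generates
its own. Each data set is built from:

* **Brand endmembers** — sums of broad Gaussian bands (centers/widths/heights
  in a fixed catalog emulating milk powder's water/fat/protein overtone
  regions), with per-brand height jitter (relative SD 0.20) drawn once per
  data set. Brands are a latent nuisance factor, as in the multi-brand study
  design; per-sample brand blends are Dirichlet(1) mixtures.
* **An adulterant endmember** — broad overlapping bands for the
  HLP-like preset (0–20 %), a few sharp bands for the melamine-like preset
  (0–10 %).
* **Linear mixing**: spectrum = (1−c)·brand_mix + c·adulterant, c uniform.
* **Nuisance terms**: a random linear+quadratic baseline (coefficient SD
  0.01 a.u.) and iid Gaussian noise (SD 0.008 a.u.).

The noise and jitter levels were fixed by requiring that a well-tuned PLS
baseline lands in the difficulty regime reported for real sharp-band
adulterant data (cross-validated R² ≈ 0.99, RMSEP a few tenths of a
percent); they are study conditions, not tuning knobs.

Two honest limitations of this emulation:

* **The broad-band (HLP-like) preset is easier than real HLP.** Real
  hydrolyzed leather protein is spectrally near-identical to milk protein;
  stylized Gaussian catalogs cannot reproduce that, so baseline methods do
  better here than the real-data difficulty gap suggests.
* **The linear mixing law makes PLS nearly optimal** on the presets, so the
  ensemble's advantage over linear baselines on real data (where scattering
  and matrix effects add nonlinearity) is not reproduced; what the tests do
  show is the ensemble's advantage over a single full-spectrum CNN and the
  selector's advantage over random subspace selection.
* **Dilution signal is everywhere**: because of the (1−c) factor, *every*
  channel with background signal correlates with c. Wavelength selection
  cannot help in that regime — consistent with the method's own logic, which
  targets sparse informative bands. A third preset
  (`sparse_informative_default`) therefore puts the adulterant's two narrow
  bands on a quasi-flat background with a raised noise floor (SD 0.02), so
  that only ~10–20 of ~215 channels carry usable signal; this is the regime
  the selector-comparison experiments run in.

No instrument-specific noise model, humidity/temperature covariates, or
multiplicative scatter effects are simulated.

## Desk-scale problem sizes

The test suite and the acceptance script run the full pipeline at reduced
sizes chosen as the package's desk-scale defaults: ensembles of 12–20
sub-models (instead of 50) and 250–400 training iterations (instead of
2000), with 10-fold external CV kept intact. At these sizes a single
cross-validated ensemble run completes in a few minutes on one core.
Convergence measurements showed sub-model training loss is within noise of
its plateau after ~400 iterations on the presets; accuracy is then limited
by sub-model variance, which the ensemble size controls. Defaults inside the
library remain the full-fidelity values.

## Numerical choices and degenerate inputs

* Optimizer for sub-models: Adam (plain SGD available). Loss: MSE in
  scaled-target space.
* Batch-norm epsilon 1e-5; running-average momentum 0.9.
* Constant training targets raise a scaler error before any training starts.
* A training loss that becomes non-finite raises a divergence error naming
  the iteration.
* `sample_wavelengths` requires nw ≤ the number of strictly positive
  probabilities; degenerate (all-zero) indicators are rejected.
* NIPALS deflation stops early if the residual X carries no covariance with
  y; requesting more components than min(n−1, m) is an error.
* Internal CV ties are broken toward the earlier grid entry,
  deterministically.
* All randomness flows through `numpy.random.SeedSequence` spawn keys, so
  every experiment is exactly rerunnable from its seed.

## Known limitations

* Sub-model training is CPU-bound NumPy; ensembles are embarrassingly
  parallel but executed serially.
* The attention profile is only as good as the dense network's fit; on data
  where informative structure is dense (e.g. strong dilution signal), the
  profile is close to uniform and AM-ECNN converges to the random-subspace
  ensemble.
* Model persistence is limited to the profile/diagnostics/manifest files the
  CLI writes; trained weight archives are not serialized.
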