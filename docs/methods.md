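# Methods

## Spectral simulator

The simulator is the data source for every experiment, standing in for
field-collected kernels whose spectra are not publicly deposited. Each
maturity stage's mean spectrum is a parametric curve on a 186-point grid
over 900–1700 nm:

```
μ_c(λ) = level_c + slope_c·(λ − 900)
         − Σ_b depth_{b,c} · exp(−(λ − center_b)² / (2 width_b²))
         + rise_c / (1 + exp(−(λ − 1620)/20))
```

clipped to (0, 1). Three Gaussian bands reproduce the published
phenomenology: a moderate 970 nm absorption (C–H/O–H), a shallow *negative*
band at 1200 nm that creates the local carbohydrate reflectance peak at
1200–1300 nm, and the dominant water trough at 1400 nm (width 55 nm). The
logistic term models the rapid rise past 1600 nm. Per-stage parameters
encode the qualitative stage ordering: baseline levels 0.600 (MUS) > 0.520
(MS) > 0.440 (HM) ≈ 0.430 (UM), and 1400 nm depths 0.180 (UM) > 0.165 (HM)
> 0.115 (MS) > 0.095 (MUS), so the dehulled mature stage is brightest
everywhere and the two early, wetter stages have the deepest troughs. The
UM/HM gap is deliberately kept below the sample-level noise scale so their
PCA clouds overlap, as the original data's do. A profile that leaves (0, 1)
by more than `profile_margin` (default 0.02) before clipping raises a
configuration error — grazing the bounds is normal, busting them signals
inconsistent level/depth settings.

Sample-level noise follows the standard NIR measurement-error
decomposition: multiplicative scatter `(1+a)` with `a ~ N(0, 0.03)`, an
additive offset `b ~ N(0, 0.01)`, smooth correlated noise (white noise
convolved with a Gaussian kernel, 15-band correlation length, marginal sd
0.008) and band-wise white noise (sd 0.004). Emitted values are clipped to
[0, 1.2] rather than [0, 1] because calibrated reflectance can slightly
exceed the white reference. The noise scales were chosen once so that
tuned classifiers land in the ≥90%-but-<100% accuracy regime the original
tables report; the class-geometry parameters above were fixed at the same
time and not revisited. `total_noise_sd()` summarises the four sources in
quadrature (multiplicative term evaluated at reflectance 0.5), ≈ 0.020.

What the simulator does **not** model: husk optics or radiative transfer,
instrument-specific wavelength response, per-variety biological covariance
structure, or session/batch effects. Passing tests therefore demonstrate
that the pipeline recovers the structure this generative model encodes —
not that the GAN or the classifiers would behave identically on real
field spectra.

Grid note: the published feature count is 186 although the camera exposes
224 bands; the trimming is never explained, so the simulator follows the
186-feature setting. Per-class sample counts are likewise ambiguous in the
source (146 varieties per harvest day, two sites, two stages sharing day
85); 146 per class is a modelling choice.

## Conditional WGAN-GP

Architecture (hidden size `h`, Leaky ReLU slope 0.2, Kaiming-normal
initialisation with the slope-adjusted gain `sqrt(2/(1+0.2²)/fan_in)`,
zero biases):

* generator: (30 noise + 4 one-hot) → h → h → 186, sigmoid output;
* critic: 186 → h → h → 1, linear output, unconditional;
* classifier: 186 → h → 4 logits.

Published hyperparameters: batch size 32, learning rate 0.001, noise
dimension 30, 186 features, hidden size 512. Everything else is standard
WGAN-GP practice fixed as documented defaults: penalty coefficient λ = 10,
5 critic updates per generator update, Adam with moments (0.5, 0.9),
`z ~ N(0, I)`, sigmoid generator output. The critic is unconditional;
label consistency is enforced solely by the auxiliary classifier, which is
trained on real labelled samples only, while the generator receives the
classifier's cross-entropy on fake samples with their conditioning labels
(weight α = 1). This auxiliary-classifier reading keeps all three losses
well-posed; training the classifier to reject fakes is a plausible
alternative the source description leaves open.

One epoch is one shuffled pass over the real minibatches; per minibatch
the critic takes 5 Adam steps (fresh noise each), then the generator one,
then the classifier one. The per-epoch history records critic loss,
generator loss, classifier loss, mean penalty term and the Wasserstein
estimate `E[D(real)] − E[D(fake)]`. Training aborts with a diagnostic
naming the epoch if any loss goes non-finite.

Gradients are computed by hand in float32 numpy. The penalty term needs
second-order derivatives (the gradient of the critic's input-gradient norm
with respect to the critic's weights); because Leaky ReLU is piecewise
linear its activation masks are locally constant, so that gradient is
obtained exactly (almost everywhere) by reverse-mode differentiation
through the input-gradient recursion with the masks held fixed — the same
value a double-backward pass through an autodiff framework produces.
Hidden biases do not enter the input gradient and receive zero penalty
gradient. All first- and second-order paths are verified against central
finite differences (in float64) in the test suite.

## Scaled study conditions

The published run trains hidden size 512 for 20000 epochs with checkpoints
at 1000/2000/5000/8000/10000/20000 and judges epoch 10000 best. The
package's `scaled` profile — used by the test suite and the acceptance
script — keeps the data dimensionality and every published
hyperparameter except size: hidden 128, 2000 epochs, 80 samples per class
for in-suite training, checkpoints at 100/250/500/1000/2000. The first
checkpoint sits at 5% of total training, the same relative position as the
published grid's first entry, so the under-trained-to-converged fidelity
trajectory is preserved. The `paper` profile keeps the full-scale setting
one flag away (`--profile paper`). At the scaled setting the epoch-100
generator is visibly unconverged (class-mean RMSE ≈ 0.033) and the final
checkpoint reaches ≈ 0.026, inside twice the simulator noise sd (0.040).

## Fidelity diagnostics

PCA (2 components, centering only — autoscaling is not applied, matching
the ambiguity in the source) is fitted once on the original data; every
checkpoint's samples are projected onto that fixed basis, never refitted.
Component signs are fixed by making each component's largest-magnitude
loading positive, since eigenvector sign is otherwise arbitrary and would
break reproducibility. The visual comparison is quantified by two
summaries per (checkpoint, class): Euclidean distance between real and
synthetic centroids in score space, and band-wise RMSE between real and
synthetic class-mean spectra in reflectance units. Distribution-level
metrics (FID/KID, kernel two-sample tests) are deliberately out of scope.

## Benchmark

Stratified 8:2 split per seed (per-class `round(n·0.8)`, clipped so both
sides are non-empty), 5-fold stratified CV grid search maximising accuracy
(ties broken by grid order), refit on the full training portion. Default
grids: SVM (RBF) C ∈ {0.1, 1, 10, 100} × γ ∈ {scale, 0.01, 0.001}; RF
trees ∈ {100, 300} × max features ∈ {√p, p/3}; KNN k ∈ {3, 5, 7, 11};
PLS-LDA latent components ∈ {2, …, 15}. The source's hyperparameter table
actually prints performance metrics, so these grids are declared defaults,
not recovered settings. A `small` grid set (one or two points per model)
backs the quick scarce-data experiments.

PLS-LDA is assembled from its definition: PLS2 latent scores against the
one-hot class indicator (centering only), then LDA on the scores, with LDA
posteriors used for AUC. Features enter all classifiers unscaled —
reflectance already lives on a common [0, 1] scale.

Accuracy, macro recall/precision/F1 and Cohen's kappa
(`(p_o − p_e)/(1 − p_e)`, `p_e` from marginal products) are computed
directly from one-vs-rest confusion-matrix counts and oracle-tested against
an independent brute-force implementation. Macro averaging is used
throughout because the source reports single multiclass values without
naming an average and macro treats the four stages symmetrically. AUC is
macro one-vs-rest; models without calibrated probabilities (SVM) get
scores via a row-wise softmax of their decision values — a monotone
transform, so ranks and AUC are unaffected by the choice. A class absent
from the truth is excluded from macro averages with a warning.

Augmentation protocol: condition A trains on the real training rows,
condition B on those rows plus **all** synthetic rows; both are evaluated
on the same real test set, and synthetic rows structurally cannot enter a
test set (asserted). The paired t-test compares per-seed accuracies
(augmented − baseline), two-sided; all-zero differences return (t, p) =
(0, 1), zero-variance non-zero differences a signed infinite t with p = 0.
Three seeds is the protocol as specified; it is statistically fragile, and
`BenchmarkConfig.seeds` accepts more. The scarce-data variant subsamples
the real training rows to a fixed per-class count (20 in the acceptance
runs) before augmenting, which is where augmentation has room to help;
at the full 146-per-class scale the classifiers are near saturation and
the augmentation effect is expected to be small of either sign.

## Numerical choices and degenerate inputs

* GAN arithmetic in float32; metrics, PCA and the simulator in float64.
* Gradient-penalty norms are floored at 1e-12 before division.
* `paired_ttest` length < 2, empty loss batches, shape mismatches, unknown
  labels, non-monotone wavelength headers and degenerate (zero-variance)
  PCA inputs all raise typed errors naming the offending item.
* `round` (banker's rounding) decides per-class split sizes; for 146
  samples at 0.8 this gives 117 train / 29 test per class.
* Checkpoint persistence: `.npz` parameter arrays plus a JSON sidecar of
  the GAN config; CSV spectra are written with 9 significant digits (round
  trip to 1e-9), HDF5 losslessly.

## Known limitations

* The numpy training loop is single-threaded BLAS-bound; the full
  published scale (hidden 512, 20000 epochs) runs but takes hours, not
  minutes.
* The auxiliary-classifier reading of "fool both the discriminator and
  classifier" is one of two defensible interpretations (see above).
* Simulator realism limits transfer of any quantitative conclusion to
  real field spectra; the package demonstrates the method, not the crop.
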