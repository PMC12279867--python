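# nirgan

Conditional WGAN-GP data augmentation for near-infrared maturity-stage
classification of buckwheat kernels.

## The problem

Deciding when to harvest buckwheat is hard: the crop matures in 70–90 days
and husk colour is a poor proxy for kernel state. NIR reflectance
spectroscopy (900–1700 nm) separates the maturity stages non-destructively —
water content drives a deep absorption trough near 1400 nm, structural
carbohydrates shape a local reflectance peak at 1200–1300 nm, and
starch/protein scattering lifts reflectance past 1600 nm — but collecting
enough labelled spectra to train reliable classifiers is slow and
labour-intensive.

This package implements, as a tested reusable pipeline, the study design in
which a **conditional Wasserstein GAN with gradient penalty** generates
labelled synthetic reflectance spectra for four maturity stages (UM, 65
days; HM, 75 days; MS, 85 days with husk; MUS, 85 days dehulled), and the
effect of that augmentation is quantified on four classifiers (SVM, RF,
KNN, PLS-LDA). Because the field-collected spectra behind the original
study are not publicly deposited, the pipeline includes a first-class
simulator that reproduces the published spectral phenomenology and serves
as the data source for all experiments.

## The model

Three dense networks compete:

* generator `G(z, c)` — latent noise `z ∈ R^30` concatenated with a one-hot
  stage label `c`, two Leaky ReLU hidden layers, sigmoid output of 186
  reflectance values in (0, 1);
* critic `D(x)` — an unconditional scalar score whose real-minus-fake gap
  estimates the Wasserstein distance

  `min_G max_D  E_{x~P_r}[D(x)] − E_{x̃~P_g}[D(x̃)]`,  `x̃ = G(z, c)`,

  regularised by the gradient penalty
  `λ · E[(‖∇_x̂ D(x̂)‖₂ − 1)²]` on random interpolates
  `x̂ = ε x + (1−ε) x̃`;
* auxiliary classifier `C(x)` — softmax over the four stages, trained on
  real labelled spectra; the generator additionally minimises `C`'s
  cross-entropy on its outputs, enforcing label consistency.

Fidelity across training is diagnosed by projecting each checkpoint's
samples onto a 2-component PCA basis fitted **once** on the original data,
and summarised by per-class centroid distances and class-mean RMSE. The
benchmark follows the study protocol: stratified 8:2 splits over 3 seeds,
5-fold CV hyperparameter tuning, accuracy / macro recall / macro precision /
macro F1 / macro one-vs-rest AUC / Cohen's kappa, and a paired t-test on
accuracy with and without the 400 synthetic spectra (100 per stage).

The networks and the full training loop (including the second-order
gradients the penalty needs) are implemented in numpy and verified against
finite differences in the test suite.

## Worked example

```python
import dataclasses
from nirgan import (SimulatorConfig, GanConfig, simulate_dataset, train,
                    sample_synthetic, run_benchmark)
from nirgan.benchmark import default_model_specs

sim = dataclasses.replace(SimulatorConfig(), n_per_class=80)
data = simulate_dataset(sim)                      # 320 x 186 labelled spectra
gan = GanConfig(hidden_size=128, total_epochs=2000,
                checkpoint_epochs=(100, 250, 500, 1000, 2000), seed=0)
result = train(data, gan)                         # ~2.5 min on one CPU
synth = sample_synthetic(result.final_state, 100, seed=123)
print(synth.spectra.shape)                        # (400, 186)

specs = [m for m in default_model_specs(small=True) if m.name in ("RF", "KNN")]
bench = run_benchmark(data, synth, seeds=[0, 1, 2, 3, 4],
                      models=specs, train_per_class=20)
for name in ("RF", "KNN"):
    print(name, round(bench.mean_metric(name, "original"), 4),
          "->", round(bench.mean_metric(name, "original+synthetic"), 4))
```

Output from the run above:

```
(400, 186)
RF 0.8812 -> 0.9031
KNN 0.8625 -> 0.8719
```

i.e. with only 20 real training spectra per stage, adding the 400
GAN-generated spectra raises mean held-out accuracy of RF from 88.1% to
90.3% and of KNN from 86.3% to 87.2% — the direction of effect the
augmentation study reports for these two models.

The same pipeline is available from the shell:

```
nirgan full --out runs/demo --seed 0            # simulate → train → generate → diagnose → benchmark
nirgan simulate --profile paper --out runs/full # full-scale simulated dataset (146/class)
```

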