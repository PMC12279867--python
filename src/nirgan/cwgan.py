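"""Conditional Wasserstein GAN with gradient penalty for labelled NIR spectra.

Three competing dense networks:

* generator ``G(z, c)``: latent noise concatenated with a one-hot maturity
  label, two Leaky ReLU hidden layers, sigmoid output so synthetic
  reflectance lies in (0, 1);
* critic ``D(x)``: unconditional scalar score; its real-minus-fake score gap
  estimates the Wasserstein distance, and its input-gradient norm is pushed
  toward 1 by the gradient penalty (the soft 1-Lipschitz constraint);
* auxiliary classifier ``C(x)``: softmax over the four maturity stages,
  trained on real labelled spectra; the generator is additionally penalised
  by the classifier's cross-entropy on its outputs, which enforces label
  consistency of the generated samples.

Objective: min_G max_D  E_x~Pr[D(x)] - E_x~Pg[D(x~)]  with
x~ = G(z, c) ~ Pg, plus the gradient penalty
lambda * E[(||grad_xhat D(xhat)||_2 - 1)^2] on random interpolates
xhat = eps*x + (1-eps)*x~, and the auxiliary cross-entropy term weighted by
``classifier_weight`` in the generator loss.

All gradients, including the second-order penalty path, are computed in
:mod:`nirgan.nn`; optimisation is Adam with moments (0.5, 0.9).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .nn import DTYPE, MLP, Adam, cross_entropy
from .spectra_sim import CLASS_LABELS, SpectraDataset

DEFAULT_CHECKPOINT_EPOCHS = (1000, 2000, 5000, 8000, 10000, 20000)


@dataclass(frozen=True)
class GanConfig:
    """Hyperparameters of the three-network conditional WGAN-GP.

    ``batch_size``, ``learning_rate``, ``noise_dim``, ``n_features`` and
    ``hidden_size`` follow the published setting for this task; the penalty
    coefficient, critic-update ratio, Adam moments and output activation are
    standard WGAN-GP practice, fixed here as documented defaults.
    """

    batch_size: int = 32
    learning_rate: float = 0.001
    noise_dim: int = 30
    n_features: int = 186
    hidden_size: int = 512
    n_classes: int = 4
    class_labels: tuple[str, ...] = CLASS_LABELS
    gp_lambda: float = 10.0
    n_critic_steps: int = 5
    classifier_weight: float = 1.0
    leaky_relu_slope: float = 0.2
    adam_betas: tuple[float, float] = (0.5, 0.9)
    total_epochs: int = 20000
    checkpoint_epochs: tuple[int, ...] = DEFAULT_CHECKPOINT_EPOCHS
    seed: int = 0

    def validate(self) -> None:
        for name in ("batch_size", "noise_dim", "n_features", "hidden_size", "n_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gp_lambda < 0:
            raise ValueError("gp_lambda must be >= 0")
        if self.n_critic_steps <= 0:
            raise ValueError("n_critic_steps must be positive")
        if self.total_epochs < 0:
            raise ValueError("total_epochs must be >= 0")
        bad = [e for e in self.checkpoint_epochs if not 1 <= e <= max(self.total_epochs, 1)]
        if self.total_epochs and bad:
            raise ValueError(f"checkpoint epochs {bad} outside [1, total_epochs]")
        if len(self.class_labels) != self.n_classes:
            raise ValueError("class_labels length must equal n_classes")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["class_labels"] = list(self.class_labels)
        d["checkpoint_epochs"] = list(self.checkpoint_epochs)
        d["adam_betas"] = list(self.adam_betas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GanConfig":
        d = dict(d)
        for k in ("class_labels", "checkpoint_epochs", "adam_betas"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GanState:
    """Parameters of the three networks plus the training random stream."""

    config: GanConfig
    generator: MLP
    critic: MLP
    classifier: MLP
    epoch: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def snapshot(self) -> "GanState":
        """Deep copy of the parameters; the random stream is not duplicated."""
        return GanState(
            config=self.config,
            generator=self.generator.copy(),
            critic=self.critic.copy(),
            classifier=self.classifier.copy(),
            epoch=self.epoch,
            rng=np.random.default_rng(0),
        )

    def label_index(self, labels: np.ndarray) -> np.ndarray:
        lookup = {lab: i for i, lab in enumerate(self.config.class_labels)}
        try:
            return np.array([lookup[lab] for lab in labels])
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in {self.config.class_labels}") from exc

    def one_hot(self, labels: np.ndarray) -> np.ndarray:
        idx = self.label_index(labels)
        out = np.zeros((len(idx), self.config.n_classes), dtype=DTYPE)
        out[np.arange(len(idx)), idx] = 1.0
        return out


@dataclass
class TrainingHistory:
    """Per-epoch averages of the adversarial losses."""

    epochs: list[int] = field(default_factory=list)
    critic_loss: list[float] = field(default_factory=list)
    generator_loss: list[float] = field(default_factory=list)
    classifier_loss: list[float] = field(default_factory=list)
    gradient_penalty: list[float] = field(default_factory=list)
    wasserstein: list[float] = field(default_factory=list)  # E[D(real)] - E[D(fake)]

    def append(self, epoch: int, d: float, g: float, c: float, gp: float, w: float) -> None:
        self.epochs.append(epoch)
        self.critic_loss.append(d)
        self.generator_loss.append(g)
        self.classifier_loss.append(c)
        self.gradient_penalty.append(gp)
        self.wasserstein.append(w)

    def __len__(self) -> int:
        return len(self.epochs)


@dataclass
class SyntheticBatch:
    """Generated spectra plus their conditioning labels and source epoch."""

    spectra: np.ndarray
    labels: np.ndarray
    source_epoch: int

    def __post_init__(self) -> None:
        if self.spectra.shape[0] != len(self.labels):
            raise ValueError("spectra rows must match labels length")
        if self.spectra.size and (self.spectra.min() < 0.0 or self.spectra.max() > 1.0):
            raise ValueError("generated reflectance must lie in [0, 1]")

    def to_dataset(self, wavelengths: np.ndarray) -> SpectraDataset:
        return SpectraDataset(
            X=self.spectra.astype(float),
            wavelengths=wavelengths,
            labels=self.labels,
            source="gan-synthetic",
        )


@dataclass
class TrainResult:
    checkpoints: dict[int, GanState]
    history: TrainingHistory
    final_state: GanState
    initial_state: GanState


def init_networks(config: GanConfig, seed: int) -> GanState:
    """Build G, D and C with Kaiming-normal weights; deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    slope = config.leaky_relu_slope
    h = config.hidden_size
    gen = MLP.init(
        [config.noise_dim + config.n_classes, h, h, config.n_features],
        rng, leaky_slope=slope, out_act="sigmoid",
    )
    critic = MLP.init([config.n_features, h, h, 1], rng, leaky_slope=slope, out_act="linear")
    clf = MLP.init([config.n_features, h, config.n_classes], rng, leaky_slope=slope, out_act="linear")
    return GanState(config=config, generator=gen, critic=critic, classifier=clf,
                    rng=np.random.default_rng(seed + 1))


def generate(state: GanState, z: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Deterministic generator forward pass: spectra for given noise and labels."""
    z = np.asarray(z, dtype=DTYPE)
    if z.ndim != 2 or z.shape[1] != state.config.noise_dim:
        raise ValueError(f"z must be (n, {state.config.noise_dim})")
    if z.shape[0] != len(labels):
        raise ValueError("z rows must match labels length")
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    inp = np.concatenate([z, state.one_hot(np.asarray(labels, dtype=object))], axis=1)
    return state.generator(inp)


def gradient_penalty(
    state: GanState,
    real: np.ndarray,
    fake: np.ndarray,
    gp_lambda: float | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """lambda * E[(||grad_xhat D(xhat)||_2 - 1)^2] on random interpolates."""
    gp_lambda = state.config.gp_lambda if gp_lambda is None else gp_lambda
    real = np.asarray(real, dtype=DTYPE)
    fake = np.asarray(fake, dtype=DTYPE)
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must have the same shape")
    if gp_lambda == 0.0:
        return 0.0
    rng = state.rng if rng is None else rng
    eps = rng.uniform(size=(real.shape[0], 1)).astype(DTYPE)
    xhat = eps * real + (1.0 - eps) * fake
    _, cache = state.critic.forward(xhat)
    g, _ = state.critic.input_gradient(cache)
    norms = np.sqrt((g.astype(np.float64) ** 2).sum(axis=1))
    return float(gp_lambda * ((norms - 1.0) ** 2).mean())


def critic_loss(
    state: GanState,
    real: np.ndarray,
    fake: np.ndarray,
    gp_lambda: float | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """mean D(fake) - mean D(real) + gradient penalty."""
    real = np.asarray(real, dtype=DTYPE)
    fake = np.asarray(fake, dtype=DTYPE)
    if real.size == 0 or fake.size == 0:
        raise ValueError("critic_loss requires non-empty batches")
    if real.shape[1] != fake.shape[1]:
        raise ValueError("real and fake batches must have the same width")
    d_real = float(state.critic(real).mean())
    d_fake = float(state.critic(fake).mean())
    lam = state.config.gp_lambda if gp_lambda is None else gp_lambda
    gp = 0.0
    if lam > 0:
        if real.shape != fake.shape:
            raise ValueError("gradient penalty requires equally sized real/fake batches")
        gp = gradient_penalty(state, real, fake, lam, rng=rng)
    return d_fake - d_real + gp


def generator_loss(
    state: GanState, z: np.ndarray, labels: np.ndarray, alpha: float | None = None
) -> float:
    """-mean D(G(z,c)) + alpha * cross-entropy(C(G(z,c)), c)."""
    alpha = state.config.classifier_weight if alpha is None else alpha
    fake = generate(state, z, labels)
    adv = -float(state.critic(fake).mean())
    ce, _ = cross_entropy(state.classifier(fake), state.label_index(np.asarray(labels, dtype=object)))
    return adv + alpha * ce


def classifier_loss(state: GanState, real: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of the auxiliary classifier on real labelled spectra."""
    real = np.asarray(real, dtype=DTYPE)
    if real.size == 0:
        raise ValueError("classifier_loss requires a non-empty batch")
    ce, _ = cross_entropy(state.classifier(real), state.label_index(np.asarray(labels, dtype=object)))
    return ce


# -- training ------------------------------------------------------------


def _critic_step(state: GanState, opt: Adam, x_real, labels, rng) -> tuple[float, float, float]:
    cfg = state.config
    m = x_real.shape[0]
    z = rng.standard_normal((m, cfg.noise_dim)).astype(DTYPE)
    x_fake = generate(state, z, labels)

    both = np.concatenate([x_real, x_fake], axis=0)
    scores, cache = state.critic.forward(both)
    d_real = float(scores[:m].mean())
    d_fake = float(scores[m:].mean())
    grad_out = np.concatenate(
        [np.full((m, 1), -1.0 / m, dtype=DTYPE), np.full((m, 1), 1.0 / m, dtype=DTYPE)]
    )
    dWs, dbs, _ = state.critic.backward(cache, grad_out)

    gp_value = 0.0
    if cfg.gp_lambda > 0:
        eps = rng.uniform(size=(m, 1)).astype(DTYPE)
        xhat = eps * x_real + (1.0 - eps) * x_fake
        _, cache_h = state.critic.forward(xhat)
        g, rs = state.critic.input_gradient(cache_h)
        norms = np.sqrt((g.astype(np.float64) ** 2).sum(axis=1, keepdims=True))
        gp_value = float(cfg.gp_lambda * ((norms - 1.0) ** 2).mean())
        u = (2.0 * cfg.gp_lambda / m) * (1.0 - 1.0 / np.maximum(norms, 1e-12)) * g
        pWs, pbs = state.critic.penalty_param_grads(cache_h, rs, u.astype(DTYPE))
        dWs = [a + b for a, b in zip(dWs, pWs)]
        dbs = [a + b for a, b in zip(dbs, pbs)]

    opt.step(dWs + dbs)
    loss = d_fake - d_real + gp_value
    return loss, gp_value, d_real - d_fake


def _generator_step(state: GanState, opt: Adam, labels, rng) -> float:
    cfg = state.config
    m = len(labels)
    z = rng.standard_normal((m, cfg.noise_dim)).astype(DTYPE)
    inp = np.concatenate([z, state.one_hot(labels)], axis=1)
    x_fake, cache_g = state.generator.forward(inp)

    scores, cache_d = state.critic.forward(x_fake)
    adv = -float(scores.mean())
    _, _, dx_d = state.critic.backward(cache_d, np.full((m, 1), -1.0 / m, dtype=DTYPE))

    logits, cache_c = state.classifier.forward(x_fake)
    ce, dlogits = cross_entropy(logits, state.label_index(labels))
    _, _, dx_c = state.classifier.backward(cache_c, cfg.classifier_weight * dlogits)

    gWs, gbs, _ = state.generator.backward(cache_g, dx_d + dx_c)
    opt.step(gWs + gbs)
    return adv + cfg.classifier_weight * ce


def _classifier_step(state: GanState, opt: Adam, x_real, labels) -> float:
    logits, cache = state.classifier.forward(x_real)
    ce, dlogits = cross_entropy(logits, state.label_index(labels))
    cWs, cbs, _ = state.classifier.backward(cache, dlogits)
    opt.step(cWs + cbs)
    return ce


def train(dataset: SpectraDataset, config: GanConfig) -> TrainResult:
    """Adversarial training loop with epoch checkpointing.

    One epoch = one shuffled pass over the real minibatches; per minibatch the
    critic is updated ``n_critic_steps`` times (fresh noise each step), then
    the generator once, then the classifier once.  States are snapshotted at
    every epoch in ``checkpoint_epochs``.  Fully reproducible given the
    config seed.
    """
    config.validate()
    if dataset.n_samples == 0:
        raise ValueError("training dataset is empty")
    if dataset.n_bands != config.n_features:
        raise ValueError(
            f"dataset has {dataset.n_bands} bands but config.n_features = {config.n_features}"
        )
    state = init_networks(config, config.seed)
    initial_state = state.snapshot()
    rng = state.rng
    betas = config.adam_betas
    opt_d = Adam(state.critic.params(), lr=config.learning_rate, beta1=betas[0], beta2=betas[1])
    opt_g = Adam(state.generator.params(), lr=config.learning_rate, beta1=betas[0], beta2=betas[1])
    opt_c = Adam(state.classifier.params(), lr=config.learning_rate, beta1=betas[0], beta2=betas[1])

    X = dataset.X.astype(DTYPE)
    labels = dataset.labels
    n = dataset.n_samples
    checkpoint_set = set(config.checkpoint_epochs)
    checkpoints: dict[int, GanState] = {}
    history = TrainingHistory()

    for epoch in range(1, config.total_epochs + 1):
        order = rng.permutation(n)
        sums = np.zeros(5)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x_real = X[idx]
            lab = labels[idx]
            for _ in range(config.n_critic_steps):
                d_loss, gp_val, wass = _critic_step(state, opt_d, x_real, lab, rng)
            g_loss = _generator_step(state, opt_g, lab, rng)
            c_loss = _classifier_step(state, opt_c, x_real, lab)
            sums += (d_loss, g_loss, c_loss, gp_val, wass)
            n_batches += 1
        avg = sums / n_batches
        if not np.all(np.isfinite(avg)):
            raise RuntimeError(f"non-finite loss at epoch {epoch}: {avg}")
        history.append(epoch, *avg)
        state.epoch = epoch
        if epoch in checkpoint_set:
            checkpoints[epoch] = state.snapshot()

    return TrainResult(
        checkpoints=checkpoints,
        history=history,
        final_state=state,
        initial_state=initial_state,
    )


def sample_synthetic(state: GanState, n_per_class: int, seed: int) -> SyntheticBatch:
    """Generate exactly ``n_per_class`` spectra for each maturity stage."""
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    cfg = state.config
    rng = np.random.default_rng(seed)
    labels = np.array(
        [lab for lab in cfg.class_labels for _ in range(n_per_class)], dtype=object
    )
    z = rng.standard_normal((len(labels), cfg.noise_dim)).astype(DTYPE)
    spectra = (
        generate(state, z, labels) if len(labels) else np.empty((0, cfg.n_features), dtype=DTYPE)
    )
    return SyntheticBatch(spectra=spectra, labels=labels, source_epoch=state.epoch)
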