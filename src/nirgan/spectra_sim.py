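"""Class-conditional simulation of NIR reflectance spectra of buckwheat kernels.

Real reflectance of kernels in the 900-1700 nm window is dominated by a broad
water absorption trough near 1400 nm (O-H stretching overtones), a moderate
C-H/O-H absorption around 900-1000 nm, a local reflectance peak at
1200-1300 nm from structural carbohydrates, and a rapid rise past 1600 nm
from starch/protein scattering.  The four maturity stages are ordered in
overall reflectance (dehulled mature MUS highest, then husked mature MS, with
the two earlier stages HM and UM lower and strongly overlapping), and the
earlier stages show deeper 1400-1500 nm troughs from their higher water
content.

The generative model is a per-class baseline (level + linear tilt) minus a
sum of Gaussian absorption bands plus a logistic post-1600 rise, clipped to
(0, 1).  Sample-level variability combines multiplicative scatter, an
additive offset, smooth correlated noise and white noise — the standard
decomposition of NIR measurement error used by scatter-correction methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Maturity-stage vocabulary, in harvest order: unripe (65 d), half mature
#: (75 d), mature with husk (85 d), mature dehulled (85 d).
CLASS_LABELS = ("UM", "HM", "MS", "MUS")


@dataclass(frozen=True)
class AbsorptionBand:
    """One Gaussian absorption feature: depth_c * exp(-(l-center)^2 / (2 width^2)).

    Negative depths model local reflectance bumps.
    """

    center_nm: float
    width_nm: float
    depth: dict[str, float]  # per-class depth, reflectance fraction


def _default_bands() -> tuple[AbsorptionBand, ...]:
    return (
        # moderate C-H / O-H combination absorption
        AbsorptionBand(970.0, 40.0, {"UM": 0.055, "HM": 0.048, "MS": 0.042, "MUS": 0.038}),
        # shallow negative band -> local carbohydrate reflectance peak 1200-1300 nm
        AbsorptionBand(1200.0, 60.0, {"UM": -0.015, "HM": -0.015, "MS": -0.015, "MUS": -0.015}),
        # dominant water trough; deeper for the wetter early stages
        AbsorptionBand(1400.0, 55.0, {"UM": 0.180, "HM": 0.165, "MS": 0.115, "MUS": 0.095}),
    )


@dataclass(frozen=True)
class SimulatorConfig:
    """Full generative description of the synthetic four-stage spectra.

    Defaults reproduce the qualitative stage phenomenology above on a
    186-band grid over 900-1700 nm with 146 samples per stage.
    """

    wavelength_start: float = 900.0
    wavelength_end: float = 1700.0
    n_bands: int = 186
    class_labels: tuple[str, ...] = CLASS_LABELS
    baseline_level: dict[str, float] = field(
        default_factory=lambda: {"UM": 0.430, "HM": 0.440, "MS": 0.520, "MUS": 0.600}
    )
    baseline_slope: dict[str, float] = field(
        default_factory=lambda: {c: 2.0e-5 for c in CLASS_LABELS}
    )  # reflectance per nm, relative to wavelength_start
    absorption_bands: tuple[AbsorptionBand, ...] = field(default_factory=_default_bands)
    post_1600_rise: dict[str, float] = field(
        default_factory=lambda: {c: 0.06 for c in CLASS_LABELS}
    )
    rise_center_nm: float = 1620.0
    rise_width_nm: float = 20.0
    sigma_mult: float = 0.03  # multiplicative scatter sd
    sigma_add: float = 0.01  # additive offset sd
    sigma_white: float = 0.004  # band-wise white noise sd
    sigma_smooth: float = 0.008  # correlated smooth-noise sd
    smooth_corr_bands: float = 15.0  # correlation length of the smooth noise, in bands
    n_per_class: int = 146
    seed: int = 0
    profile_margin: float = 0.02  # tolerated pre-clip excursion outside (0, 1)

    def validate(self) -> None:
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        if self.wavelength_end <= self.wavelength_start:
            raise ValueError("wavelength_end must exceed wavelength_start")
        if len(set(self.class_labels)) != 4:
            raise ValueError("class_labels must be 4 distinct labels")
        for band in self.absorption_bands:
            if not self.wavelength_start <= band.center_nm <= self.wavelength_end:
                raise ValueError(f"band center {band.center_nm} nm outside the grid")
            if band.width_nm <= 0:
                raise ValueError("band widths must be positive")
        for sd in (self.sigma_mult, self.sigma_add, self.sigma_white, self.sigma_smooth):
            if sd < 0:
                raise ValueError("noise sds must be >= 0")
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_start, self.wavelength_end, self.n_bands)

    def total_noise_sd(self) -> float:
        """Scalar summary of per-band noise: quadrature sum of the four sources.

        The multiplicative term is evaluated at a representative reflectance
        of 0.5 so the summary does not depend on the class.
        """
        return float(
            np.sqrt(
                (self.sigma_mult * 0.5) ** 2
                + self.sigma_add**2
                + self.sigma_white**2
                + self.sigma_smooth**2
            )
        )


@dataclass(frozen=True)
class ClassProfile:
    """Noise-free mean reflectance spectrum of one maturity stage."""

    label: str
    mean_spectrum: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.mean_spectrum <= 0.0) or np.any(self.mean_spectrum >= 1.0):
            raise ValueError("class profile must lie strictly in (0, 1)")


@dataclass
class SpectraDataset:
    """Labelled reflectance matrix on a common wavelength grid.

    The common currency of the pipeline: the simulator emits it, the GAN
    trains on it, the benchmark splits it.
    """

    X: np.ndarray  # (n_samples, n_bands) reflectance fractions
    wavelengths: np.ndarray  # (n_bands,) nm, strictly increasing
    labels: np.ndarray  # (n_samples,) maturity-class strings
    source: str = "simulated"  # simulated | gan-synthetic | file

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.X.ndim != 2 or self.X.shape[1] != self.wavelengths.size:
            raise ValueError("X must be (n_samples, n_bands) matching the grid")
        if self.X.shape[0] != self.labels.size:
            raise ValueError("labels length must match the number of rows")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("reflectance values must be finite")
        if self.X.size and (self.X.min() < 0.0 or self.X.max() > 1.2):
            raise ValueError("reflectance values must lie in [0, 1.2]")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def class_mean(self, label: str) -> np.ndarray:
        mask = self.labels == label
        if not mask.any():
            raise ValueError(f"no samples with label {label!r}")
        return self.X[mask].mean(axis=0)


def build_class_profiles(config: SimulatorConfig) -> list[ClassProfile]:
    """Evaluate the generative band model into one mean spectrum per stage.

    profile(l) = level + slope*(l - l0) - sum_b depth_b * gauss(l; center_b, width_b)
                 + rise / (1 + exp(-(l - rise_center)/rise_width)),
    clipped to (0, 1).  Raises if the raw profile leaves (0, 1) by more than
    ``profile_margin`` — that signals inconsistent level/depth settings rather
    than ordinary boundary grazing.
    """
    config.validate()
    lam = config.wavelengths
    profiles = []
    for label in config.class_labels:
        mu = config.baseline_level[label] + config.baseline_slope[label] * (
            lam - config.wavelength_start
        )
        for band in config.absorption_bands:
            mu = mu - band.depth[label] * np.exp(
                -((lam - band.center_nm) ** 2) / (2.0 * band.width_nm**2)
            )
        mu = mu + config.post_1600_rise[label] / (
            1.0 + np.exp(-(lam - config.rise_center_nm) / config.rise_width_nm)
        )
        if mu.min() < -config.profile_margin or mu.max() > 1.0 + config.profile_margin:
            raise ValueError(
                f"profile for {label!r} leaves (0,1) by more than the configured "
                f"margin {config.profile_margin} (range [{mu.min():.3f}, {mu.max():.3f}]); "
                "level/depth settings are inconsistent"
            )
        mu = np.clip(mu, 1e-6, 1.0 - 1e-6)
        profiles.append(ClassProfile(label, mu))
    return profiles


def _smooth_noise(
    rng: np.random.Generator, n: int, n_bands: int, sd: float, corr_bands: float
) -> np.ndarray:
    """Stationary Gaussian noise with ~``corr_bands`` correlation length.

    White noise convolved with a Gaussian kernel, then rescaled so each band
    has marginal sd ``sd``.
    """
    if sd == 0.0 or n == 0:
        return np.zeros((n, n_bands))
    half = int(np.ceil(3 * corr_bands))
    taps = np.exp(-0.5 * (np.arange(-half, half + 1) / corr_bands) ** 2)
    taps /= np.sqrt((taps**2).sum())  # unit output variance before scaling
    white = rng.standard_normal((n, n_bands + 2 * half))
    out = np.empty((n, n_bands))
    for i in range(n):
        out[i] = np.convolve(white[i], taps, mode="valid")
    return sd * out


def simulate_dataset(config: SimulatorConfig) -> SpectraDataset:
    """Draw ``n_per_class`` noisy spectra around each class profile.

    Row model: profile * (1 + a) + b + smooth(l) + white, with
    a ~ N(0, sigma_mult), b ~ N(0, sigma_add), smooth a correlated Gaussian
    process along the grid, white i.i.d. per band; clipped to [0, 1.2].
    Fully deterministic given the config (including its seed).
    """
    config.validate()
    profiles = build_class_profiles(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_per_class
    blocks, labels = [], []
    for prof in profiles:
        a = rng.normal(0.0, config.sigma_mult, size=(n, 1))
        b = rng.normal(0.0, config.sigma_add, size=(n, 1))
        smooth = _smooth_noise(rng, n, config.n_bands, config.sigma_smooth, config.smooth_corr_bands)
        white = rng.normal(0.0, config.sigma_white, size=(n, config.n_bands))
        rows = prof.mean_spectrum[None, :] * (1.0 + a) + b + smooth + white
        blocks.append(np.clip(rows, 0.0, 1.2))
        labels.extend([prof.label] * n)
    X = np.vstack(blocks) if blocks else np.empty((0, config.n_bands))
    return SpectraDataset(
        X=X, wavelengths=config.wavelengths, labels=np.array(labels, dtype=object), source="simulated"
    )
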