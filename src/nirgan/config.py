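"""Pipeline configuration: YAML round-trip, validation, profiles.

Two run profiles are provided.  ``paper`` uses the published full-scale GAN
setting (hidden size 512, 20000 epochs, checkpoints at
1000/2000/5000/8000/10000/20000, 146 samples per class).  ``scaled`` is the
desk-scale counterpart used by the test suite and the one-command
reproduction: hidden size 128, 2000 epochs, 80 samples per class, with
proportionally placed checkpoints.  Both profiles share every other default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cwgan import GanConfig
from .spectra_sim import AbsorptionBand, SimulatorConfig

SCALED_GAN = {
    "hidden_size": 128,
    "total_epochs": 2000,
    "checkpoint_epochs": (100, 250, 500, 1000, 2000),
}
SCALED_SIM = {"n_per_class": 80}


class ConfigError(ValueError):
    """A pipeline configuration key is unknown or invalid."""


def sim_config_to_dict(cfg: SimulatorConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["class_labels"] = list(cfg.class_labels)
    d["absorption_bands"] = [
        {"center_nm": b.center_nm, "width_nm": b.width_nm, "depth": dict(b.depth)}
        for b in cfg.absorption_bands
    ]
    return d


def sim_config_from_dict(d: dict) -> SimulatorConfig:
    d = dict(d)
    if "class_labels" in d:
        d["class_labels"] = tuple(d["class_labels"])
    if "absorption_bands" in d:
        d["absorption_bands"] = tuple(AbsorptionBand(**b) for b in d["absorption_bands"])
    _check_keys(d, SimulatorConfig, "simulator")
    return SimulatorConfig(**d)


def _check_keys(d: dict, cls, section: str) -> None:
    known = set(cls.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{section}': {sorted(unknown)}")


@dataclass(frozen=True)
class DiagnosticsConfig:
    n_per_class: int = 100
    make_plots: bool = True


@dataclass(frozen=True)
class BenchmarkConfig:
    seeds: tuple[int, ...] = (0, 1, 2)
    train_frac: float = 0.8
    cv_folds: int = 5
    small_grids: bool = False
    scarce_train_per_class: int | None = None  # scarce-data variant when set
    n_synthetic_per_class: int = 100


@dataclass(frozen=True)
class PipelineConfig:
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    gan: GanConfig = field(default_factory=GanConfig)
    diagnostics: DiagnosticsConfig = field(default_factory=DiagnosticsConfig)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    seed: int = 0
    profile: str = "scaled"
    output_dir: str = "nirgan_out"

    def validate(self) -> None:
        self.simulator.validate()
        try:
            self.gan.validate()
        except ValueError as exc:
            raise ConfigError(f"gan.{exc}") from exc
        if self.gan.gp_lambda < 0:
            raise ConfigError("gan.gp_lambda must be >= 0")
        if self.profile not in ("scaled", "paper"):
            raise ConfigError("profile must be 'scaled' or 'paper'")

    def to_dict(self) -> dict:
        return {
            "simulator": sim_config_to_dict(self.simulator),
            "gan": self.gan.to_dict(),
            "diagnostics": dataclasses.asdict(self.diagnostics),
            "benchmark": dataclasses.asdict(self.benchmark),
            "seed": self.seed,
            "profile": self.profile,
            "output_dir": self.output_dir,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def apply_profile(config: PipelineConfig) -> PipelineConfig:
    """Overlay the scaled-profile GAN/simulator sizes when profile == 'scaled'."""
    if config.profile != "scaled":
        return config
    gan = dataclasses.replace(config.gan, **SCALED_GAN)
    sim = dataclasses.replace(config.simulator, **SCALED_SIM)
    return dataclasses.replace(config, gan=gan, simulator=sim)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML pipeline config, filling defaults for omitted keys.

    The run profile supplies size defaults (``scaled`` shrinks the GAN and
    simulator; ``paper`` keeps the published full-scale setting); keys set
    explicitly in the file always win over the profile.  Unknown keys raise
    :class:`ConfigError` naming the key; invalid values raise naming the
    section and constraint.  ``overrides`` is a flat dict of top-level
    replacements applied after parsing (used by the CLI flags).
    """
    overrides = dict(overrides or {})
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must be a mapping")
    known = {"simulator", "gan", "diagnostics", "benchmark", "seed", "profile", "output_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    profile = str(overrides.get("profile", raw.get("profile", "scaled")))
    sim_d = dict(raw.get("simulator", {}))
    gan_d = dict(raw.get("gan", {}))
    if profile == "scaled":
        for k, v in SCALED_SIM.items():
            sim_d.setdefault(k, v)
        for k, v in SCALED_GAN.items():
            gan_d.setdefault(k, v)
    sim = sim_config_from_dict(sim_d)
    _check_keys(gan_d, GanConfig, "gan")
    try:
        gan = GanConfig.from_dict(gan_d)
    except TypeError as exc:
        raise ConfigError(f"gan: {exc}") from exc
    diag_d = dict(raw.get("diagnostics", {}))
    _check_keys(diag_d, DiagnosticsConfig, "diagnostics")
    bench_d = dict(raw.get("benchmark", {}))
    _check_keys(bench_d, BenchmarkConfig, "benchmark")
    if "seeds" in bench_d:
        bench_d["seeds"] = tuple(bench_d["seeds"])
    cfg = PipelineConfig(
        simulator=sim,
        gan=gan,
        diagnostics=DiagnosticsConfig(**diag_d),
        benchmark=BenchmarkConfig(**bench_d),
        seed=int(raw.get("seed", 0)),
        profile=profile,
        output_dir=str(raw.get("output_dir", "nirgan_out")),
    )
    overrides.pop("profile", None)
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    try:
        cfg.validate()
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path
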