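"""Stage orchestration: simulate -> train-gan -> generate -> diagnose -> benchmark.

Every stage writes its artifacts under the output directory together with a
JSON manifest recording the stage name, input files, config hash, seed and
package version, so each output is traceable to the exact configuration that
produced it.  Re-running with an identical config and seed reproduces
identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .benchmark import default_model_specs, run_benchmark
from .config import PipelineConfig, save_config
from .cwgan import SyntheticBatch, train
from .diagnostics import epoch_sweep
from .io_formats import load_checkpoint, read_spectra, save_checkpoint, write_spectra
from .spectra_sim import simulate_dataset
from .cwgan import sample_synthetic

log = logging.getLogger("nirgan")

STAGES = ("simulate", "train-gan", "generate", "diagnose", "benchmark", "full")


class MissingArtifactError(FileNotFoundError):
    """A downstream stage is missing an upstream output."""


def _write_manifest(out: Path, stage: str, inputs: list[str], config: PipelineConfig) -> None:
    manifest = {
        "stage": stage,
        "inputs": sorted(inputs),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }
    (out / f"manifest_{stage.replace('-', '_')}.json").write_text(
        json.dumps(manifest, indent=2) + "\n"
    )


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"required file {path} not found; run the '{producer}' stage first"
        )
    return path


def run_stage(stage: str, config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run one pipeline stage (or 'full' for the whole chain).

    Returns a dict of the artifact paths written.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    config.validate()
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "effective_config.yaml")

    if stage == "full":
        artifacts = {}
        for s in STAGES[:-1]:
            artifacts.update(run_stage(s, config, out))
        return artifacts

    if stage == "simulate":
        sim = dataclasses.replace(config.simulator, seed=config.simulator.seed + config.seed)
        dataset = simulate_dataset(sim)
        path = write_spectra(dataset, out / "simulated_spectra.csv", "csv")
        log.info("simulate: %d rows x %d bands -> %s", dataset.n_samples, dataset.n_bands, path)
        _write_manifest(out, stage, [], config)
        return {"spectra": path}

    if stage == "train-gan":
        data_path = _require(out / "simulated_spectra.csv", "simulate")
        dataset = read_spectra(data_path, "csv")
        gan_cfg = dataclasses.replace(config.gan, seed=config.gan.seed + config.seed)
        result = train(dataset, gan_cfg)
        hist = result.history
        ckpt_paths = []
        for epoch, state in sorted(result.checkpoints.items()):
            p = save_checkpoint(state, gan_cfg, out / f"checkpoint_{epoch:06d}.npz")
            ckpt_paths.append(p)
        import pandas as pd

        hist_path = out / "training_history.csv"
        pd.DataFrame(
            {
                "epoch": hist.epochs,
                "critic_loss": hist.critic_loss,
                "gen_loss": hist.generator_loss,
                "clf_loss": hist.classifier_loss,
                "gp": hist.gradient_penalty,
                "wasserstein": hist.wasserstein,
            }
        ).to_csv(hist_path, index=False)
        for e, w in zip(hist.epochs, hist.wasserstein):
            if e % 100 == 0:
                log.info("train-gan: epoch %d wasserstein %.4f", e, w)
        _write_manifest(out, stage, [data_path.name], config)
        return {"history": hist_path, "checkpoints": ckpt_paths}

    if stage == "generate":
        ckpts = sorted(out.glob("checkpoint_*.npz"))
        if not ckpts:
            raise MissingArtifactError(
                f"no checkpoint_*.npz under {out}; run the 'train-gan' stage first"
            )
        state, _ = load_checkpoint(ckpts[-1])  # converged = last checkpoint epoch
        batch = sample_synthetic(state, config.benchmark.n_synthetic_per_class, config.seed)
        data_path = _require(out / "simulated_spectra.csv", "simulate")
        wavelengths = read_spectra(data_path, "csv").wavelengths
        path = write_spectra(batch.to_dataset(wavelengths), out / "synthetic_spectra.csv", "csv")
        log.info("generate: %d synthetic rows from epoch %d -> %s",
                 batch.spectra.shape[0], batch.source_epoch, path)
        _write_manifest(out, stage, [ckpts[-1].name, data_path.name], config)
        return {"synthetic": path}

    if stage == "diagnose":
        data_path = _require(out / "simulated_spectra.csv", "simulate")
        ckpts = sorted(out.glob("checkpoint_*.npz"))
        if not ckpts:
            raise MissingArtifactError(
                f"no checkpoint_*.npz under {out}; run the 'train-gan' stage first"
            )
        original = read_spectra(data_path, "csv")
        states = {}
        for p in ckpts:
            state, _ = load_checkpoint(p)
            states[state.epoch] = state
        diag = epoch_sweep(
            states,
            original,
            n_per_class=config.diagnostics.n_per_class,
            seed=config.seed,
            plot_dir=out / "plots" if config.diagnostics.make_plots else None,
        )
        diag_path = out / "diagnostics.csv"
        diag.to_frame().to_csv(diag_path, index=False)
        _write_manifest(out, stage, [data_path.name] + [p.name for p in ckpts], config)
        return {"diagnostics": diag_path}

    # stage == "benchmark"
    data_path = _require(out / "simulated_spectra.csv", "simulate")
    synth_path = _require(out / "synthetic_spectra.csv", "generate")
    original = read_spectra(data_path, "csv")
    synth_ds = read_spectra(synth_path, "csv")
    synthetic = SyntheticBatch(
        spectra=np.clip(synth_ds.X, 0.0, 1.0), labels=synth_ds.labels, source_epoch=-1
    )
    bench_cfg = config.benchmark
    result = run_benchmark(
        original,
        synthetic,
        seeds=[s + config.seed for s in bench_cfg.seeds],
        models=default_model_specs(small=bench_cfg.small_grids),
        train_frac=bench_cfg.train_frac,
        cv_folds=bench_cfg.cv_folds,
        train_per_class=bench_cfg.scarce_train_per_class,
    )
    bench_path = out / "benchmark_metrics.csv"
    result.to_frame().to_csv(bench_path, index=False)
    tt_path = out / "benchmark_ttests.json"
    tt_path.write_text(
        json.dumps(
            {
                "ttests_accuracy_augmented_minus_baseline": {
                    m: {"t": t, "p": p} for m, (t, p) in result.ttests.items()
                },
                "mean_accuracy": {
                    m: {c: result.mean_metric(m, c) for c in result.conditions}
                    for m in result.model_names
                },
            },
            indent=2,
        )
        + "\n"
    )
    _write_manifest(out, "benchmark", [data_path.name, synth_path.name], config)
    return {"benchmark": bench_path, "ttests": tt_path}
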