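"""Reading and writing labelled spectra tables and model checkpoints.

The interchange format is a wide CSV — ``id,label`` then one column per band
named by its wavelength in nm — because chemometrics tooling conventionally
consumes spectra that way; HDF5 is offered for lossless storage.  Band
columns are keyed by wavelength rather than index so datasets on different
grids fail loudly instead of silently misaligning.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .spectra_sim import CLASS_LABELS, SpectraDataset


class SchemaError(ValueError):
    """A spectra table violates the wide-table schema."""


def _check_labels(labels: np.ndarray, vocabulary: tuple[str, ...]) -> None:
    for i, lab in enumerate(labels):
        if lab not in vocabulary:
            raise SchemaError(f"unknown label {lab!r} at row {i} (expected one of {vocabulary})")


def write_spectra(dataset: SpectraDataset, path: str | Path, format: str = "csv") -> Path:
    """Write a dataset as wide CSV or HDF5; deterministic byte content."""
    path = Path(path)
    if format == "csv":
        cols = {"id": np.arange(dataset.n_samples), "label": dataset.labels}
        for j, wl in enumerate(dataset.wavelengths):
            cols[format_wavelength(wl)] = dataset.X[:, j]
        pd.DataFrame(cols).to_csv(path, index=False, lineterminator="\n", float_format="%.9g")
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=dataset.X)
            f.create_dataset("wavelengths", data=dataset.wavelengths)
            f.create_dataset("labels", data=np.array([str(l) for l in dataset.labels], dtype="S16"))
            f.create_dataset("meta", data=json.dumps({"source": dataset.source}))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def format_wavelength(wl: float) -> str:
    """Canonical band-column name: the wavelength with up to 6 significant decimals."""
    return f"{wl:.6f}".rstrip("0").rstrip(".")


def read_spectra(
    path: str | Path,
    format: str = "csv",
    vocabulary: tuple[str, ...] = CLASS_LABELS,
) -> SpectraDataset:
    """Read a wide CSV or HDF5 spectra table, validating schema and labels."""
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise SchemaError("missing 'label' column")
        band_cols = [c for c in df.columns if c not in ("id", "label")]
        try:
            wls = np.array([float(c) for c in band_cols])
        except ValueError as exc:
            raise SchemaError(f"non-numeric band column name: {exc}") from exc
        if np.any(np.diff(wls) <= 0):
            raise SchemaError("wavelength columns are not strictly increasing")
        labels = df["label"].to_numpy(dtype=object)
        _check_labels(labels, vocabulary)
        X = df[band_cols].to_numpy(dtype=float)
        return SpectraDataset(X=X, wavelengths=wls, labels=labels, source="file")
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            X = f["X"][()]
            wls = f["wavelengths"][()]
            labels = np.array([l.decode() for l in f["labels"][()]], dtype=object)
            meta = json.loads(f["meta"][()])
        if np.any(np.diff(wls) <= 0):
            raise SchemaError("wavelengths are not strictly increasing")
        _check_labels(labels, vocabulary)
        return SpectraDataset(X=X, wavelengths=wls, labels=labels, source=meta.get("source", "file"))
    raise ValueError(f"unknown format {format!r}")


def average_replicates(scans: np.ndarray) -> np.ndarray:
    """Band-wise arithmetic mean of k repeated scans of the same sample.

    Mirrors the acquisition protocol in which each sample is scanned several
    times against a white reference and the replicate spectra are averaged.
    """
    scans = np.asarray(scans, dtype=float)
    if scans.ndim != 2 or scans.shape[0] == 0:
        raise ValueError("scans must be a non-empty (k, n_bands) matrix")
    return scans.mean(axis=0)


# -- GAN checkpoint persistence ------------------------------------------


def save_checkpoint(state, config, path: str | Path) -> Path:
    """Persist a GAN state as .npz parameters plus a JSON config sidecar."""
    from .cwgan import GanConfig, GanState  # local import to avoid a cycle

    assert isinstance(state, GanState) and isinstance(config, GanConfig)
    path = Path(path)
    arrays = {"epoch": np.array(state.epoch)}
    for name, net in (("g", state.generator), ("d", state.critic), ("c", state.classifier)):
        for i, w in enumerate(net.weights):
            arrays[f"{name}_w{i}"] = w
        for i, b in enumerate(net.biases):
            arrays[f"{name}_b{i}"] = b
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(config.to_dict(), indent=2))
    return path


def load_checkpoint(path: str | Path):
    """Load a checkpoint written by :func:`save_checkpoint`.

    Returns (GanState, GanConfig).
    """
    from .cwgan import GanConfig, init_networks

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    config = GanConfig.from_dict(json.loads(sidecar.read_text()))
    state = init_networks(config, seed=0)
    with np.load(path) as data:
        state.epoch = int(data["epoch"])
        for name, net in (("g", state.generator), ("d", state.critic), ("c", state.classifier)):
            for i in range(len(net.weights)):
                net.weights[i] = data[f"{name}_w{i}"]
                net.biases[i] = data[f"{name}_b{i}"]
    return state, config
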