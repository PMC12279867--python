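"""Fidelity diagnostics for generated spectra across training checkpoints.

A 2-component PCA is fitted once on the original spectra and reused as the
projection basis for every checkpoint's synthetic samples, so all epochs are
compared in the same coordinate frame.  Fidelity is summarised per
(checkpoint, class) by two quantitative twins of the usual visual check:
the Euclidean distance between real and synthetic class centroids in PCA
space, and the band-wise RMSE between the real and synthetic class-mean
spectra in original reflectance units.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .cwgan import GanState, sample_synthetic
from .spectra_sim import SpectraDataset


@dataclass(frozen=True)
class PcaModel:
    """Mean vector, orthonormal component rows and explained-variance fractions."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_bands)
    explained_variance_ratio: np.ndarray

    def hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.mean).tobytes())
        h.update(np.ascontiguousarray(self.components).tobytes())
        return h.hexdigest()


@dataclass
class EpochDiagnostics:
    """Per-(checkpoint, class) fidelity records plus plotting coordinates."""

    records: list[dict] = field(default_factory=list)  # epoch, label, centroid_distance, mean_rmse
    scatter: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    pca_hash: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def fit_pca(original: SpectraDataset, n_components: int = 2) -> PcaModel:
    """Top principal components of the mean-centred original spectra.

    Eigenvector sign is arbitrary, so each component is flipped to make its
    largest-magnitude loading positive — keeps projections reproducible.
    """
    if original.n_samples <= n_components:
        raise ValueError("need more samples than components")
    if np.allclose(original.X.std(axis=0), 0.0):
        raise ValueError("degenerate dataset: zero variance in every band")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(original.X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PcaModel(
        mean=pca.mean_.copy(),
        components=comps,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def project(pca: PcaModel, X: np.ndarray) -> np.ndarray:
    """(X - mean) @ components^T."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != pca.mean.size:
        raise ValueError(f"X has {X.shape[1]} bands, PCA expects {pca.mean.size}")
    return (X - pca.mean) @ pca.components.T


def centroid_distance(
    real_scores: np.ndarray,
    synth_scores: np.ndarray,
    labels_real: np.ndarray,
    labels_synth: np.ndarray,
) -> dict[str, float]:
    """Per-class Euclidean distance between real and synthetic centroids."""
    out = {}
    for lab in dict.fromkeys(labels_real):
        mask_r = np.asarray(labels_real) == lab
        mask_s = np.asarray(labels_synth) == lab
        if not mask_s.any():
            raise ValueError(f"class {lab!r} missing from the synthetic scores")
        out[lab] = float(
            np.linalg.norm(real_scores[mask_r].mean(axis=0) - synth_scores[mask_s].mean(axis=0))
        )
    for lab in dict.fromkeys(labels_synth):
        if not (np.asarray(labels_real) == lab).any():
            raise ValueError(f"class {lab!r} missing from the real scores")
    return out


def epoch_sweep(
    checkpoints: dict[int, GanState],
    original: SpectraDataset,
    n_per_class: int = 100,
    seed: int = 0,
    plot_dir: str | Path | None = None,
) -> EpochDiagnostics:
    """Project every checkpoint's samples on the original-data PCA basis.

    The same sampling seed is used at every checkpoint so differences between
    epochs reflect the generator parameters, not the noise draw.  If
    ``plot_dir`` is given, one scatter plot per checkpoint plus an
    original-data panel are written there.
    """
    if not checkpoints:
        raise ValueError("no checkpoints to diagnose")
    pca = fit_pca(original, n_components=2)
    real_scores = project(pca, original.X)
    diag = EpochDiagnostics(pca_hash=pca.hash())
    class_means = {lab: original.class_mean(lab) for lab in original.classes}

    for epoch in sorted(checkpoints):
        batch = sample_synthetic(checkpoints[epoch], n_per_class, seed)
        synth_scores = project(pca, batch.spectra)
        dists = centroid_distance(real_scores, synth_scores, original.labels, batch.labels)
        for lab in original.classes:
            synth_mean = batch.spectra[batch.labels == lab].mean(axis=0)
            rmse = float(np.sqrt(((synth_mean - class_means[lab]) ** 2).mean()))
            diag.records.append(
                {
                    "epoch": epoch,
                    "label": lab,
                    "centroid_distance": dists[lab],
                    "mean_rmse": rmse,
                }
            )
        diag.scatter[epoch] = (synth_scores, batch.labels)

    if plot_dir is not None:
        _write_plots(Path(plot_dir), real_scores, original.labels, diag)
    return diag


def _write_plots(plot_dir: Path, real_scores, real_labels, diag: EpochDiagnostics) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)
    panels = [("original", real_scores, real_labels)] + [
        (f"epoch_{e}", s, l) for e, (s, l) in sorted(diag.scatter.items())
    ]
    for name, scores, labels in panels:
        fig, ax = plt.subplots(figsize=(5, 4))
        for lab in dict.fromkeys(labels):
            m = np.asarray(labels) == lab
            ax.scatter(scores[m, 0], scores[m, 1], s=8, alpha=0.6, label=str(lab))
        ax.set_xlabel("PCA1")
        ax.set_ylabel("PCA2")
        ax.set_title(name)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(plot_dir / f"pca_{name}.png", dpi=110)
        plt.close(fig)
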