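"""Masked change matrices and PCA feature reduction.

Baseline maps define a voxel mask (cross-subject mean strictly above a
threshold, 0.2 by default); the same baseline-derived mask is applied to
both timepoints. The change matrix is follow-up minus baseline restricted
to in-mask voxels, flattened in C-order raster. Each modality's change
matrix is then reduced to K principal-component features (columns centered,
not scaled; K = 100 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .synthetic import VoxelMapSet

__all__ = [
    "Mask",
    "ChangeMatrix",
    "PCAModel",
    "build_mask",
    "apply_mask_and_delta",
    "fit_pca",
    "variance_report",
    "save_pca",
    "load_pca",
]


@dataclass
class Mask:
    include: np.ndarray  # boolean, 3D
    threshold: float

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())


@dataclass
class ChangeMatrix:
    """Follow-up minus baseline values at in-mask voxels, one row per
    subject; columns follow the C-order raster of the mask."""

    values: np.ndarray
    subject_ids: list[str]
    modality: str


@dataclass
class PCAModel:
    """Centered (unscaled) PCA basis with a deterministic sign convention:
    each component's largest-|loading| entry is positive."""

    mean_vector: np.ndarray
    loadings: np.ndarray  # (n_voxels, K), orthonormal columns
    explained_variance_ratio: np.ndarray
    K: int

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean_vector) @ self.loadings

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.loadings.T + self.mean_vector


def _baseline_array(maps: "VoxelMapSet | np.ndarray") -> np.ndarray:
    return maps.baseline if isinstance(maps, VoxelMapSet) else np.asarray(maps)


def build_mask(baseline_maps: "VoxelMapSet | np.ndarray", threshold: float = 0.2) -> Mask:
    """Voxel included iff the cross-subject baseline mean strictly exceeds
    ``threshold``. Raises when no voxel survives."""
    arr = _baseline_array(baseline_maps)
    if arr.ndim != 4 or arr.shape[0] < 1:
        raise ValueError("expected a (subject, x, y, z) baseline array")
    include = arr.mean(axis=0) > threshold
    if not include.any():
        raise ValueError(
            f"mask threshold {threshold} excludes every voxel; "
            "lower it or check the input maps"
        )
    return Mask(include=include, threshold=threshold)


def apply_mask_and_delta(
    baseline: VoxelMapSet, followup: "VoxelMapSet | None" = None, mask: Mask | None = None
) -> ChangeMatrix:
    """Follow-up minus baseline at in-mask voxels.

    ``followup=None`` takes both timepoints from the first argument's
    ``VoxelMapSet``. Columns are ordered by the C-order raster of the mask.
    """
    if isinstance(baseline, VoxelMapSet):
        base_arr, modality = baseline.baseline, baseline.modality
        if followup is None:
            followup = baseline
    else:
        base_arr, modality = np.asarray(baseline), "unknown"
        if followup is None:
            raise ValueError("follow-up maps are required with raw baseline arrays")
    follow_arr = followup.followup if isinstance(followup, VoxelMapSet) else np.asarray(followup)
    if mask is None:
        raise ValueError("a mask built from baseline maps is required")
    if base_arr.shape != follow_arr.shape:
        raise ValueError(
            f"shape mismatch: baseline {base_arr.shape} vs follow-up {follow_arr.shape}"
        )
    if mask.include.shape != base_arr.shape[1:]:
        raise ValueError(
            f"mask shape {mask.include.shape} does not match maps {base_arr.shape[1:]}"
        )
    n = base_arr.shape[0]
    delta = (follow_arr - base_arr).reshape(n, -1)[:, mask.include.ravel()]
    return ChangeMatrix(
        values=delta,
        subject_ids=[f"S{i:05d}" for i in range(n)],
        modality=modality,
    )


def fit_pca(
    delta: "ChangeMatrix | np.ndarray", K: int = 100
) -> tuple[PCAModel, np.ndarray]:
    """Fit a K-component PCA to the change matrix; returns the model and
    the n x K centered projection scores."""
    values = delta.values if isinstance(delta, ChangeMatrix) else np.asarray(delta, float)
    n, v = values.shape
    if K > min(n - 1, v):
        raise ValueError(f"K={K} exceeds min(n-1, v)={min(n - 1, v)}")
    pca = PCA(n_components=K, svd_solver="full")
    scores = pca.fit_transform(values)
    loadings = pca.components_.T  # (v, K)

    top = np.argmax(np.abs(loadings), axis=0)
    flip = np.where(loadings[top, np.arange(K)] < 0, -1.0, 1.0)
    loadings = loadings * flip
    scores = scores * flip

    model = PCAModel(
        mean_vector=pca.mean_,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        K=K,
    )
    return model, scores


def variance_report(model: PCAModel) -> np.ndarray:
    """Cumulative explained-variance curve over components 1..K."""
    return np.cumsum(model.explained_variance_ratio)


def save_pca(model: PCAModel, path: str | Path) -> None:
    """Persist mean, loadings and ratios as a single TSV archive."""
    v, K = model.loadings.shape
    df = pd.DataFrame(model.loadings, columns=[f"pc{j + 1}" for j in range(K)])
    df.insert(0, "mean", model.mean_vector)
    df.to_csv(path, sep="\t", index=False)
    ratio_path = Path(path).with_suffix(".ratios.tsv")
    pd.DataFrame({"explained_variance_ratio": model.explained_variance_ratio}).to_csv(
        ratio_path, sep="\t", index=False
    )


def load_pca(path: str | Path) -> PCAModel:
    df = pd.read_csv(path, sep="\t")
    mean = df.pop("mean").to_numpy()
    loadings = df.to_numpy()
    ratios = pd.read_csv(Path(path).with_suffix(".ratios.tsv"), sep="\t")[
        "explained_variance_ratio"
    ].to_numpy()
    return PCAModel(
        mean_vector=mean,
        loadings=loadings,
        explained_variance_ratio=ratios,
        K=loadings.shape[1],
    )
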