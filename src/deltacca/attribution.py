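"""Occlusion-based feature attribution and voxel back-projection.

A feature's contribution to each latent component is the mean shift of the
latent representation when that input feature (a PCA score column) is set
to zero while all others are left unchanged: occluding feature j, the
per-sample difference between the occluded and original latent vectors is
averaged over samples, giving row j of the feature x component
contribution matrix. Absolute values are used only for ranking. Linear
weight vectors can be scattered back through the PCA basis into the voxel
mask for spatial display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cca import CCAModel
from .dccae import DCCAEModel
from .preprocess import Mask, PCAModel

__all__ = [
    "ContributionMatrix",
    "occlusion_contributions",
    "top_features",
    "backproject_weights",
]


@dataclass
class ContributionMatrix:
    """Signed mean latent shifts, feature x component, for one view."""

    scores: np.ndarray
    view: str

    @property
    def abs_scores(self) -> np.ndarray:
        return np.abs(self.scores)


def _latent_fn(model, view: str):
    view = view.upper()
    if view not in ("X", "Y"):
        raise ValueError(f"view must be 'X' or 'Y', got {view!r}")
    if isinstance(model, DCCAEModel):
        return model.latents_x if view == "X" else model.latents_y
    if isinstance(model, CCAModel):
        if view == "X":
            return lambda X: (X - model.x_mean) @ model.u
        return lambda Y: (Y - model.y_mean) @ model.v
    raise TypeError(f"unsupported model type {type(model).__name__}")


def occlusion_contributions(model, X: np.ndarray, view: str = "X") -> ContributionMatrix:
    """Contribution score matrix by single-feature occlusion.

    For each input feature j the raw column is zeroed (before any
    centering the model applies internally), the data is re-encoded, and
    the mean over samples of (occluded - original) latent vectors forms
    row j. For a 100-feature input and 20 latent dimensions this yields
    the 100 x 20 contribution matrix.
    """
    X = np.asarray(X, dtype=float)
    latent = _latent_fn(model, view)
    base = latent(X)
    p = X.shape[1]
    scores = np.empty((p, base.shape[1]))
    for j in range(p):
        Xo = X.copy()
        Xo[:, j] = 0.0
        scores[j] = (latent(Xo) - base).mean(axis=0)
    return ContributionMatrix(scores=scores, view=view.upper())


def top_features(
    contribs: ContributionMatrix, component: int, top_k: int = 5
) -> np.ndarray:
    """Feature indices ranked by |contribution| to one component,
    descending; ties broken by the lower feature index."""
    p, k = contribs.scores.shape
    if not 0 <= component < k:
        raise IndexError(f"component {component} outside [0, {k})")
    if top_k > p:
        raise ValueError(f"top_k={top_k} exceeds feature count {p}")
    order = np.argsort(-contribs.abs_scores[:, component], kind="stable")
    return order[:top_k]


def backproject_weights(
    component_weights: np.ndarray, pca_model: PCAModel, mask: Mask
) -> np.ndarray:
    """Scatter a linear component weight vector back into voxel space.

    Voxel values are PCA loadings times the component weights at in-mask
    positions (C-order raster, matching the change-matrix columns);
    out-of-mask voxels are zero. Signs are preserved so positive and
    negative regions stay distinguishable.
    """
    w = np.asarray(component_weights, dtype=float).ravel()
    if w.shape[0] != pca_model.K:
        raise ValueError(
            f"weight vector length {w.shape[0]} does not match PCA K={pca_model.K}"
        )
    voxel_values = pca_model.loadings @ w
    if voxel_values.shape[0] != mask.n_voxels:
        raise ValueError(
            f"PCA basis covers {voxel_values.shape[0]} voxels but the mask "
            f"has {mask.n_voxels}"
        )
    out = np.zeros(mask.include.shape)
    out[mask.include] = voxel_values
    return out
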