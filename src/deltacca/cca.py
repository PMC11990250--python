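"""Linear canonical correlation analysis with ridge-stabilised covariances.

Fits paired projection weights (u, v) maximising the Pearson correlation
between canonical variates Xu and Yv, subject to unit-variance variates,
via the SVD of the whitened cross-covariance

    T = (S_x + r I)^{-1/2} S_xy (S_y + r I)^{-1/2}.

Held-out projection, per-component correlation t-tests, and the dual-split
(train AND test) Bonferroni screen live here as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CCAModel",
    "ComponentScreen",
    "fit_cca",
    "project",
    "correlation_significance",
    "select_significant",
    "train_test_split_indices",
]

# Relative eigenvalue cutoff below which an unridged covariance is treated
# as singular.
_SINGULAR_RTOL = 1e-10


@dataclass
class CCAModel:
    """Fitted CCA: weights, training means and per-component correlations.

    Training variates ``(X - x_mean) @ u`` have unit sample variance
    (ddof=1); ``train_correlations`` are nonincreasing Pearson correlations
    of the paired training variates, sign-fixed to be nonnegative.
    """

    u: np.ndarray
    v: np.ndarray
    train_correlations: np.ndarray
    ridge: tuple[float, float]
    train_n: int
    x_mean: np.ndarray
    y_mean: np.ndarray

    @property
    def k(self) -> int:
        return self.u.shape[1]


@dataclass
class ComponentScreen:
    """Per-component dual-split significance screen.

    A component is flagged significant only when its correlation p-value is
    below ``alpha_corrected`` in BOTH the training and the testing split.
    """

    train_r: np.ndarray
    train_p: np.ndarray
    test_r: np.ndarray
    test_p: np.ndarray
    significant: np.ndarray
    alpha_corrected: float
    m_tests: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.train_r) + 1),
                "train_r": self.train_r,
                "train_p": self.train_p,
                "test_r": self.test_r,
                "test_p": self.test_p,
                "significant": self.significant,
            }
        )


def _cov(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Cross-covariance of centered matrices with 1/(n-1) scaling."""
    return A.T @ B / (A.shape[0] - 1)


def _inv_sqrt(S: np.ndarray, what: str, ridged: bool) -> np.ndarray:
    """Symmetric inverse square root; errors on singularity when unridged."""
    S = (S + S.T) / 2.0
    w, V = np.linalg.eigh(S)
    if w[0] <= _SINGULAR_RTOL * max(w[-1], 1.0):
        if not ridged:
            raise np.linalg.LinAlgError(
                f"{what} covariance is singular (min eigenvalue {w[0]:.3e}); "
                "pass a positive ridge to regularise it"
            )
        w = np.clip(w, _SINGULAR_RTOL * max(w[-1], 1.0), None)
    return (V / np.sqrt(w)) @ V.T


def fit_cca(
    X: np.ndarray,
    Y: np.ndarray,
    k: int = 20,
    ridge: float | None = None,
) -> CCAModel:
    """Fit a k-component linear CCA on paired views.

    Parameters
    ----------
    X, Y
        Row-aligned (n, p) and (n, q) matrices.
    k
        Number of canonical component pairs, ``k <= min(p, q)``. Default 20.
    ridge
        Added to the diagonal of each view's covariance. ``None`` picks
        ``1e-4 * trace(S)/p`` per view; ``0`` disables regularisation and
        raises on singular covariance.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"row mismatch: X has {X.shape[0]} rows, Y {Y.shape[0]}")
    n, p = X.shape
    q = Y.shape[1]
    if k > min(p, q):
        raise ValueError(f"k={k} exceeds min(p, q)={min(p, q)}")
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean

    Sx = _cov(Xc, Xc)
    Sy = _cov(Yc, Yc)
    Sxy = _cov(Xc, Yc)

    if ridge is None:
        rx = 1e-4 * np.trace(Sx) / p
        ry = 1e-4 * np.trace(Sy) / q
    else:
        rx = ry = float(ridge)
    ridged = rx > 0

    Kx = _inv_sqrt(Sx + rx * np.eye(p), "X", ridged)
    Ky = _inv_sqrt(Sy + ry * np.eye(q), "Y", ridged)

    U, _, Vt = np.linalg.svd(Kx @ Sxy @ Ky)
    u = Kx @ U[:, :k]
    v = Ky @ Vt[:k].T

    # Rescale so training variates have unit sample variance (exact under
    # ridge = 0, enforced empirically otherwise).
    vx = Xc @ u
    vy = Yc @ v
    u = u / vx.std(axis=0, ddof=1)
    v = v / vy.std(axis=0, ddof=1)
    vx = Xc @ u
    vy = Yc @ v

    # Sign convention: corr(Xu_j, Yv_j) >= 0, then largest-|u_j| entry > 0.
    r = np.array([np.corrcoef(vx[:, j], vy[:, j])[0, 1] for j in range(k)])
    flip_v = np.where(r < 0, -1.0, 1.0)
    v = v * flip_v
    r = np.abs(r)
    top = np.argmax(np.abs(u), axis=0)
    flip_pair = np.where(u[top, np.arange(k)] < 0, -1.0, 1.0)
    u = u * flip_pair
    v = v * flip_pair

    order = np.argsort(-r, kind="stable")
    return CCAModel(
        u=u[:, order],
        v=v[:, order],
        train_correlations=r[order],
        ridge=(rx, ry),
        train_n=n,
        x_mean=x_mean,
        y_mean=y_mean,
    )


def project(
    model: CCAModel, X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project data through fitted weights; correlations are per-component
    Pearson r on the provided sample. Centering uses the training means."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != model.u.shape[0] or Y.shape[1] != model.v.shape[0]:
        raise ValueError(
            f"column mismatch: model expects ({model.u.shape[0]}, "
            f"{model.v.shape[0]}) features, got ({X.shape[1]}, {Y.shape[1]})"
        )
    vx = (X - model.x_mean) @ model.u
    vy = (Y - model.y_mean) @ model.v
    r = _pairwise_corr(vx, vy)
    return vx, vy, r


def _pairwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Columnwise Pearson r between paired columns of A and B."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    denom = np.linalg.norm(Ac, axis=0) * np.linalg.norm(Bc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->j", Ac, Bc) / denom
    return np.where(denom > 0, r, 0.0)


def correlation_significance(r, n: int):
    """Two-sided p-value for a Pearson correlation.

    Uses the exact-null t statistic ``t = r sqrt(n-2) / sqrt(1-r^2)`` on
    n - 2 degrees of freedom. Accepts scalars or arrays.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 to test a correlation, got n={n}")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    r = np.clip(r, -1.0, 1.0)
    degenerate = np.abs(r) >= 1.0
    if np.any(degenerate):
        warnings.warn(
            "perfect correlation encountered; returning p = 0 for it",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = np.where(degenerate, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return float(p) if p.ndim == 0 else p


def select_significant(
    train_r: np.ndarray,
    test_r: np.ndarray,
    train_n: int,
    test_n: int,
    alpha: float = 0.05,
    m: int | None = None,
) -> ComponentScreen:
    """Bonferroni dual-split screen: significant iff p < alpha/m in both
    the training and the testing split."""
    train_r = np.asarray(train_r, dtype=float)
    test_r = np.asarray(test_r, dtype=float)
    if train_r.shape != test_r.shape:
        raise ValueError("train and test correlation vectors differ in length")
    if m is None:
        m = len(train_r)
    if m == 0:
        raise ValueError("number of tests m must be positive")
    alpha_corrected = alpha / m
    train_p = np.atleast_1d(correlation_significance(train_r, train_n))
    test_p = np.atleast_1d(correlation_significance(test_r, test_n))
    significant = (train_p < alpha_corrected) & (test_p < alpha_corrected)
    return ComponentScreen(
        train_r=train_r,
        train_p=train_p,
        test_r=test_r,
        test_p=test_p,
        significant=significant,
        alpha_corrected=alpha_corrected,
        m_tests=m,
    )


def train_test_split_indices(
    n: int, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random 80/20-style subject split, deterministic given seed."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(train_fraction * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
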