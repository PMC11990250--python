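"""Independent brute-force oracles used only by the test suite.

These deliberately take different computational routes than the package:
canonical correlations via the generalized eigenvalue problem rather than
a whitened SVD, PCA via a dense eigendecomposition of the sample
covariance, and p-values via numerical quadrature of the t density.
"""

import numpy as np
from scipy import integrate, linalg, special


def cca_canonical_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Canonical correlations from the generalized eigenproblem
    S_xy S_y^-1 S_yx u = rho^2 S_x u."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    n = X.shape[0]
    Sx = Xc.T @ Xc / (n - 1)
    Sy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    w = linalg.eigvals(Sxy @ np.linalg.inv(Sy) @ Sxy.T, Sx)
    rho = np.sqrt(np.clip(np.real(w), 0.0, 1.0))
    return np.sort(rho)[::-1]


def pca_eigendecomposition(values: np.ndarray):
    """Eigenvalues/vectors of the dense sample covariance, descending."""
    Xc = values - values.mean(axis=0)
    C = Xc.T @ Xc / (values.shape[0] - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    return w[order], V[:, order]


def t_two_sided_p(t: float, df: int) -> float:
    """Two-sided tail probability by quadrature of the t density."""

    def pdf(x):
        c = special.gamma((df + 1) / 2) / (
            np.sqrt(df * np.pi) * special.gamma(df / 2)
        )
        return c * (1 + x**2 / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(pdf, abs(t), np.inf)
    return 2.0 * tail
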