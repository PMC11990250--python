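"""Component-outcome association and cross-method comparison.

Latent brain-growth components are related to outcome-change scores with
linear mixed-effects models: the component, age and sex enter as fixed
effects and the collection site as a random intercept, fitted by REML with
Wald tests on the fixed effects. Variance explained by a combined set of
components is the increment in marginal (fixed-effects) R^2 over a
covariates-only model. CCA and DCCAE components are compared by all-pairs
Pearson correlation with an absolute-value retention threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .cca import correlation_significance

__all__ = [
    "AssociationResult",
    "CorrelationTable",
    "fit_lme_association",
    "variance_explained",
    "cross_method_correlation",
]


@dataclass
class AssociationResult:
    component: int
    outcome: str
    coefficient: float
    std_error: float
    p_value: float
    sign: str

    def __post_init__(self) -> None:
        self.sign = "+" if self.coefficient >= 0 else "-"


@dataclass
class CorrelationTable:
    """Pairs of CCA/DCCAE components correlated above |r| > threshold."""

    rows: pd.DataFrame  # columns cca_index, dccae_index, r, p
    threshold: float


def _mixed_fit(formula: str, data: pd.DataFrame):
    """REML random-intercept fit.

    The default quasi-Newton optimizer can stop with fixed effects
    inconsistent with a boundary (zero) site-variance estimate, so fits
    that land on or near the boundary, or fail to converge, are re-run
    with Powell's method, which resolves the degenerate case exactly.
    """
    model = smf.mixedlm(formula, data=data, groups=data["site"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = None
        try:
            res = model.fit(reml=True)
        except Exception:
            pass
        needs_polish = (
            res is None
            or not res.converged
            or float(res.cov_re.iloc[0, 0]) < 1e-3 * float(res.scale)
        )
        if needs_polish:
            try:
                polished = model.fit(reml=True, method="powell", maxiter=2000)
                if np.isfinite(polished.params).all():
                    res = polished
            except Exception:
                pass
        if res is None:
            raise RuntimeError(f"mixed-model fit failed for {formula!r}")
    return res


def fit_lme_association(
    component_scores: np.ndarray,
    outcome: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    site: np.ndarray,
    component_index: int = 0,
    outcome_name: str = "outcome",
) -> AssociationResult:
    """Single-component random-intercept LME association.

    Fits ``outcome ~ component + age + sex`` with a random intercept per
    site (REML); returns the component's fixed-effect coefficient, Wald
    standard error, two-sided p-value and sign. Rows with missing values
    are dropped listwise. A boundary fit (zero estimated site variance) is
    reported with a warning rather than raised.
    """
    data = pd.DataFrame(
        {
            "y": np.asarray(outcome, float),
            "component": np.asarray(component_scores, float),
            "age": np.asarray(age, float),
            "sex": np.asarray(sex, float),
            "site": np.asarray(site),
        }
    ).dropna()
    if data["site"].nunique() < 2:
        raise ValueError("need at least 2 sites for a random-intercept model")
    res = _mixed_fit("y ~ component + age + sex", data)
    if res.cov_re.iloc[0, 0] <= 1e-10:
        warnings.warn(
            "site variance estimated at the boundary (~0); reporting the "
            "boundary fit",
            RuntimeWarning,
            stacklevel=2,
        )
    return AssociationResult(
        component=component_index,
        outcome=outcome_name,
        coefficient=float(res.params["component"]),
        std_error=float(res.bse["component"]),
        p_value=float(res.pvalues["component"]),
        sign="+",
    )


def _marginal_r2(res, data: pd.DataFrame, fixed_cols: list[str]) -> float:
    """Nakagawa-style marginal R^2: fixed-effect variance over fixed +
    random-intercept + residual variance."""
    X = sm.add_constant(data[fixed_cols]) if fixed_cols else None
    if fixed_cols:
        pred = X.to_numpy() @ res.fe_params.to_numpy()
    else:
        pred = np.full(len(data), res.fe_params.iloc[0])
    var_f = float(np.var(pred))
    var_re = float(res.cov_re.iloc[0, 0])
    var_res = float(res.scale)
    return var_f / (var_f + var_re + var_res)


def variance_explained(
    gm_components: np.ndarray,
    fa_components: np.ndarray,
    outcome: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    site: np.ndarray,
) -> float:
    """Percent outcome variance explained by the combined GM and FA
    components beyond age and sex.

    Both component sets enter one mixed model jointly (random site
    intercept); the result is ``100 * (R2m_full - R2m_covariates)`` with
    marginal (fixed-effects) R^2, clamped at 0 — the increment can come
    out marginally negative through REML variance re-estimation.
    """
    G = np.atleast_2d(np.asarray(gm_components, float))
    F = np.atleast_2d(np.asarray(fa_components, float))
    if G.shape[0] != F.shape[0]:
        raise ValueError("GM and FA component matrices must be row-aligned")
    n = G.shape[0]
    a, b = G.shape[1], F.shape[1]
    if a + b >= n:
        raise ValueError(
            f"{a + b} components for {n} subjects would overfit; reduce the set"
        )
    data = pd.DataFrame(
        {
            "y": np.asarray(outcome, float),
            "age": np.asarray(age, float),
            "sex": np.asarray(sex, float),
            "site": np.asarray(site),
        }
    )
    comp_cols = []
    for j in range(a):
        data[f"gm{j + 1}"] = G[:, j]
        comp_cols.append(f"gm{j + 1}")
    for j in range(b):
        data[f"fa{j + 1}"] = F[:, j]
        comp_cols.append(f"fa{j + 1}")
    data = data.dropna()

    full = _mixed_fit("y ~ " + " + ".join(comp_cols + ["age", "sex"]), data)
    cov_only = _mixed_fit("y ~ age + sex", data)
    r2_full = _marginal_r2(full, data, comp_cols + ["age", "sex"])
    r2_cov = _marginal_r2(cov_only, data, ["age", "sex"])
    increment = 100.0 * (r2_full - r2_cov)
    if increment < 0:
        warnings.warn(
            f"variance-explained increment {increment:.3f} < 0; clamping to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        increment = 0.0
    return increment


def cross_method_correlation(
    cca_variates: np.ndarray,
    dccae_variates: np.ndarray,
    threshold: float = 0.15,
) -> CorrelationTable:
    """All-pairs Pearson correlation between CCA and DCCAE variates,
    keeping pairs with |r| > threshold (sign flips between methods are
    expected and carry no meaning, hence the absolute value)."""
    A = np.asarray(cca_variates, float)
    B = np.asarray(dccae_variates, float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("variate matrices must be row-aligned")
    n = A.shape[0]
    Ac = (A - A.mean(axis=0)) / A.std(axis=0, ddof=0)
    Bc = (B - B.mean(axis=0)) / B.std(axis=0, ddof=0)
    R = Ac.T @ Bc / n  # (k1, k2)
    rows = []
    for i in range(R.shape[0]):
        for j in range(R.shape[1]):
            r = R[i, j]
            if abs(r) > threshold:
                rows.append(
                    {
                        "cca_index": i + 1,
                        "dccae_index": j + 1,
                        "r": r,
                        "p": correlation_significance(r, n),
                    }
                )
    frame = pd.DataFrame(rows, columns=["cca_index", "dccae_index", "r", "p"])
    return CorrelationTable(rows=frame, threshold=threshold)
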