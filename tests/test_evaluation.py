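"""Mixed-effects associations, variance explained and method comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deltacca import (
    SyntheticSpec,
    cross_method_correlation,
    fit_lme_association,
    generate_coupled_views,
    generate_outcomes,
    variance_explained,
)


def _center_within_site(y, site):
    df = pd.DataFrame({"y": y, "site": site})
    return y - df.groupby("site")["y"].transform("mean").to_numpy() + y.mean()


@pytest.fixture(scope="module")
def outcome_data():
    spec = SyntheticSpec(
        n_subjects=1200,
        p_x=8,
        p_y=8,
        k_latent=2,
        canonical_corrs=(0.6, 0.3),
        site_sd=0.0,
        seed=2,
        outcome_effects={"y": np.array([0.5, 0.0])},
    )
    views = generate_coupled_views(spec)
    out = generate_outcomes(views, spec)
    return views, out


def test_boundary_fit_matches_ols(outcome_data):
    """With exactly zero between-site variation REML lands on the
    boundary and the fixed effects coincide with OLS."""
    import statsmodels.api as sm

    views, out = outcome_data
    z = views.true_latents[:, 0]
    y = _center_within_site(out["y"].to_numpy(), out["site"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fit_lme_association(
            z,
            y,
            out["age"].to_numpy(),
            out["sex"].to_numpy(),
            out["site"].to_numpy(),
        )
    X = sm.add_constant(np.column_stack([z, out["age"], out["sex"]]))
    ols = sm.OLS(y, X).fit()
    assert res.coefficient == pytest.approx(ols.params[1], abs=1e-4)
    assert res.std_error > 0
    assert res.sign == ("+" if res.coefficient >= 0 else "-")


def test_association_requires_multiple_sites(outcome_data):
    views, out = outcome_data
    with pytest.raises(ValueError, match="site"):
        fit_lme_association(
            views.true_latents[:, 0],
            out["y"].to_numpy(),
            out["age"].to_numpy(),
            out["sex"].to_numpy(),
            np.zeros(len(out)),
        )


def test_planted_coefficient_recovered(outcome_data):
    views, out = outcome_data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fit_lme_association(
            views.true_latents[:, 0],
            out["y"].to_numpy(),
            out["age"].to_numpy(),
            out["sex"].to_numpy(),
            out["site"].to_numpy(),
        )
    assert res.coefficient == pytest.approx(0.5, abs=3 * res.std_error)
    assert res.p_value < 1e-6


def test_null_p_values_uniform():
    """Under a null outcome the LME p-values are uniform (KS test)."""
    pvals = []
    for rep in range(60):
        rng = np.random.default_rng(rep)
        n = 300
        data = dict(
            scores=rng.standard_normal(n),
            y=rng.standard_normal(n),
            age=rng.uniform(108, 132, n),
            sex=rng.integers(0, 2, n),
            site=rng.integers(0, 10, n),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_lme_association(
                data["scores"], data["y"], data["age"], data["sex"], data["site"]
            )
        pvals.append(res.p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_variance_explained_null_bound():
    """Components independent of the outcome inflate the increment by at
    most ~ (a+b)/n."""
    rng = np.random.default_rng(4)
    n = 800
    G = rng.standard_normal((n, 3))
    F = rng.standard_normal((n, 3))
    y = rng.standard_normal(n)
    age = rng.uniform(108, 132, n)
    sex = rng.integers(0, 2, n).astype(float)
    site = rng.integers(0, 10, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pct = variance_explained(G, F, y, age, sex, site)
    assert 0.0 <= pct <= 100 * 6 / n + 2.0


def test_variance_explained_overfit_guard():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="overfit"):
        variance_explained(
            rng.standard_normal((10, 6)),
            rng.standard_normal((10, 6)),
            rng.standard_normal(10),
            rng.uniform(108, 132, 10),
            rng.integers(0, 2, 10),
            rng.integers(0, 3, 10),
        )


def test_cross_method_identity_and_sign_flip(rng):
    V = rng.standard_normal((300, 4))
    table = cross_method_correlation(V, V.copy())
    diag = table.rows[table.rows.cca_index == table.rows.dccae_index]
    assert len(diag) == 4
    np.testing.assert_allclose(diag["r"], 1.0, atol=1e-12)
    flipped = cross_method_correlation(V, -V)
    diag = flipped.rows[flipped.rows.cca_index == flipped.rows.dccae_index]
    np.testing.assert_allclose(diag["r"], -1.0, atol=1e-12)
    assert (flipped.rows["r"].abs() > flipped.threshold).all()


def test_cross_method_null_retention_rare():
    """Independent variates at n = 660 almost never exceed |r| > 0.15:
    the analytic tail probability is ~1e-4 per pair."""
    total = 0
    n_pairs = 0
    for rep in range(20):
        rng = np.random.default_rng(1000 + rep)
        A = rng.standard_normal((660, 5))
        B = rng.standard_normal((660, 5))
        table = cross_method_correlation(A, B)
        total += len(table.rows)
        n_pairs += 25
    t = 0.15 * np.sqrt(658) / np.sqrt(1 - 0.15**2)
    p_tail = 2 * stats.t.sf(t, 658)
    # binomial upper band around the analytic expectation
    bound = n_pairs * p_tail + 3 * np.sqrt(n_pairs * p_tail)
    assert total <= max(2, bound)


def test_cross_method_symmetry(rng):
    A = rng.standard_normal((200, 3))
    B = 0.5 * A[:, [1, 0, 2]] + 0.5 * rng.standard_normal((200, 3))
    t1 = cross_method_correlation(A, B, threshold=0.1)
    t2 = cross_method_correlation(B, A, threshold=0.1)
    m1 = {(r.cca_index, r.dccae_index): r.r for r in t1.rows.itertuples()}
    m2 = {(r.dccae_index, r.cca_index): r.r for r in t2.rows.itertuples()}
    assert m1 == m2
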