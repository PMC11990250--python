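"""DCCAE: losses, gradients, training behavior and the linear ablation."""

import numpy as np
import pytest

from deltacca import (
    DCCAEConfig,
    ablate_linear,
    cca_loss,
    fit_cca,
    project,
    reconstruction_loss,
    train_dccae,
)
from deltacca.dccae import cca_loss_grad, cross_validate, default_config, encode_and_cca
from deltacca import SyntheticSpec, generate_coupled_views


@pytest.fixture(scope="module")
def medium_views():
    spec = SyntheticSpec(
        n_subjects=1200,
        p_x=30,
        p_y=30,
        k_latent=2,
        canonical_corrs=(0.6, 0.3),
        seed=21,
    )
    return generate_coupled_views(spec)


def small_cfg(p, **kw):
    kw.setdefault("encoder_layers", (p, 16, 6))
    kw.setdefault("k_corr", 6)
    kw.setdefault("epochs", 30)
    kw.setdefault("batch_size", 128)
    return DCCAEConfig(**kw)


def test_reconstruction_loss_values(rng):
    X = rng.standard_normal((20, 5))
    assert reconstruction_loss(X, X) == 0.0
    assert reconstruction_loss(np.array([[1.0, 0.0]]), np.zeros((1, 2))) == 1.0
    Xh = rng.standard_normal((20, 5))
    oracle = np.sum((X - Xh) ** 2) / 20
    assert reconstruction_loss(X, Xh) == pytest.approx(oracle, abs=1e-12)
    with pytest.raises(ValueError):
        reconstruction_loss(X, Xh[:, :3])


def test_cca_loss_self_and_null(rng):
    X = rng.standard_normal((100, 4))
    assert cca_loss(X, X, k=4) == pytest.approx(-4.0, abs=1e-8)
    # independent views: each singular value is O(sqrt(d/n))
    FX = rng.standard_normal((2000, 4))
    GY = rng.standard_normal((2000, 4))
    assert abs(cca_loss(FX, GY, k=4)) < 4 * 3 * np.sqrt(4 / 2000)


def test_cca_loss_batch_too_small(rng):
    with pytest.raises(ValueError, match="batch"):
        cca_loss(rng.standard_normal((4, 6)), rng.standard_normal((4, 6)), k=2)


def test_cca_loss_gradient_matches_finite_differences(rng):
    FX = rng.standard_normal((32, 4))
    GY = rng.standard_normal((32, 4))
    k, r = 3, 1e-3
    _, gFX, gGY = cca_loss_grad(FX, GY, k, r, r)
    eps = 1e-6
    for M, g, which in ((FX, gFX, "x"), (GY, gGY, "y")):
        idx = [(0, 0), (5, 2), (31, 3), (17, 1)]
        for i, j in idx:
            Mp, Mm = M.copy(), M.copy()
            Mp[i, j] += eps
            Mm[i, j] -= eps
            if which == "x":
                num = (cca_loss(Mp, GY, k, r, r) - cca_loss(Mm, GY, k, r, r)) / (2 * eps)
            else:
                num = (cca_loss(FX, Mp, k, r, r) - cca_loss(FX, Mm, k, r, r)) / (2 * eps)
            assert num == pytest.approx(g[i, j], abs=1e-4)


def test_config_validation():
    with pytest.raises(ValueError, match="lambda"):
        DCCAEConfig(encoder_layers=(10, 5), k_corr=5, lambda_recon=1.5)
    with pytest.raises(ValueError, match="k_corr"):
        DCCAEConfig(encoder_layers=(10, 5), k_corr=8)
    with pytest.raises(ValueError, match="batch_size"):
        DCCAEConfig(encoder_layers=(10, 5), k_corr=5, batch_size=4)


def test_training_determinism(medium_views):
    v = medium_views
    cfg = small_cfg(30, seed=3, epochs=10)
    m1 = train_dccae(v.X[v.train], v.Y[v.train], cfg)
    m2 = train_dccae(v.X[v.train], v.Y[v.train], cfg)
    assert abs(m1.loss_trace[-1] - m2.loss_trace[-1]) < 1e-6
    np.testing.assert_array_equal(m1.enc_x[0][0], m2.enc_x[0][0])


def test_loss_trace_decreases_smoothed(medium_views):
    v = medium_views
    cfg = small_cfg(30, seed=3, epochs=40)
    m = train_dccae(v.X[v.train], v.Y[v.train], cfg)
    smooth = np.convolve(m.loss_trace, np.ones(5) / 5, mode="valid")
    assert smooth[-1] < smooth[0]
    # nonincreasing after smoothing, up to small jitter
    assert np.all(np.diff(smooth) < 0.05 * (abs(smooth[0]) + 1))


def test_pure_autoencoder_ignores_correlation_term(medium_views):
    """lambda = 1: the correlation term contributes no gradient, so its
    ridge setting cannot affect training."""
    v = medium_views
    X, Y = v.X[v.train], v.Y[v.train]
    m1 = train_dccae(X, Y, small_cfg(30, seed=5, epochs=8, lambda_recon=1.0, r_x=0.5))
    m2 = train_dccae(X, Y, small_cfg(30, seed=5, epochs=8, lambda_recon=1.0, r_x=123.0))
    np.testing.assert_array_equal(m1.loss_trace, m2.loss_trace)
    np.testing.assert_array_equal(m1.enc_x[0][0], m2.enc_x[0][0])


def test_divergence_aborts_with_trace(medium_views):
    v = medium_views
    cfg = small_cfg(30, seed=0, epochs=5, lr=1e6)
    with pytest.raises(RuntimeError, match="diverged") as exc:
        train_dccae(v.X[v.train], v.Y[v.train], cfg)
    assert hasattr(exc.value, "loss_trace")


def test_encode_and_cca_self_consistency(medium_views):
    v = medium_views
    X, Y = v.X[v.train], v.Y[v.train]
    model = train_dccae(X, Y, small_cfg(30, seed=1, epochs=10))
    res = encode_and_cca(model, X, Y)
    np.testing.assert_allclose(
        res.correlations, model.cca.train_correlations, atol=1e-10
    )


def test_encode_and_cca_screen(medium_views):
    v = medium_views
    model = train_dccae(v.X[v.train], v.Y[v.train], small_cfg(30, seed=1, epochs=10))
    res = encode_and_cca(model, v.X, v.Y, split_labels=v.split_labels)
    assert res.screen is not None
    assert res.screen.alpha_corrected == pytest.approx(0.05 / 6)
    assert res.screen.significant.dtype == bool


def test_ablate_linear_collapses_hidden_layers():
    cfg = default_config(100)
    abl = ablate_linear(cfg)
    assert abl.encoder_layers == (100, 20)
    # ablating an already-linear config is a no-op
    assert ablate_linear(abl).encoder_layers == (100, 20)


def test_linear_ablation_matches_cca(medium_views):
    """Affine encoder + post-hoc CCA recovers plain CCA's held-out
    correlations on linear data."""
    v = medium_views
    Xtr, Ytr = v.X[v.train], v.Y[v.train]
    Xte, Yte = v.X[v.test], v.Y[v.test]
    cca_m = fit_cca(Xtr, Ytr, k=6)
    _, _, r_cca = project(cca_m, Xte, Yte)
    cfg = ablate_linear(small_cfg(30, seed=2, epochs=60))
    model = train_dccae(Xtr, Ytr, cfg)
    r_dcca = encode_and_cca(model, Xte, Yte).correlations
    assert abs(r_dcca[:5].mean() - r_cca[:5].mean()) < 0.05


def test_cross_validate_prefers_stable_config(medium_views):
    v = medium_views
    X, Y = v.X[v.train], v.Y[v.train]
    good = small_cfg(30, seed=0, epochs=6, folds=3)
    bad = small_cfg(30, seed=0, epochs=6, folds=3, lr=1e6)
    assert cross_validate(X, Y, [good, bad], folds=3) is good
    assert cross_validate(X, Y, [good], folds=3) is good
    with pytest.raises(ValueError):
        cross_validate(X, Y, [], folds=3)
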