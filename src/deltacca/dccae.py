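"""Deep CCA with autoencoder reconstruction (DCCAE).

Two per-view MLP encoders f, g are trained jointly with mirrored decoders
on the weighted objective

    (1 - lambda) * L_corr(f(X), g(Y)) + lambda * (MSE_x + MSE_y),

where L_corr is the negative sum of the top-k singular values of the
ridge-whitened cross-covariance of the encoded minibatch (the total
canonical correlation of the encodings) and MSE is the per-sample mean
squared reconstruction error. After descent, a plain CCA is fitted on the
full-training-set encodings; those post-hoc weights (u, v) define the
latent components and enforce the unit-variance / cross-orthogonality
constraints exactly.

The networks are plain numpy MLPs (tanh hidden layers, linear output)
trained by minibatch gradient descent; the correlation-loss gradient uses
the closed form obtained by differentiating the singular values of the
whitened cross-covariance. Defaults: hidden width 100, latent width 20,
batch 256, 150 epochs, learning rate 0.01, reconstruction weight 0.08.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from . import cca as cca_core
from .cca import CCAModel, ComponentScreen, _pairwise_corr

__all__ = [
    "DCCAEConfig",
    "DCCAEModel",
    "EncodeResult",
    "reconstruction_loss",
    "cca_loss",
    "train_dccae",
    "cross_validate",
    "encode_and_cca",
    "ablate_linear",
    "default_config",
]

_EIG_EPS = 1e-12


@dataclass
class DCCAEConfig:
    """Architecture and optimisation settings.

    ``encoder_layers`` lists widths input -> hidden... -> latent; the
    decoder mirrors it. ``lambda_recon`` weighs reconstruction against
    correlation (correlation weight = 1 - lambda_recon). ``r_x, r_y``
    ridge the per-batch encoding covariances inside the correlation loss;
    because inputs are rescaled to unit average feature variance before
    training, they are expressed as a fraction of that variance. The
    default 0.5 keeps low-variance nonlinear directions — the vehicle for
    correlation memorisation — from being amplified by the whitening.
    """

    encoder_layers: tuple[int, ...] = (100, 100, 20)
    encoder_layers_y: tuple[int, ...] | None = None
    k_corr: int = 20
    lambda_recon: float = 0.08
    r_x: float = 0.5
    r_y: float = 0.5
    lr: float = 0.01
    epochs: int = 150
    batch_size: int = 256
    seed: int = 0
    folds: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_recon <= 1.0:
            raise ValueError("lambda_recon must lie in [0, 1]")
        if len(self.encoder_layers) < 2:
            raise ValueError("encoder_layers needs at least input and latent widths")
        if self.k_corr > self.encoder_layers[-1]:
            raise ValueError(
                f"k_corr={self.k_corr} exceeds latent width {self.encoder_layers[-1]}"
            )
        if self.batch_size <= self.encoder_layers[-1]:
            raise ValueError(
                "batch_size must exceed the latent width for covariance "
                f"estimability (got {self.batch_size} <= {self.encoder_layers[-1]})"
            )

    @property
    def layers_y(self) -> tuple[int, ...]:
        return self.encoder_layers_y or self.encoder_layers


def default_config(p_x: int, p_y: int | None = None, **overrides) -> DCCAEConfig:
    """Study-scale default: encoder p -> 100 -> 20, 20 post-hoc components."""
    layers_y = (p_y, 100, 20) if p_y is not None and p_y != p_x else None
    return DCCAEConfig(
        encoder_layers=(p_x, 100, 20), encoder_layers_y=layers_y, **overrides
    )


# ---------------------------------------------------------------------------
# MLP primitives (tanh hidden layers, linear output)
# ---------------------------------------------------------------------------


def _init_mlp(widths: Sequence[int], rng: np.random.Generator) -> list[list[np.ndarray]]:
    params = []
    for d_in, d_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (d_in + d_out))
        params.append([rng.uniform(-limit, limit, (d_in, d_out)), np.zeros(d_out)])
    return params


def _forward(params, X: np.ndarray) -> list[np.ndarray]:
    """Returns activations [input, hidden..., output]."""
    acts = [X]
    last = len(params) - 1
    for i, (W, b) in enumerate(params):
        z = acts[-1] @ W + b
        acts.append(z if i == last else np.tanh(z))
    return acts


def _backward(params, acts, grad_out: np.ndarray):
    """Gradients wrt parameters and wrt the network input."""
    grads = [None] * len(params)
    g = grad_out
    last = len(params) - 1
    for i in range(last, -1, -1):
        if i != last:
            g = g * (1.0 - acts[i + 1] ** 2)  # tanh'
        W, _ = params[i]
        grads[i] = [acts[i].T @ g, g.sum(axis=0)]
        g = g @ W.T
    return grads, g


def _sgd_step(params, grads, lr: float) -> None:
    for (W, b), (gW, gb) in zip(params, grads):
        W -= lr * gW
        b -= lr * gb


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def reconstruction_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Mean over samples of the squared error row norm."""
    X = np.asarray(X, float)
    X_hat = np.asarray(X_hat, float)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    return float(np.mean(np.sum((X - X_hat) ** 2, axis=1)))


def _inv_sqrt_psd(C: np.ndarray) -> np.ndarray:
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    w = np.clip(w, _EIG_EPS * max(w[-1], 1.0), None)
    return (V / np.sqrt(w)) @ V.T


def _cca_loss_core(FX, GY, k, r_x, r_y, want_grad):
    FX = np.asarray(FX, float)
    GY = np.asarray(GY, float)
    n, d1 = FX.shape
    d2 = GY.shape[1]
    if GY.shape[0] != n:
        raise ValueError("FX and GY must have the same number of rows")
    if n <= max(d1, d2):
        raise ValueError(
            f"batch size {n} must exceed the encoding width {max(d1, d2)}; "
            "use a larger batch"
        )
    if k > min(d1, d2):
        raise ValueError(f"k={k} exceeds encoding width {min(d1, d2)}")

    H1 = (FX - FX.mean(axis=0)).T  # (d1, n)
    H2 = (GY - GY.mean(axis=0)).T
    s = 1.0 / (n - 1)
    C11 = s * H1 @ H1.T + r_x * np.eye(d1)
    C22 = s * H2 @ H2.T + r_y * np.eye(d2)
    C12 = s * H1 @ H2.T
    if not (np.isfinite(C11).all() and np.isfinite(C22).all() and np.isfinite(C12).all()):
        raise FloatingPointError("non-finite covariance inside the correlation loss")

    K1 = _inv_sqrt_psd(C11)
    K2 = _inv_sqrt_psd(C22)
    U, S, Vt = np.linalg.svd(K1 @ C12 @ K2)
    loss = -float(S[:k].sum())
    if not want_grad:
        return loss, None, None

    Uk = U[:, :k]
    Vk = Vt[:k].T
    Dk = S[:k]
    D12 = K1 @ Uk @ Vk.T @ K2
    D11 = -0.5 * K1 @ (Uk * Dk) @ Uk.T @ K1
    D22 = -0.5 * K2 @ (Vk * Dk) @ Vk.T @ K2
    dcorr_H1 = s * (2.0 * D11 @ H1 + D12 @ H2)  # (d1, n)
    dcorr_H2 = s * (2.0 * D22 @ H2 + D12.T @ H1)
    # chain through batch centering, then negate (loss = -corr)
    gFX = -(dcorr_H1.T - dcorr_H1.T.mean(axis=0))
    gGY = -(dcorr_H2.T - dcorr_H2.T.mean(axis=0))
    return loss, gFX, gGY


def cca_loss(FX, GY, k: int, r_x: float = 0.0, r_y: float = 0.0) -> float:
    """Negative total canonical correlation of two encoded batches:
    -sum of the top-k singular values of the ridge-whitened
    cross-covariance (batch-centered, 1/(n-1) scaling)."""
    loss, _, _ = _cca_loss_core(FX, GY, k, r_x, r_y, want_grad=False)
    return loss


def cca_loss_grad(FX, GY, k: int, r_x: float = 0.0, r_y: float = 0.0):
    """Loss plus analytic gradients wrt FX and GY."""
    return _cca_loss_core(FX, GY, k, r_x, r_y, want_grad=True)


# ---------------------------------------------------------------------------
# Model and training
# ---------------------------------------------------------------------------


@dataclass
class DCCAEModel:
    """Trained encoder/decoder parameters with post-hoc CCA weights over
    the training-set encodings.

    ``x_scale``/``y_scale`` are the global per-view input scales (RMS
    feature standard deviation of the training data) applied before the
    encoders; they keep tanh units out of saturation while preserving the
    relative variance structure of the input features.
    """

    enc_x: list
    enc_y: list
    dec_x: list
    dec_y: list
    cca: CCAModel
    config: DCCAEConfig
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    x_scale: float = 1.0
    y_scale: float = 1.0

    def encode_x(self, X: np.ndarray) -> np.ndarray:
        return _forward(self.enc_x, np.asarray(X, float) / self.x_scale)[-1]

    def encode_y(self, Y: np.ndarray) -> np.ndarray:
        return _forward(self.enc_y, np.asarray(Y, float) / self.y_scale)[-1]

    def latents_x(self, X: np.ndarray) -> np.ndarray:
        """Canonical variates: encode then apply the post-hoc CCA weights."""
        return (self.encode_x(X) - self.cca.x_mean) @ self.cca.u

    def latents_y(self, Y: np.ndarray) -> np.ndarray:
        return (self.encode_y(Y) - self.cca.y_mean) @ self.cca.v

    def reconstruct_x(self, X: np.ndarray) -> np.ndarray:
        return _forward(self.dec_x, self.encode_x(X))[-1]

    def reconstruct_y(self, Y: np.ndarray) -> np.ndarray:
        return _forward(self.dec_y, self.encode_y(Y))[-1]


class EncodeResult(NamedTuple):
    variates_x: np.ndarray
    variates_y: np.ndarray
    correlations: np.ndarray
    screen: ComponentScreen | None


def train_dccae(X: np.ndarray, Y: np.ndarray, config: DCCAEConfig) -> DCCAEModel:
    """Minibatch gradient descent on the weighted DCCAE objective,
    followed by a plain CCA fit on the full-training encodings.

    Deterministic given ``config.seed``. Raises ``RuntimeError`` (with the
    loss trace attached as ``.loss_trace``) if the loss goes non-finite.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be row-aligned")
    n = X.shape[0]
    lx, ly = config.encoder_layers, config.layers_y
    if X.shape[1] != lx[0] or Y.shape[1] != ly[0]:
        raise ValueError(
            f"encoder input widths {(lx[0], ly[0])} do not match data "
            f"widths {(X.shape[1], Y.shape[1])}"
        )
    d_latent = lx[-1]
    if n <= d_latent:
        raise ValueError("need more samples than latent dimensions")

    # global per-view rescale to unit average feature variance
    x_scale = float(np.sqrt(X.var(axis=0).mean())) or 1.0
    y_scale = float(np.sqrt(Y.var(axis=0).mean())) or 1.0
    X = X / x_scale
    Y = Y / y_scale

    rng = np.random.default_rng(config.seed)
    enc_x = _init_mlp(lx, rng)
    dec_x = _init_mlp(lx[::-1], rng)
    enc_y = _init_mlp(ly, rng)
    dec_y = _init_mlp(ly[::-1], rng)

    lam = config.lambda_recon
    w_corr = 1.0 - lam
    batch = min(config.batch_size, n)
    trace = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch):
            idx = perm[start : start + batch]
            # covariance inside the correlation loss needs nb > latent width
            if len(idx) <= d_latent:
                continue
            Xb, Yb = X[idx], Y[idx]
            with np.errstate(over="ignore", invalid="ignore"):
                acts_fx = _forward(enc_x, Xb)
                acts_gy = _forward(enc_y, Yb)
            FX, GY = acts_fx[-1], acts_gy[-1]

            loss = 0.0
            gFX = np.zeros_like(FX)
            gGY = np.zeros_like(GY)

            if w_corr > 0.0:
                try:
                    c_loss, gc_fx, gc_gy = cca_loss_grad(
                        FX, GY, config.k_corr, config.r_x, config.r_y
                    )
                except FloatingPointError:
                    err = RuntimeError(
                        f"training diverged at epoch {epoch + 1}: non-finite "
                        "encodings in the correlation loss"
                    )
                    err.loss_trace = np.asarray(trace + [np.nan])
                    raise err from None
                loss += w_corr * c_loss
                gFX += w_corr * gc_fx
                gGY += w_corr * gc_gy

            with np.errstate(over="ignore", invalid="ignore"):
                if lam > 0.0:
                    acts_px = _forward(dec_x, FX)
                    acts_qy = _forward(dec_y, GY)
                    Xh, Yh = acts_px[-1], acts_qy[-1]
                    nb = len(idx)
                    loss += lam * (
                        reconstruction_loss(Xb, Xh) + reconstruction_loss(Yb, Yh)
                    )
                    gdec_x, g_in_x = _backward(
                        dec_x, acts_px, lam * 2.0 * (Xh - Xb) / nb
                    )
                    gdec_y, g_in_y = _backward(
                        dec_y, acts_qy, lam * 2.0 * (Yh - Yb) / nb
                    )
                    gFX += g_in_x
                    gGY += g_in_y
                    _sgd_step(dec_x, gdec_x, config.lr)
                    _sgd_step(dec_y, gdec_y, config.lr)

                genc_x, _ = _backward(enc_x, acts_fx, gFX)
                genc_y, _ = _backward(enc_y, acts_gy, gGY)
                _sgd_step(enc_x, genc_x, config.lr)
                _sgd_step(enc_y, genc_y, config.lr)
            epoch_losses.append(loss)

        with np.errstate(over="ignore", invalid="ignore"):
            epoch_loss = float(np.mean(epoch_losses)) if epoch_losses else np.nan
        trace.append(epoch_loss)
        if not np.isfinite(epoch_loss):
            err = RuntimeError(
                f"training diverged at epoch {epoch + 1}: non-finite loss"
            )
            err.loss_trace = np.asarray(trace)
            raise err

    EX = _forward(enc_x, X)[-1]
    EY = _forward(enc_y, Y)[-1]
    post_cca = cca_core.fit_cca(EX, EY, k=config.k_corr)
    return DCCAEModel(
        enc_x=enc_x,
        enc_y=enc_y,
        dec_x=dec_x,
        dec_y=dec_y,
        cca=post_cca,
        config=config,
        loss_trace=np.asarray(trace),
        x_scale=x_scale,
        y_scale=y_scale,
    )


def encode_and_cca(
    model: DCCAEModel,
    X: np.ndarray,
    Y: np.ndarray,
    split_labels: np.ndarray | None = None,
    alpha: float = 0.05,
    m: int | None = None,
) -> EncodeResult:
    """Encode both views, apply the stored post-hoc CCA weights, and
    report per-component Pearson correlations. When ``split_labels``
    ('train'/'test' per row) are given, also return the dual-split
    Bonferroni screen."""
    vx = model.latents_x(X)
    vy = model.latents_y(Y)
    r = _pairwise_corr(vx, vy)
    screen = None
    if split_labels is not None:
        split_labels = np.asarray(split_labels)
        tr = split_labels == "train"
        te = split_labels == "test"
        screen = cca_core.select_significant(
            _pairwise_corr(vx[tr], vy[tr]),
            _pairwise_corr(vx[te], vy[te]),
            int(tr.sum()),
            int(te.sum()),
            alpha=alpha,
            m=m,
        )
    return EncodeResult(vx, vy, r, screen)


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    grid: Sequence[DCCAEConfig],
    folds: int | None = None,
    n_corr: int = 10,
) -> DCCAEConfig:
    """K-fold cross-validation scoring each config by the mean over folds
    of the sum of the first ``n_corr`` validation-fold canonical
    correlations; ties keep the earlier grid entry, diverging configs
    score -inf."""
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    if folds is None:
        folds = grid[0].folds
    if folds < 2:
        raise ValueError("need at least 2 folds")

    from sklearn.model_selection import KFold

    kf = KFold(n_splits=folds, shuffle=True, random_state=grid[0].seed % (2**31))
    splits = list(kf.split(X))
    best_cfg, best_score = None, -np.inf
    for cfg in grid:
        fold_scores = []
        for tr_idx, val_idx in splits:
            try:
                model = train_dccae(X[tr_idx], Y[tr_idx], cfg)
            except (RuntimeError, FloatingPointError):
                fold_scores = [-np.inf]
                break
            res = encode_and_cca(model, X[val_idx], Y[val_idx])
            fold_scores.append(float(res.correlations[:n_corr].sum()))
        score = float(np.mean(fold_scores))
        if score > best_score:
            best_cfg, best_score = cfg, score
    return best_cfg


def ablate_linear(config: DCCAEConfig) -> DCCAEConfig:
    """Drop all hidden layers: the encoder becomes a single affine map
    input -> latent (no nonlinearity), the decoder its mirror."""
    layers_y = config.encoder_layers_y
    return replace(
        config,
        encoder_layers=(config.encoder_layers[0], config.encoder_layers[-1]),
        encoder_layers_y=(layers_y[0], layers_y[-1]) if layers_y else None,
    )
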