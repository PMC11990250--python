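"""Synthetic paired multimodal change data with planted canonical structure.

Real longitudinal GM-density / FA change data of the kind this pipeline
targets is controlled-access, so every downstream stage is exercised on
generated data instead: two feature matrices sharing low-rank latent
structure with specified population canonical correlations, outcome change
scores linearly driven by the latents with site random intercepts, and
small voxel-map stand-ins feeding the masking/PCA path.

Latent coupling is constructed so the population canonical correlation of
latent pair j is exactly ``canonical_corrs[j]``: the X-side factor is the
shared standard-normal factor z_j itself, the Y-side factor is
``rho_j z_j + sqrt(1 - rho_j^2) w_j`` with w_j independent noise. Features
are orthonormal loading columns (scaled by ``loading_scale``) times the
factors plus independent Gaussian noise, optionally passed through an
elementwise tanh (signal only) for mildly nonlinear mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "PairedViews",
    "VoxelMapSet",
    "default_outcome_effects",
    "generate_coupled_views",
    "generate_outcomes",
    "generate_voxel_dataset",
    "write_views",
    "write_outcomes",
    "write_voxel_maps",
    "read_voxel_maps",
]

COGNITION_OUTCOMES = ("fluid", "crystallized", "total_composite")
CBCL_SYNDROMES = (
    "anxious_depressed",
    "withdrawn_depressed",
    "somatic_complaints",
    "social_problems",
    "thought_problems",
    "attention_problems",
    "rule_breaking",
    "aggressive_behavior",
)


def default_outcome_effects(k_latent: int) -> dict[str, np.ndarray]:
    """Eleven outcome-change scores (three cognition, eight behavior).

    Cognition loads modestly on the leading latents; behavior syndromes
    load weakly and negatively on the first latent, emulating the typical
    asymmetry between cognitive and behavioral effect sizes.
    """
    effects: dict[str, np.ndarray] = {}
    for i, name in enumerate(COGNITION_OUTCOMES):
        e = np.zeros(k_latent)
        e[min(i, k_latent - 1)] = 0.3
        effects[name] = e
    for name in CBCL_SYNDROMES:
        e = np.zeros(k_latent)
        e[0] = -0.1
        effects[name] = e
    return effects


@dataclass
class SyntheticSpec:
    """Generator configuration; defaults mirror the study scale
    (3302 subjects, 100 PCA features per modality).

    ``canonical_corrs`` are target population canonical correlations, one
    per shared latent factor, nonincreasing in [0, 1]. ``loading_scale``
    is the column norm of each orthonormal loading direction; with feature
    noise sd ``noise_sd`` the achievable factor recovery correlation per
    view is ``loading_scale / sqrt(loading_scale^2 + noise_sd^2)``.
    """

    n_subjects: int = 3302
    p_x: int = 100
    p_y: int = 100
    k_latent: int = 3
    canonical_corrs: tuple[float, ...] = (0.6, 0.4, 0.2)
    mixing: str = "linear"
    noise_sd: float = 1.0
    n_sites: int = 20
    site_sd: float = 0.5
    outcome_effects: dict[str, np.ndarray] | None = None
    seed: int = 0
    train_fraction: float = 0.8
    loading_scale: float = 10.0
    age_effect: float = 0.01  # outcome units per month of age
    sex_effect: float = 0.2
    outcome_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        rho = np.asarray(self.canonical_corrs, dtype=float)
        if len(rho) != self.k_latent:
            raise ValueError(
                f"canonical_corrs has length {len(rho)}, expected k_latent="
                f"{self.k_latent}"
            )
        if np.any(rho < 0) or np.any(rho > 1):
            raise ValueError("canonical correlations must lie in [0, 1]")
        if np.any(np.diff(rho) > 1e-12):
            raise ValueError("canonical_corrs must be nonincreasing")
        if self.k_latent > min(self.p_x, self.p_y):
            raise ValueError(
                f"k_latent={self.k_latent} exceeds min(p_x, p_y)="
                f"{min(self.p_x, self.p_y)}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.site_sd < 0:
            raise ValueError("site_sd must be nonnegative")
        if self.mixing not in ("linear", "tanh"):
            raise ValueError(f"unknown mixing {self.mixing!r}")

    def effects(self) -> dict[str, np.ndarray]:
        if self.outcome_effects is None:
            return default_outcome_effects(self.k_latent)
        return {k: np.asarray(v, dtype=float) for k, v in self.outcome_effects.items()}


@dataclass
class PairedViews:
    """Two row-aligned subject x feature matrices with split labels and,
    for recovery tests, the true shared latents."""

    X: np.ndarray
    Y: np.ndarray
    split_labels: np.ndarray  # 'train' / 'test' per subject
    true_latents: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subject_ids:
            self.subject_ids = [f"S{i:05d}" for i in range(self.X.shape[0])]

    @property
    def train(self) -> np.ndarray:
        return self.split_labels == "train"

    @property
    def test(self) -> np.ndarray:
        return self.split_labels == "test"


@dataclass
class VoxelMapSet:
    """Per-subject baseline and follow-up 3D maps (4D arrays), plus the
    planted change matrix (subject x in-mask voxel) for verification."""

    baseline: np.ndarray
    followup: np.ndarray
    modality: str
    planted_delta: np.ndarray | None = None
    planted_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.baseline.shape != self.followup.shape:
            raise ValueError("baseline and followup shapes differ")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(8)[stream])


def _orthonormal_loadings(rng: np.random.Generator, p: int, k: int) -> np.ndarray:
    Q, _ = np.linalg.qr(rng.standard_normal((p, k)))
    return Q


def generate_coupled_views(spec: SyntheticSpec) -> PairedViews:
    """Draw paired feature matrices with planted canonical correlations.

    Deterministic given ``spec.seed``; the 80/20-style split assignment is
    drawn from the same seed stream.
    """
    rng = _rng(spec.seed, 0)
    n, k = spec.n_subjects, spec.k_latent
    rho = np.asarray(spec.canonical_corrs, dtype=float)

    Z = rng.standard_normal((n, k))
    W = rng.standard_normal((n, k))
    Fx = Z
    Fy = rho * Z + np.sqrt(1.0 - rho**2) * W

    Ax = spec.loading_scale * _orthonormal_loadings(rng, spec.p_x, k)
    Ay = spec.loading_scale * _orthonormal_loadings(rng, spec.p_y, k)

    Sx = Fx @ Ax.T
    Sy = Fy @ Ay.T
    if spec.mixing == "tanh":
        Sx = np.tanh(Sx)
        Sy = np.tanh(Sy)

    X = Sx + spec.noise_sd * rng.standard_normal((n, spec.p_x))
    Y = Sy + spec.noise_sd * rng.standard_normal((n, spec.p_y))

    n_train = int(round(spec.train_fraction * n))
    perm = rng.permutation(n)
    labels = np.full(n, "test", dtype=object)
    labels[perm[:n_train]] = "train"

    return PairedViews(X=X, Y=Y, split_labels=np.asarray(labels), true_latents=Z)


def generate_outcomes(views: PairedViews, spec: SyntheticSpec) -> pd.DataFrame:
    """Outcome-change table driven linearly by the true latents.

    Each outcome is ``loadings . z + age_effect (age - 120) + sex_effect sex
    + site intercept + residual``; age is uniform on [108, 132] months, sex
    Bernoulli(0.5), sites assigned uniformly at random with intercepts
    N(0, site_sd^2). Returns columns subject_id, site, age, sex, then one
    column per outcome.
    """
    effects = spec.effects()
    if not effects:
        raise ValueError("outcome_effects must be nonempty")
    if spec.n_sites < 1:
        raise ValueError("n_sites must be at least 1")
    k = views.true_latents.shape[1]
    for name, e in effects.items():
        if len(e) != k:
            raise ValueError(
                f"loading vector for {name!r} has length {len(e)}, expected {k}"
            )

    rng = _rng(spec.seed, 1)
    n = views.true_latents.shape[0]
    site = rng.integers(0, spec.n_sites, size=n)
    site_intercepts = spec.site_sd * rng.standard_normal(spec.n_sites)
    age = rng.uniform(108.0, 132.0, size=n)
    sex = rng.integers(0, 2, size=n)

    table = {
        "subject_id": views.subject_ids,
        "site": site,
        "age": age,
        "sex": sex,
    }
    base = (
        spec.age_effect * (age - 120.0)
        + spec.sex_effect * sex
        + site_intercepts[site]
    )
    for name, e in effects.items():
        noise = spec.outcome_noise_sd * rng.standard_normal(n)
        table[name] = views.true_latents @ e + base + noise
    return pd.DataFrame(table)


def generate_voxel_dataset(
    spec: SyntheticSpec,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    modality: str = "GM",
    mask_threshold: float = 0.2,
    change_scale: float = 0.25,
) -> VoxelMapSet:
    """Small voxel-map stand-in whose masked change matrix is a planted
    coupled view.

    A smooth radial template defines a central in-mask blob (template mean
    value above ``mask_threshold``); subject baselines add small positive
    jitter. The follow-up map is baseline plus a subject-specific change
    whose vectorized in-mask form is a row of a coupled-view matrix
    (X for GM-like, Y for FA-like), rescaled to max |change| =
    ``change_scale`` so all map values stay nonnegative. ``change_scale=0``
    plants no change.
    """
    if np.prod(grid_shape) > 20**3:
        raise ValueError("voxel stand-ins are limited to small grids (<= 20^3)")
    if not 0.0 <= change_scale < 0.45:
        raise ValueError("change_scale must lie in [0, 0.45) to keep maps nonnegative")
    rng = _rng(spec.seed, 2 if modality.upper() == "GM" else 3)

    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij"), axis=-1
    )
    center = (np.asarray(grid_shape) - 1) / 2.0
    d2 = np.sum((coords - center) ** 2, axis=-1)
    radius2 = (min(grid_shape) / 3.0) ** 2
    # central blob well above the mask threshold, background well below,
    # so subject jitter cannot flip voxels across the threshold
    template = np.where(d2 <= radius2, 0.5, 0.05)
    mask = template > mask_threshold
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("template produced an empty mask; enlarge the grid")

    n = spec.n_subjects
    baseline = np.clip(
        template[None] + 0.01 * rng.standard_normal((n, *grid_shape)), 0.0, None
    )

    vspec = replace(
        spec, p_x=n_mask, p_y=n_mask, outcome_effects=spec.outcome_effects
    )
    views = generate_coupled_views(vspec)
    raw = views.X if modality.upper() == "GM" else views.Y
    if change_scale > 0:
        delta = raw * (change_scale / np.max(np.abs(raw)))
    else:
        delta = np.zeros_like(raw)

    # in-mask baseline sits near 0.5 and |delta| <= change_scale < 0.5, so
    # follow-up stays nonnegative without clipping (which would corrupt
    # the planted change)
    followup = baseline.copy()
    flat = followup.reshape(n, -1)
    flat[:, mask.ravel()] = flat[:, mask.ravel()] + delta
    followup = flat.reshape(n, *grid_shape)

    return VoxelMapSet(
        baseline=baseline,
        followup=followup,
        modality=modality,
        planted_delta=delta,
        planted_mask=mask,
    )


# ---------------------------------------------------------------------------
# Plain-text / NIfTI export
# ---------------------------------------------------------------------------


def write_views(views: PairedViews, out_dir: str | Path, prefix: str = "view") -> None:
    """Write both views as TSV (subject_id column, feature-name header)
    plus split labels and true latents."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tag, M in (("x", views.X), ("y", views.Y)):
        df = pd.DataFrame(
            M, columns=[f"{tag}{j + 1}" for j in range(M.shape[1])]
        )
        df.insert(0, "subject_id", views.subject_ids)
        df.to_csv(out / f"{prefix}_{tag}.tsv", sep="\t", index=False)
    meta = pd.DataFrame(
        {"subject_id": views.subject_ids, "split": views.split_labels}
    )
    for j in range(views.true_latents.shape[1]):
        meta[f"z{j + 1}"] = views.true_latents[:, j]
    meta.to_csv(out / f"{prefix}_latents.tsv", sep="\t", index=False)


def write_outcomes(outcomes: pd.DataFrame, path: str | Path) -> None:
    outcomes.to_csv(path, index=False)


def write_voxel_maps(vms: VoxelMapSet, out_dir: str | Path) -> tuple[Path, Path]:
    """One 4D NIfTI per timepoint (x, y, z, subject), identity affine."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for tag, arr in (("baseline", vms.baseline), ("followup", vms.followup)):
        img = nib.Nifti1Image(
            np.moveaxis(arr, 0, -1).astype(np.float64), affine=np.eye(4)
        )
        path = out / f"{vms.modality.lower()}_{tag}.nii"
        nib.save(img, path)
        paths.append(path)
    return tuple(paths)


def read_voxel_maps(
    baseline_path: str | Path, followup_path: str | Path, modality: str
) -> VoxelMapSet:
    base = np.moveaxis(np.asarray(nib.load(baseline_path).dataobj, dtype=np.float64), -1, 0)
    follow = np.moveaxis(np.asarray(nib.load(followup_path).dataobj, dtype=np.float64), -1, 0)
    return VoxelMapSet(baseline=base, followup=follow, modality=modality)
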