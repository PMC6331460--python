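"""Synthetic cohorts with a planted rank-1 brain–behavior association.

The generator emulates the statistical structure of a skeletonised
white-matter study: N elderly subjects, P skeleton voxels, one behavioral
score, and a single latent factor linking a signed subset of "salient" voxels
to the score.

Model
-----
Let ``z ~ N(0, 1)`` be the per-subject latent factor and ``a`` a unit-norm
voxel loading vector supported on ``n_salient`` voxels (each entry
``sign / sqrt(n_salient)``, a configurable fraction with negative sign).  Then

    X = s * z a^T + E,          E_ij ~ N(0, noise_sd^2)
    y = alpha * z + beta_age * age + beta_gender * gender + eps,  eps ~ N(0,1)

calibrated so the *population* canonical correlation between the voxel
block's best direction (``X a``) and ``y`` equals ``rho``.  Because
``corr(Xa, y) = corr(Xa, z) * corr(z, y)``, ``rho`` has to be split between
the two legs.  The split is deliberately asymmetric: the voxel-side alignment
``c_x = corr(Xa, z)`` is held high (``c_x = max(signal_alignment,
sqrt(rho))``, default 0.95) and the score side carries ``r_y = rho / c_x``:

    s     = noise_sd * c_x / sqrt(1 - c_x**2)   ->  corr(Xa, z) = c_x
    alpha = r_y / sqrt(1 - r_y**2)              ->  corr(z,  y) = r_y
    corr(Xa, y) = c_x * r_y = rho               (exactly, in population)

The high voxel-side alignment keeps the planted rank-1 spike above the
spiked-covariance detection threshold (``s^2/noise_sd^2 > sqrt(P/N)``) with
enough margin that it stays detectable even inside bootstrap folds, where
resampling roughly halves the effective sample size: at the default 0.98 the
spike strength ``c_x^2/(1-c_x^2) ~ 24`` is about four times the fold-level
threshold for the largest emulated aspect ratios.  A symmetric ``sqrt(rho)``
split would plant a direction the leading SVD subspace provably cannot find
when ``P >> N`` — not the regime that real skeleton data (strongly low-rank,
with full-data R of 0.4-0.9) occupies.  ``n_salient`` does not enter the
calibration: the loading vector is unit-norm however many voxels carry it.

``rho = 0`` zeroes the score side only (``alpha = 0``): the salient loading
structure is still present in X but the score is independent of it — the
exact null regime.  Ages are uniform on [65, 80] years and gender is
Bernoulli(0.5); by default the confound coefficients are zero, and nonzero
values inject age/gender effects into the score only, exercising the
covariate-adjustment path.

The skeleton mask is a random thin structure (one-voxel-thick axis-aligned
line segments) occupying ``round(skeleton_fraction * grid volume)`` voxels —
the analysis is geometry-agnostic, only mask bookkeeping matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import BehaviorTable, SkeletonDataset, mask_voxel_index
from .errors import ConfigError

#: Cohort sizes in the emulated study ranged over roughly 57-163 subjects;
#: the default sits at the upper (control-group) end.
DEFAULT_N_SUBJECTS = 160


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort (fully reproducible from ``seed``)."""

    n_subjects: int = DEFAULT_N_SUBJECTS
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    skeleton_fraction: float = 0.15
    n_salient: int = 50
    frac_negative: float = 0.3
    rho: float = 0.5
    signal_alignment: float = 0.98
    noise_sd: float = 1.0
    confound_beta_age: float = 0.0
    confound_beta_gender: float = 0.0
    score_name: str = "score"
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if self.n_subjects < 3:
            raise ConfigError("n_subjects must be >= 3")
        if len(self.grid_shape) != 3 or any(g < 1 for g in self.grid_shape):
            raise ConfigError("grid_shape must be three positive integers")
        if not (0.0 < self.skeleton_fraction < 1.0):
            raise ConfigError("skeleton_fraction must be in (0, 1)")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError("rho must be in [0, 1)")
        if not (0.0 < self.signal_alignment < 1.0):
            raise ConfigError("signal_alignment must be in (0, 1)")
        if not (0.0 <= self.frac_negative <= 1.0):
            raise ConfigError("frac_negative must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.n_salient < 0:
            raise ConfigError("n_salient must be >= 0")
        if self.n_salient > self.n_voxels:
            raise ConfigError(
                f"n_salient={self.n_salient} exceeds the {self.n_voxels} skeleton voxels"
            )

    @property
    def n_voxels(self) -> int:
        """Exact skeleton voxel count implied by grid and fraction."""
        return int(round(self.skeleton_fraction * int(np.prod(self.grid_shape))))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class GroundTruth:
    """What was planted: salient voxel coordinates with signs, and the latent."""

    salient_coords: np.ndarray   # (n_salient, 3)
    salient_signs: np.ndarray    # (n_salient,) in {-1, +1}
    latent_scores: np.ndarray    # (N,) the latent factor z
    true_rho: float
    loading: np.ndarray = field(repr=False, default=None)  # (P,) unit-norm a

    def salient_flags(self, voxel_index: np.ndarray) -> np.ndarray:
        """Per-column planted sign (+1/-1 salient, 0 elsewhere) for a dataset."""
        lookup = {tuple(c): s for c, s in zip(self.salient_coords, self.salient_signs)}
        return np.array([lookup.get(tuple(c), 0) for c in voxel_index], dtype=int)


def _skeleton_mask(
    grid_shape: tuple[int, int, int], n_target: int, rng: np.random.Generator
) -> np.ndarray:
    """Random thin mask: axis-aligned one-voxel-thick segments, exactly n_target voxels."""
    if n_target < 1:
        raise ConfigError("skeleton must contain at least one voxel")
    mask = np.zeros(grid_shape, dtype=bool)
    grid = np.asarray(grid_shape)
    while mask.sum() < n_target:
        axis = int(rng.integers(3))
        start = rng.integers(0, grid)
        max_len = grid[axis] - start[axis]
        length = int(rng.integers(1, max_len + 1))
        idx = [slice(int(c), int(c) + 1) for c in start]
        idx[axis] = slice(int(start[axis]), int(start[axis]) + length)
        mask[tuple(idx)] = True
    excess = int(mask.sum()) - n_target
    if excess:
        coords = np.argwhere(mask)
        drop = rng.choice(len(coords), size=excess, replace=False)
        mask[tuple(coords[drop].T)] = False
    return mask


def generate_cohort(
    config: SimulationConfig,
) -> tuple[SkeletonDataset, BehaviorTable, GroundTruth]:
    """Draw one cohort from the planted rank-1 model (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    mask = _skeleton_mask(config.grid_shape, config.n_voxels, rng)
    coords = mask_voxel_index(mask)
    p = len(coords)

    # signed unit-norm loading on a random salient subset
    loading = np.zeros(p)
    if config.n_salient > 0:
        salient_idx = np.sort(rng.choice(p, size=config.n_salient, replace=False))
        n_neg = int(round(config.frac_negative * config.n_salient))
        signs = np.ones(config.n_salient)
        signs[:n_neg] = -1.0
        rng.shuffle(signs)
        loading[salient_idx] = signs / np.sqrt(config.n_salient)
    else:
        salient_idx = np.array([], dtype=int)
        signs = np.array([])

    z = rng.standard_normal(n)
    c_x = max(config.signal_alignment, np.sqrt(config.rho))
    s = config.noise_sd * c_x / np.sqrt(1.0 - c_x**2)
    x = s * np.outer(z, loading) + rng.normal(0.0, config.noise_sd, size=(n, p))

    age = rng.uniform(65.0, 80.0, size=n)
    gender = rng.integers(0, 2, size=n).astype(float)
    r_y = config.rho / c_x
    alpha = r_y / np.sqrt(1.0 - r_y**2)
    y = (
        alpha * z
        + config.confound_beta_age * age
        + config.confound_beta_gender * gender
        + rng.standard_normal(n)
    )

    ids = [f"sub-{i:04d}" for i in range(n)]
    dataset = SkeletonDataset(
        matrix=x, mask=mask, voxel_index=coords, subject_ids=ids, affine=np.eye(4)
    )
    table = BehaviorTable(
        scores={config.score_name: y},
        covariates=pd.DataFrame({"age": age, "gender": gender}),
        subject_ids=ids,
    )
    truth = GroundTruth(
        salient_coords=coords[salient_idx],
        salient_signs=signs.astype(int),
        latent_scores=z,
        true_rho=config.rho,
        loading=loading,
    )
    return dataset, table, truth


def make_null_cohort(config: SimulationConfig) -> tuple[SkeletonDataset, BehaviorTable]:
    """Cohort with no imaging–behavior link (``rho = 0``): the null regime."""
    null_cfg = SimulationConfig(**{**asdict(config), "rho": 0.0})
    dataset, table, _ = generate_cohort(null_cfg)
    return dataset, table


def write_cohort(
    dataset: SkeletonDataset,
    table: BehaviorTable,
    out_dir: str | Path,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write a cohort in the NIfTI + TSV layout the loaders consume."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = dataset.affine if dataset.affine is not None else np.eye(4)

    vol4d = np.zeros((*dataset.mask.shape, dataset.n_subjects), dtype=np.float64)
    vol4d[dataset.mask, :] = dataset.matrix.T
    paths = {
        "images": out_dir / "features.nii.gz",
        "mask": out_dir / "mask.nii.gz",
        "table": out_dir / "subjects.tsv",
    }
    nib.save(nib.Nifti1Image(vol4d, affine), str(paths["images"]))
    nib.save(
        nib.Nifti1Image(dataset.mask.astype(np.uint8), affine), str(paths["mask"])
    )
    df = pd.DataFrame({"subject_id": table.subject_ids})
    for name, vec in table.scores.items():
        df[name] = vec
    for col in table.covariates.columns:
        df[col] = table.covariates[col].to_numpy()
    df.to_csv(paths["table"], sep="\t", index=False)

    if truth is not None:
        paths["ground_truth"] = out_dir / "ground_truth.tsv"
        gt = pd.DataFrame(
            {
                "x": truth.salient_coords[:, 0],
                "y": truth.salient_coords[:, 1],
                "z": truth.salient_coords[:, 2],
                "sign": truth.salient_signs,
            }
        )
        gt.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
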