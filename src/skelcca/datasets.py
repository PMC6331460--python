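"""Domain containers and NIfTI / table I/O.

The central container is :class:`SkeletonDataset`: an ``N x P`` matrix of
per-subject voxel values restricted to a 3-D skeleton mask, together with the
mask itself and the coordinate of every matrix column.  Voxel columns are
ordered by a C-order raster scan of the mask (``numpy.argwhere`` order: the
last axis varies fastest), so column order is a pure function of the mask and
two loads of the same files are bit-identical.

Behavioral data live in :class:`BehaviorTable`: one or more named score
vectors plus a covariate matrix (typically age in years and gender coded 0/1),
row-aligned to the imaging subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    DataError,
    GeometryError,
    PairingError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Default mapping from gender labels to the 0/1 coding used as a covariate.
DEFAULT_GENDER_MAP: Mapping[str, float] = {
    "f": 0.0, "female": 0.0, "w": 0.0, "0": 0.0,
    "m": 1.0, "male": 1.0, "1": 1.0,
}


@dataclass
class SkeletonDataset:
    """Subjects x in-mask-voxels feature matrix with its mask geometry.

    Parameters
    ----------
    matrix : (N, P) float array
        One row per subject, one column per mask voxel.  Fractional-anisotropy
        values lie in [0, 1] for real data; synthetic features are
        unconstrained.
    mask : 3-D bool array
        Skeleton mask; ``P == mask.sum()``.
    voxel_index : (P, 3) int array
        Coordinate of each column, in C-order raster order of the mask.
    subject_ids : sequence of str
        Row labels, aligned with a paired :class:`BehaviorTable`.
    """

    matrix: np.ndarray
    mask: np.ndarray
    voxel_index: np.ndarray
    subject_ids: list[str]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        self.subject_ids = [str(s) for s in self.subject_ids]
        n, p = self.matrix.shape
        if n < 3:
            raise DataError(f"need at least 3 subjects, got {n}")
        if p != int(self.mask.sum()):
            raise GeometryError(
                f"matrix has {p} columns but mask has {int(self.mask.sum())} voxels"
            )
        if self.voxel_index.shape != (p, 3):
            raise GeometryError("voxel_index must be (P, 3)")
        if len(self.subject_ids) != n:
            raise DataError("subject_ids length must match matrix rows")
        if not np.all(np.isfinite(self.matrix)):
            raise DataError("non-finite voxel values in feature matrix")
        coords = self.voxel_index
        if len({tuple(c) for c in coords}) != p:
            raise GeometryError("duplicate voxel coordinates")
        if p and not self.mask[tuple(coords.T)].all():
            raise GeometryError("voxel_index contains coordinates outside the mask")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]

    def to_volume(self, values: np.ndarray) -> np.ndarray:
        """Scatter a length-P vector back into a 3-D volume (zero off-mask)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise GeometryError("values must have one entry per mask voxel")
        vol = np.zeros(self.mask.shape, dtype=float)
        vol[tuple(self.voxel_index.T)] = values
        return vol


@dataclass
class BehaviorTable:
    """Per-subject behavioral scores and covariates.

    ``scores`` maps each score name to a length-N vector; ``covariates`` is an
    N x C frame with named columns (e.g. ``age``, ``gender``).
    """

    scores: dict[str, np.ndarray]
    covariates: pd.DataFrame
    subject_ids: list[str]
    rejected_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        n = len(self.subject_ids)
        clean = {}
        for name, vec in self.scores.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n,):
                raise DataError(f"score {name!r} has length {vec.shape}, expected {n}")
            if not np.all(np.isfinite(vec)):
                raise DataError(f"score {name!r} contains missing/non-finite values")
            clean[name] = vec
        self.scores = clean
        self.covariates = pd.DataFrame(self.covariates)
        if len(self.covariates) != n:
            raise DataError("covariates must have one row per subject")
        if not np.all(np.isfinite(self.covariates.to_numpy(dtype=float))):
            raise DataError("covariates contain missing/non-finite values")
        self.covariates.index = pd.Index(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def score(self, name: str) -> np.ndarray:
        if name not in self.scores:
            raise SchemaError(
                f"unknown score {name!r}; available: {sorted(self.scores)}"
            )
        return self.scores[name]

    def covariate_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = list(self.covariates.columns) if names is None else list(names)
        missing = [c for c in names if c not in self.covariates.columns]
        if missing:
            raise SchemaError(f"missing covariate columns: {missing}")
        return self.covariates[names].to_numpy(dtype=float)


@dataclass
class SaliencyVolume:
    """A result map in mask geometry: bootstrap ratios or a signed -1/0/+1 mask."""

    values: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise GeometryError("values and mask shapes differ")
        if not self.meta.get("filled", False):
            off = self.values[~self.mask]
            if off.size and np.any(off != 0):
                raise GeometryError("nonzero values outside the mask")


def mask_voxel_index(mask: np.ndarray) -> np.ndarray:
    """C-order raster coordinates of the true voxels of ``mask`` (last axis fastest)."""
    return np.argwhere(np.asarray(mask, dtype=bool))


def load_skeleton_dataset(
    image_path: str | Path | Sequence[str | Path],
    mask_path: str | Path,
    fa_threshold: float = 0.0,
    subject_ids: Sequence[str] | None = None,
) -> SkeletonDataset:
    """Load per-subject skeleton volumes into an ``N x P`` matrix.

    ``image_path`` is either a single 4-D NIfTI (last axis = subjects) or a
    list of 3-D NIfTIs, one per subject.  When ``fa_threshold > 0`` the mask is
    additionally restricted to voxels whose *mean* value across subjects
    exceeds the threshold — mirroring how a mean-FA skeleton is thresholded
    (default 0.2) before voxelwise statistics.
    """
    if fa_threshold < 0:
        raise DataError("fa_threshold must be >= 0")
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    if mask.ndim != 3:
        raise GeometryError("mask must be a 3-D volume")

    if isinstance(image_path, (str, Path)):
        img = nib.load(str(image_path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 3:
            data = data[..., np.newaxis]
        if data.ndim != 4:
            raise GeometryError("image must be 3-D or 4-D")
        if data.shape[:3] != mask.shape:
            raise GeometryError(
                f"image grid {data.shape[:3]} != mask grid {mask.shape}"
            )
        stack = np.moveaxis(data, -1, 0)  # subjects first
    else:
        vols = []
        for p in image_path:
            d = np.asarray(nib.load(str(p)).dataobj, dtype=float)
            if d.shape != mask.shape:
                raise GeometryError(
                    f"image grid {d.shape} ({p}) != mask grid {mask.shape}"
                )
            vols.append(d)
        stack = np.stack(vols, axis=0)

    if not np.all(np.isfinite(stack[:, mask])):
        raise DataError("non-finite voxel values inside the mask")

    if fa_threshold > 0:
        mean_img = stack.mean(axis=0)
        mask = mask & (mean_img > fa_threshold)
    if not mask.any():
        raise GeometryError("no voxels survive the mask / FA threshold")

    coords = mask_voxel_index(mask)
    matrix = stack[:, mask]  # boolean indexing follows C-order == argwhere order
    n = matrix.shape[0]
    ids = [f"sub-{i:04d}" for i in range(n)] if subject_ids is None else list(subject_ids)
    return SkeletonDataset(
        matrix=matrix,
        mask=mask,
        voxel_index=coords,
        subject_ids=ids,
        affine=np.asarray(mask_img.affine),
    )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype={0: str})


def load_behavior_table(
    table_path: str | Path,
    score_columns: Sequence[str],
    covariate_columns: Sequence[str] = (),
    id_column: str = "subject_id",
    gender_map: Mapping[str, float] = DEFAULT_GENDER_MAP,
) -> BehaviorTable:
    """Read a delimited subject table (tab for .tsv/.txt, comma for .csv).

    Rows with a missing value in any requested column are dropped; their ids
    are logged and recorded in ``rejected_ids``.  Non-numeric gender labels
    are mapped through ``gender_map`` (unknown labels are an error).
    """
    df = _read_table(table_path)
    needed = [id_column, *score_columns, *covariate_columns]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table_path} is missing columns: {missing}")

    df = df.copy()
    df[id_column] = df[id_column].astype(str)

    for col in covariate_columns:
        if df[col].dtype == object:
            mapped = df[col].astype(str).str.strip().str.lower().map(gender_map)
            bad = df[col][mapped.isna() & df[col].notna()]
            if len(bad):
                raise DataError(
                    f"column {col!r} has labels outside the coding map: "
                    f"{sorted(set(bad))}"
                )
            df[col] = mapped

    for col in score_columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        # distinguish 'value present but not a number' from 'missing'
        non_numeric = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if non_numeric.any():
            raise DataError(
                f"non-numeric score values in {col!r} for subjects "
                f"{df.loc[non_numeric, id_column].tolist()}"
            )
        df[col] = coerced

    keep = df[needed].notna().all(axis=1)
    rejected = df.loc[~keep, id_column].tolist()
    if rejected:
        logger.warning("rejected %d rows with missing values: %s", len(rejected), rejected)
    df = df.loc[keep]
    if df.empty:
        raise DataError("no complete rows remain after missing-value rejection")

    scores = {c: df[c].to_numpy(dtype=float) for c in score_columns}
    cov = df[list(covariate_columns)].astype(float).reset_index(drop=True)
    return BehaviorTable(
        scores=scores,
        covariates=cov,
        subject_ids=df[id_column].tolist(),
        rejected_ids=rejected,
    )


def align_subjects(
    dataset: SkeletonDataset, table: BehaviorTable
) -> tuple[SkeletonDataset, BehaviorTable]:
    """Restrict both containers to their common subjects, in dataset order.

    The retained order is the order of ``dataset.subject_ids`` filtered to the
    intersection, so the operation is idempotent.
    """
    table_pos = {s: i for i, s in enumerate(table.subject_ids)}
    keep = [i for i, s in enumerate(dataset.subject_ids) if s in table_pos]
    if not keep:
        raise PairingError("imaging and behavioral tables share no subject ids")
    dropped = (len(dataset.subject_ids) - len(keep)) + (len(table.subject_ids) - len(keep))
    if dropped:
        logger.info("align_subjects dropped %d unmatched subject rows", dropped)

    ids = [dataset.subject_ids[i] for i in keep]
    ds = SkeletonDataset(
        matrix=dataset.matrix[keep],
        mask=dataset.mask,
        voxel_index=dataset.voxel_index,
        subject_ids=ids,
        affine=dataset.affine,
    )
    tidx = [table_pos[s] for s in ids]
    tb = BehaviorTable(
        scores={k: v[tidx] for k, v in table.scores.items()},
        covariates=table.covariates.iloc[tidx].reset_index(drop=True),
        subject_ids=ids,
    )
    return ds, tb


def write_saliency(
    volume: SaliencyVolume,
    out_path: str | Path,
    affine: np.ndarray | None = None,
) -> Path:
    """Write a saliency volume to NIfTI (float32; signed masks round-trip exactly).

    The affine comes from ``affine``, then ``volume.meta['affine']``, then
    identity.  Values are validated against the mask invariant before writing.
    """
    SaliencyVolume(volume.values, volume.mask, volume.meta)  # re-validate
    if affine is None:
        affine = volume.meta.get("affine")
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(volume.values.astype(np.float32), np.asarray(affine))
    img.header.set_data_dtype(np.float32)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(out_path))
    return out_path


def read_saliency(path: str | Path, mask: np.ndarray, **meta) -> SaliencyVolume:
    """Read a NIfTI written by :func:`write_saliency` back into mask geometry."""
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    meta.setdefault("affine", np.asarray(img.affine))
    return SaliencyVolume(values=values, mask=mask, meta=meta)
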