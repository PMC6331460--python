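import nibabel as nib
import numpy as np
import pandas as pd
import pytest

from skelcca import SimulationConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Planted-signal cohort small enough for per-test resampling."""
    cfg = SimulationConfig(
        n_subjects=60,
        grid_shape=(10, 10, 8),
        skeleton_fraction=0.25,
        n_salient=20,
        rho=0.6,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def nifti_cohort(tmp_path):
    """A tiny cohort written to disk as 4-D NIfTI + mask + TSV table."""
    rng = np.random.default_rng(0)
    shape = (6, 5, 4)
    mask = np.zeros(shape, dtype=bool)
    mask[1:5, 1:4, 1:3] = True
    n = 8
    data = np.zeros((*shape, n))
    data[mask, :] = rng.uniform(0.1, 0.9, size=(int(mask.sum()), n))
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    img_path = tmp_path / "fa.nii.gz"
    mask_path = tmp_path / "mask.nii.gz"
    nib.save(nib.Nifti1Image(data, affine), str(img_path))
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(mask_path))
    table_path = tmp_path / "subjects.tsv"
    pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "agreeableness": rng.normal(100, 15, n),
            "age": rng.uniform(65, 80, n).round(1),
            "gender": rng.integers(0, 2, n),
        }
    ).to_csv(table_path, sep="\t", index=False)
    return {"images": img_path, "mask": mask_path, "table": table_path,
            "mask_array": mask, "n": n}
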