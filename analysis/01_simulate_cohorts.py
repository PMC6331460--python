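#!/usr/bin/env python
"""Generate the synthetic study cohorts used by the downstream analyses.

Writes one planted-association cohort (N=160 subjects, ~2000 skeleton voxels,
latent correlation rho=0.5 — mid-range of the effect sizes the method is
designed for) and one matched null cohort to scratch/cohorts/ in the NIfTI +
TSV layout the loaders consume.  All downstream scripts regenerate nothing:
they read these files like a real study would.
"""

from pathlib import Path

from skelcca import SimulationConfig, generate_cohort, make_null_cohort, write_cohort

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohorts"

CONFIG = SimulationConfig(
    n_subjects=160,
    grid_shape=(24, 24, 24),
    skeleton_fraction=0.15,
    n_salient=50,
    frac_negative=0.3,
    rho=0.5,
    seed=20260924,
)


def main() -> None:
    dataset, table, truth = generate_cohort(CONFIG)
    paths = write_cohort(dataset, table, OUT / "planted", truth=truth)
    print(f"planted cohort: N={dataset.n_subjects}, P={dataset.n_voxels}, "
          f"rho={CONFIG.rho} -> {paths['images'].parent}")

    null_ds, null_tb = make_null_cohort(CONFIG)
    null_paths = write_cohort(null_ds, null_tb, OUT / "null")
    print(f"null cohort:    N={null_ds.n_subjects}, P={null_ds.n_voxels}, "
          f"rho=0.0 -> {null_paths['images'].parent}")


if __name__ == "__main__":
    main()
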