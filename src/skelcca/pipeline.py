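"""Study orchestration: one config drives load -> align -> select Q ->
permutation -> bootstrap -> maps, independently per behavioral score.

Each analysis group (e.g. controls, MCI) is one invocation with its own
config; no between-group statistics are computed.  The machine-readable
summary is timestamp-free so a rerun with the same config and seed is
byte-identical; wall-clock provenance lives in the human-readable log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import (
    SaliencyVolume,
    align_subjects,
    load_behavior_table,
    load_skeleton_dataset,
    write_saliency,
)
from .errors import ConfigError, SchemaError, SkelccaError
from .inference import adjusted_and_unadjusted, analyze_score, fill_for_display

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Everything one analysis run needs; defaults match the standard protocol
    (10000 permutations, B=1000 bootstrap folds, ratio threshold 1.96,
    mean-FA mask threshold 0.2)."""

    image_path: str | list[str]
    mask_path: str
    table_path: str
    output_dir: str
    scores: list[str]
    covariates: list[str] = field(default_factory=lambda: ["age", "gender"])
    id_column: str = "subject_id"
    fa_threshold: float = 0.2
    n_perm: int = 10000
    b_folds: int = 1000
    threshold: float = 1.96
    q_max: int | None = None   # cap on the LOO-CV grid; None -> min(N-2, P)
    fill_radius: int = 1
    seed: int = 0
    adjustment: str = "both"   # both | unadjusted | adjusted

    def __post_init__(self) -> None:
        if not self.scores:
            raise ConfigError("at least one score name is required")
        if self.adjustment not in {"both", "unadjusted", "adjusted"}:
            raise ConfigError("adjustment must be both|unadjusted|adjusted")
        if self.threshold < 0 or self.fa_threshold < 0:
            raise ConfigError("thresholds must be >= 0")
        if self.n_perm < 99 or self.b_folds < 10:
            raise ConfigError("n_perm >= 99 and b_folds >= 10 required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown study config keys: {sorted(unknown)}")
        missing = {"image_path", "mask_path", "table_path", "output_dir", "scores"} - set(raw)
        if missing:
            raise ConfigError(f"study config missing keys: {sorted(missing)}")
        return cls(**raw)


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Run the full per-score analysis chain and write the result bundle.

    Writes, per score and arm: a bootstrap-ratio NIfTI, a signed-mask NIfTI
    and its display-filled version, plus one summary table (TSV) and a JSON
    provenance record covering every constant needed to reproduce the run.
    A score failing at any stage is logged and skipped; other scores proceed.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("skelcca")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        dataset = load_skeleton_dataset(
            config.image_path, config.mask_path, fa_threshold=config.fa_threshold
        )
        table = load_behavior_table(
            config.table_path,
            score_columns=config.scores,
            covariate_columns=config.covariates,
            id_column=config.id_column,
        )
        dataset, table = align_subjects(dataset, table)
        logger.info(
            "aligned cohort: N=%d subjects, P=%d voxels", dataset.n_subjects, dataset.n_voxels
        )
        mean_fa = np.zeros(dataset.mask.shape)
        mean_fa[dataset.mask] = dataset.matrix.mean(axis=0)

        n, p = dataset.matrix.shape
        q_cap = min(n - 2, p)
        if config.q_max is not None:
            q_cap = min(q_cap, config.q_max)
        q_grid = range(1, q_cap + 1)

        arms = (
            ["unadjusted", "adjusted"] if config.adjustment == "both" else [config.adjustment]
        )
        rows = []
        for score_name in config.scores:
            try:
                results = _run_one_score(dataset, table, score_name, q_grid, config, arms)
            except SkelccaError as exc:
                logger.error("score %s aborted: %s", score_name, exc)
                continue
            for arm, res in results.items():
                rows.append(
                    {
                        "score": score_name,
                        "arm": arm,
                        "n_subjects": n,
                        "n_voxels": p,
                        "q": res.selection.selected_q,
                        "R": round(res.solution.correlation, 6),
                        "p_value": round(res.permutation.p_value, 6),
                        "bootstrap_R_sd": round(float(np.std(res.saliency.fold_correlations, ddof=1)), 6)
                        if res.saliency is not None
                        else float("nan"),
                        "n_suprathreshold": int(np.sum(res.saliency.signed_mask != 0))
                        if res.saliency is not None
                        else 0,
                        "n_redraws": res.saliency.n_redraws if res.saliency is not None else 0,
                        "n_perm": config.n_perm,
                        "b_folds": config.b_folds,
                        "threshold": config.threshold,
                        "seed": config.seed,
                    }
                )
                if res.saliency is not None:
                    _write_maps(dataset, mean_fa, res, score_name, arm, config, out_dir)

        summary = pd.DataFrame(rows)
        summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
        provenance = {
            "package_version": __version__,
            "config": {k: v for k, v in vars(config).items()},
            "n_subjects": n,
            "n_voxels": p,
            "q_grid_max": q_cap,
        }
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_one_score(dataset, table, score_name, q_grid, config, arms):
    if set(arms) == {"unadjusted"}:
        res = analyze_score(
            dataset.matrix,
            table.score(score_name),
            q_grid,
            n_perm=config.n_perm,
            b_folds=config.b_folds,
            threshold=config.threshold,
            seed=config.seed,
        )
        return {"unadjusted": res}
    both = adjusted_and_unadjusted(
        dataset,
        table,
        score_name,
        covariate_columns=config.covariates,
        q_grid=q_grid,
        n_perm=config.n_perm,
        b_folds=config.b_folds,
        threshold=config.threshold,
        seed=config.seed,
    )
    return {arm: both[arm] for arm in arms}


def _write_maps(dataset, mean_fa, res, score_name, arm, config, out_dir):
    sal = res.saliency
    meta = {
        "score": score_name,
        "arm": arm,
        "q": res.selection.selected_q,
        "b_folds": sal.b_folds,
        "threshold": sal.threshold,
        "seed": config.seed,
        "affine": dataset.affine,
    }
    finite_ratio = np.where(np.isfinite(sal.ratio), sal.ratio, 0.0)
    ratio_vol = SaliencyVolume(dataset.to_volume(finite_ratio), dataset.mask, dict(meta))
    mask_vol = SaliencyVolume(
        dataset.to_volume(sal.signed_mask.astype(float)), dataset.mask, dict(meta)
    )
    stem = out_dir / f"{score_name}_{arm}"
    write_saliency(ratio_vol, f"{stem}_bootstrap_ratio.nii.gz")
    write_saliency(mask_vol, f"{stem}_signed_mask.nii.gz")
    filled = fill_for_display(mask_vol, mean_fa, radius=config.fill_radius)
    write_saliency(filled, f"{stem}_signed_mask_filled.nii.gz")
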