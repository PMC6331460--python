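"""Resampling inference: LOO-CV dimensionality selection, permutation
significance, and bootstrap-ratio saliency mapping.

The analysis chain for one behavioral score is:

1.  Choose the number of retained SVD components Q by leave-one-out
    cross-validation: for each candidate q, refit the reduction and the
    canonical pair on N-1 subjects, project the held-out subject, and keep the
    q whose pooled held-out variate pairs correlate best.
2.  Test the full-data canonical correlation R against a permutation null
    (score entries shuffled, imaging block untouched, Q held fixed).
3.  Assess per-voxel reliability by resampling subjects with replacement:
    each bootstrap fold is re-reduced, its components Procrustes-aligned to
    the full-data components, refit, sign-corrected against the full-data
    solution, and back-projected to voxel space.  The bootstrap ratio
    (mean / SD over folds, per voxel) is a pseudo-z; |ratio| >= 1.96 marks a
    voxel as reliably positive or negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .core import (
    RANK_TOL,
    CCASolution,
    ReducedBasis,
    backproject,
    fit_cca_single,
    fit_truncated_svd,
    residualize,
)
from .datasets import BehaviorTable, SaliencyVolume, SkeletonDataset
from .errors import (
    DegenerateDataError,
    ParameterError,
    SchemaError,
)

logger = logging.getLogger(__name__)

MAX_REDRAWS = 100


def _as_matrix(dataset) -> np.ndarray:
    return dataset.matrix if isinstance(dataset, SkeletonDataset) else np.asarray(dataset, float)


@dataclass
class CVSelection:
    """Leave-one-out CV correlations over candidate dimensionalities."""

    cv_correlations: dict[int, float]
    selected_q: int
    n_folds: int


@dataclass
class PermutationResult:
    """Observed canonical correlation against its permutation null."""

    observed_r: float
    null_rs: np.ndarray
    p_value: float
    n_perm: int
    seed: int


@dataclass
class SaliencyResult:
    """Per-voxel bootstrap weight distributions and their ratio summary."""

    weight_distribution: np.ndarray  # (B, P)
    ratio: np.ndarray                # (P,)
    signed_mask: np.ndarray          # (P,) in {-1, 0, +1}
    threshold: float
    b_folds: int
    reference_weights: np.ndarray    # (P,) full-data voxel weights
    fold_correlations: np.ndarray = field(default=None)  # (B,) per-fold R
    n_redraws: int = 0
    degenerate_voxels: np.ndarray = field(default=None)  # zero-variance flags


def loocv_select_q(dataset, y: np.ndarray, q_grid) -> CVSelection:
    """Choose the retained dimensionality Q by leave-one-out cross-validation.

    For each candidate q and each held-out subject: refit SVD + CCA on the
    remaining N-1 subjects, sign-align the fold solution to the full-data
    solution via the correlation of back-projected voxel weights, project the
    held-out row to a held-out canonical score u, and pair it with the
    held-out centered behavioral value v.  The CV correlation for q is the
    Pearson correlation of the N pooled (u, v) pairs; the selected Q maximizes
    it (ties broken toward the smallest q).
    """
    x = _as_matrix(dataset)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if n < 4:
        raise ParameterError("LOO-CV needs at least 4 subjects")
    q_grid = sorted({int(q) for q in q_grid})
    q_max_allowed = min(n - 2, p)
    if not q_grid or q_grid[0] < 1 or q_grid[-1] > q_max_allowed:
        raise ParameterError(f"q_grid must lie within 1..{q_max_allowed}")
    q_max = q_grid[-1]

    # full-data reference weights per q, for fold sign alignment
    basis_full, scores_full = fit_truncated_svd(x, q_max)
    w_full = {}
    for q in q_grid:
        sol = fit_cca_single(scores_full[:, :q], y)
        w_full[q] = basis_full.components[:, :q] @ sol.weights_x

    held_u = {q: np.empty(n) for q in q_grid}
    held_v = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        y_fold = y[keep]
        if np.ptp(y_fold) == 0:
            raise DegenerateDataError(f"fold {i}: remaining score vector is constant")
        x_fold = x[keep]
        mu = x_fold.mean(axis=0)
        xc = x_fold - mu
        u_svd, s_svd, vt = scipy.linalg.svd(xc, full_matrices=False)
        held_row = x[i] - mu
        held_v[i] = y[i] - y_fold.mean()
        for q in q_grid:
            fold_scores = u_svd[:, :q] * s_svd[:q]
            sol = fit_cca_single(fold_scores, y_fold)
            w_fold = vt[:q].T @ sol.weights_x
            sign = 1.0 if float(w_fold @ w_full[q]) >= 0 else -1.0
            held_u[q][i] = sign * float((held_row @ vt[:q].T) @ sol.weights_x)

    cv = {}
    for q in q_grid:
        u = held_u[q]
        if np.ptp(u) == 0:
            cv[q] = 0.0
        else:
            cv[q] = float(np.corrcoef(u, held_v)[0, 1])
    selected = q_grid[0]
    for q in q_grid[1:]:
        if cv[q] > cv[selected]:
            selected = q
    return CVSelection(cv_correlations=cv, selected_q=selected, n_folds=n)


def permutation_test(
    dataset, y: np.ndarray, q: int, n_perm: int = 10000, seed: int = 0
) -> PermutationResult:
    """Permutation test of the canonical correlation at a fixed Q.

    Only the score vector is permuted; the imaging block (and hence its SVD
    basis) is unchanged, so each permutation refits the canonical pair on the
    same reduced scores.  The p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_perm)``, never exactly zero.
    """
    x = _as_matrix(dataset)
    y = np.asarray(y, dtype=float).ravel()
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")
    if np.ptp(y) == 0:
        raise DegenerateDataError("score vector is constant")
    basis, scores = fit_truncated_svd(x, q)
    observed = fit_cca_single(scores, y).correlation

    # With a 1-D behavioral block, R is the norm of the projection of the
    # centered score onto the (orthonormalized) component scores; the centered
    # permuted score is a permutation of the centered score, so one matrix
    # product evaluates all permutations at once.
    yc = y - y.mean()
    y_norm = float(np.linalg.norm(yc))
    u_orth = scores / basis.singular_values  # left singular vectors, orthonormal
    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_perm, y.size)), axis=1)
    null_rs = np.linalg.norm(u_orth.T @ yc[perm].T, axis=0) / y_norm
    p_value = float((1 + np.sum(null_rs >= observed)) / (1 + n_perm))
    return PermutationResult(
        observed_r=observed,
        null_rs=null_rs,
        p_value=p_value,
        n_perm=n_perm,
        seed=seed,
    )


def compute_bootstrap_ratio(weight_distribution: np.ndarray):
    """Mean / SD (N-1 denominator) per voxel over bootstrap folds.

    Voxels whose weight distribution has zero variance but nonzero mean get a
    ``sign(mean) * inf`` sentinel (all-zero distributions get 0); a boolean
    flag vector marks them.
    """
    w = np.asarray(weight_distribution, dtype=float)
    mean = w.mean(axis=0)
    sd = w.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean / sd
        ratio[degenerate] = np.sign(mean[degenerate]) * np.inf
    ratio[degenerate & (mean == 0)] = 0.0
    return ratio, degenerate


def threshold_ratios(ratio: np.ndarray, threshold: float) -> np.ndarray:
    """Signed suprathreshold mask: ``sign(ratio)`` where ``|ratio| >= threshold``."""
    ratio = np.asarray(ratio, dtype=float)
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    with np.errstate(invalid="ignore"):
        supra = np.abs(ratio) >= threshold
    return (np.sign(ratio) * supra).astype(int)


def bootstrap_saliency(
    dataset,
    y: np.ndarray,
    q: int,
    b_folds: int = 1000,
    threshold: float = 1.96,
    seed: int = 0,
) -> SaliencyResult:
    """Bootstrap-ratio saliency of every voxel's contribution to the correlation.

    Subjects are resampled with replacement ``b_folds`` times.  Each fold's
    feature matrix is re-reduced by SVD, its components Procrustes-aligned to
    the full-data components (removing rotation/reflection indeterminacy), the
    canonical pair refit, the fold solution's global sign corrected against
    the full-data back-projected weights, and the fold weights back-projected
    to voxel space.  Folds whose resampled score is constant are redrawn (at
    most ``MAX_REDRAWS`` times in total).
    """
    x = _as_matrix(dataset)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if b_folds < 10:
        raise ParameterError("b_folds must be >= 10")
    basis, scores = fit_truncated_svd(x, q)
    if basis.q < q:
        raise ParameterError(f"full data supports only {basis.q} components, q={q}")
    sol_full = fit_cca_single(scores, y)
    w_ref = backproject(sol_full.weights_x, basis)

    rng = np.random.default_rng(seed)
    weights = np.empty((b_folds, p))
    fold_r = np.empty(b_folds)
    redraws = 0
    for b in range(b_folds):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.ptp(y[idx]) > 0:
                break
            redraws += 1
            if redraws > MAX_REDRAWS:
                raise DegenerateDataError(
                    f"exceeded {MAX_REDRAWS} redraws of constant-score folds"
                )
        y_b = y[idx]
        xc = x[idx] - x[idx].mean(axis=0)
        u_svd, s_svd, vt = scipy.linalg.svd(xc, full_matrices=False)
        if s_svd[q - 1] < RANK_TOL * s_svd[0]:
            raise DegenerateDataError(f"bootstrap fold {b} has rank below q={q}")
        vb = vt[:q].T
        rotation, vb_aligned = _procrustes(vb, basis.components)
        scores_b = (u_svd[:, :q] * s_svd[:q]) @ rotation
        sol_b = fit_cca_single(scores_b, y_b)
        w_b = vb_aligned @ sol_b.weights_x
        if float(w_b @ w_ref) < 0:
            w_b = -w_b
        weights[b] = w_b
        fold_r[b] = sol_b.correlation
    if redraws:
        logger.info("bootstrap_saliency redrew %d degenerate folds", redraws)

    ratio, degenerate = compute_bootstrap_ratio(weights)
    signed = threshold_ratios(ratio, threshold)
    return SaliencyResult(
        weight_distribution=weights,
        ratio=ratio,
        signed_mask=signed,
        threshold=threshold,
        b_folds=b_folds,
        reference_weights=w_ref,
        fold_correlations=fold_r,
        n_redraws=redraws,
        degenerate_voxels=degenerate,
    )


def _procrustes(source: np.ndarray, reference: np.ndarray):
    # internal fast path: inputs are SVD factors, orthonormal by construction
    rotation, _ = scipy.linalg.orthogonal_procrustes(source, reference)
    return rotation, source @ rotation


def fill_for_display(
    volume: SaliencyVolume, mean_fa: np.ndarray, radius: int = 1
) -> SaliencyVolume:
    """Thicken a signed suprathreshold mask for display.

    Each suprathreshold voxel's sign is dilated into neighbors within the
    given Chebyshev radius wherever ``mean_fa > 0.2`` (the same low-FA cutoff
    that defines the skeleton).  Voxels reached by both signs stay 0; original
    suprathreshold voxels are never overwritten.  Display-only: the result is
    marked ``filled`` in its metadata and must not feed back into analysis.
    """
    from scipy.ndimage import binary_dilation

    if radius < 0:
        raise ParameterError("radius must be >= 0")
    values = volume.values
    if radius == 0:
        return SaliencyVolume(values.copy(), volume.mask, {**volume.meta})
    mean_fa = np.asarray(mean_fa, dtype=float)
    structure = np.ones((3, 3, 3), dtype=bool)
    pos = binary_dilation(values > 0, structure=structure, iterations=radius)
    neg = binary_dilation(values < 0, structure=structure, iterations=radius)
    allowed = (values == 0) & (mean_fa > 0.2)
    out = values.copy()
    out[allowed & pos & ~neg] = 1.0
    out[allowed & neg & ~pos] = -1.0
    meta = {**volume.meta, "filled": True, "fill_radius": radius}
    return SaliencyVolume(out, volume.mask, meta)


@dataclass
class ScoreAnalysis:
    """Full chain for one score: Q selection, full fit, permutation, bootstrap."""

    selection: CVSelection
    solution: CCASolution
    basis: ReducedBasis
    permutation: PermutationResult
    saliency: SaliencyResult | None


def analyze_score(
    x,
    y: np.ndarray,
    q_grid,
    n_perm: int = 10000,
    b_folds: int = 1000,
    threshold: float = 1.96,
    seed: int = 0,
    run_bootstrap: bool = True,
) -> ScoreAnalysis:
    """Q selection -> full-data fit -> permutation p -> bootstrap saliency."""
    x = _as_matrix(x)
    selection = loocv_select_q(x, y, q_grid)
    q = selection.selected_q
    basis, scores = fit_truncated_svd(x, q)
    solution = fit_cca_single(scores, y)
    permutation = permutation_test(x, y, q, n_perm=n_perm, seed=seed)
    saliency = None
    if run_bootstrap:
        saliency = bootstrap_saliency(
            x, y, q, b_folds=b_folds, threshold=threshold, seed=seed + 1
        )
    return ScoreAnalysis(
        selection=selection,
        solution=solution,
        basis=basis,
        permutation=permutation,
        saliency=saliency,
    )


def adjusted_and_unadjusted(
    dataset: SkeletonDataset,
    table: BehaviorTable,
    score_name: str,
    covariate_columns=("age", "gender"),
    q_grid=None,
    n_perm: int = 10000,
    b_folds: int = 1000,
    threshold: float = 1.96,
    seed: int = 0,
    run_bootstrap: bool = True,
) -> dict[str, ScoreAnalysis]:
    """Run the full chain twice: on raw data and after covariate residualization.

    The adjusted arm residualizes *both* the voxel block and the score on an
    intercept plus the named covariates (typically age and gender) before
    repeating Q selection, permutation, and bootstrap.
    """
    y = table.score(score_name)
    x = dataset.matrix
    if q_grid is None:
        q_grid = range(1, min(x.shape[0] - 2, x.shape[1]) + 1)
    missing = [c for c in covariate_columns if c not in table.covariates.columns]
    if missing:
        raise SchemaError(f"missing covariate columns for adjustment: {missing}")
    cov = table.covariate_matrix(covariate_columns)

    results = {}
    results["unadjusted"] = analyze_score(
        x, y, q_grid, n_perm=n_perm, b_folds=b_folds, threshold=threshold,
        seed=seed, run_bootstrap=run_bootstrap,
    )
    x_adj = residualize(x, cov)
    y_adj = residualize(y, cov)
    results["adjusted"] = analyze_score(
        x_adj, y_adj, q_grid, n_perm=n_perm, b_folds=b_folds, threshold=threshold,
        seed=seed, run_bootstrap=run_bootstrap,
    )
    return results
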