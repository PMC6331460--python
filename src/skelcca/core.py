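"""Numerical core: residualization, truncated SVD, Procrustes, 1-D CCA.

With a one-dimensional behavioral block, canonical correlation analysis
degenerates to the multiple correlation coefficient: the canonical weight
vector ``E`` on the reduced imaging scores is (up to scale) the OLS
coefficient vector of the score on those components, and the canonical
correlation ``R`` is sqrt(R^2) of that regression.  :func:`fit_cca_single`
implements exactly this, with a fixed sign convention (``weight_y > 0`` and
``R >= 0``) so that a positive back-projected voxel weight always means
"higher feature value goes with higher score".

Singular values below ``RANK_TOL`` times the largest are treated as zero
everywhere (dropped from bases, rejected as collinearity) rather than
inverted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import ConditioningError, DegenerateDataError, ParameterError

RANK_TOL = 1e-10


@dataclass
class ReducedBasis:
    """Truncated SVD of a column-centered feature matrix.

    ``components`` holds the leading right singular vectors (P x q,
    orthonormal columns); ``column_means`` are the centering statistics of the
    fitting data, reused verbatim when projecting held-out rows.
    """

    components: np.ndarray       # (P, q), orthonormal columns
    singular_values: np.ndarray  # (q,), non-increasing, positive
    column_means: np.ndarray     # (P,)
    q: int

    def project(self, rows: np.ndarray) -> np.ndarray:
        """Project (possibly held-out) feature rows onto the basis."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        return (rows - self.column_means) @ self.components


@dataclass
class CCASolution:
    """One canonical pair for a reduced imaging block and a single score.

    ``variate_x = centered_scores @ weights_x`` and
    ``variate_y = weight_y * centered_y`` each have unit sample variance;
    ``correlation`` is their Pearson correlation (>= 0 by sign convention).
    """

    weights_x: np.ndarray  # (Q,)  -- E
    weight_y: float        # scalar -- F, > 0
    variate_x: np.ndarray  # (N,)  -- U
    variate_y: np.ndarray  # (N,)  -- V
    correlation: float     # R in [0, 1]


def residualize(block: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residualize each column of ``block`` on an intercept plus ``covariates``.

    Returns the least-squares residuals, orthogonal to the intercept and to
    every covariate column.  Used to produce age/gender-adjusted analyses.
    """
    block = np.asarray(block, dtype=float)
    squeeze = block.ndim == 1
    if squeeze:
        block = block[:, np.newaxis]
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != block.shape[0]:
        covariates = covariates.T
    n, c = covariates.shape
    if n <= c + 1:
        raise ParameterError(f"need N > C+1 rows, got N={n}, C={c}")
    design = np.column_stack([np.ones(n), covariates])
    sv = scipy.linalg.svdvals(design)
    if sv[-1] < RANK_TOL * sv[0]:
        raise ConditioningError("covariate design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, block, rcond=None)
    resid = block - design @ beta
    return resid[:, 0] if squeeze else resid


def fit_truncated_svd(matrix: np.ndarray, q: int) -> tuple[ReducedBasis, np.ndarray]:
    """Center columns and keep the top ``q`` singular triplets.

    Returns the basis and the N x q score matrix (``centered @ components``,
    i.e. ``U_q * s_q``).  Components whose singular value falls below
    ``RANK_TOL * s_1`` are dropped with a warning, so the returned ``q`` may be
    smaller than requested on rank-deficient input.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ParameterError("matrix must be 2-D")
    n, p = matrix.shape
    if not np.all(np.isfinite(matrix)):
        raise ParameterError("matrix contains non-finite values")
    q_max = min(n - 1, p)
    if not (1 <= q <= q_max):
        raise ParameterError(f"q={q} outside 1..{q_max} for a {n}x{p} matrix")
    means = matrix.mean(axis=0)
    centered = matrix - means
    u, s, vt = scipy.linalg.svd(centered, full_matrices=False)
    keep = min(q, s.size)
    good = s[:keep] > RANK_TOL * s[0] if s[0] > 0 else np.zeros(keep, dtype=bool)
    if not good.all():
        warnings.warn(
            f"dropping {int((~good).sum())} numerically null components "
            f"(singular value < {RANK_TOL} * s1)",
            RuntimeWarning,
            stacklevel=2,
        )
        keep = int(good.sum())
        if keep == 0:
            raise ConditioningError("matrix has no non-null singular values")
    basis = ReducedBasis(
        components=vt[:keep].T.copy(),
        singular_values=s[:keep].copy(),
        column_means=means,
        q=keep,
    )
    scores = u[:, :keep] * s[:keep]
    return basis, scores


def procrustes_align(
    source: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal Procrustes: rotate ``source`` columns onto ``reference``.

    Finds the orthogonal Q x Q matrix (reflections allowed — SVD components
    carry arbitrary signs) minimizing ``||source @ R - reference||_F`` and
    returns ``(R, source @ R)``.
    """
    source = np.asarray(source, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if source.shape != reference.shape or source.ndim != 2:
        raise ParameterError("source and reference must be equal-shape 2-D arrays")
    for name, m in (("source", source), ("reference", reference)):
        gram = m.T @ m
        if not np.allclose(gram, np.eye(m.shape[1]), atol=1e-8):
            raise ParameterError(f"{name} columns are not orthonormal within 1e-8")
    rotation, _ = scipy.linalg.orthogonal_procrustes(source, reference)
    return rotation, source @ rotation


def fit_cca_single(scores: np.ndarray, y: np.ndarray) -> CCASolution:
    """Single canonical pair between reduced imaging scores and one score vector.

    Solves the K=1 canonical correlation problem for an N x Q imaging block
    against a length-N behavioral vector by ordinary least squares: the
    canonical correlation equals the multiple correlation coefficient of ``y``
    on the score columns.  Variates are scaled to unit sample variance and the
    sign convention ``weight_y > 0``, ``correlation >= 0`` is enforced.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if scores.ndim != 2 or scores.shape[0] != y.size:
        raise ParameterError("scores must be N x Q with one row per y entry")
    n, q = scores.shape
    if n <= q + 1:
        raise ParameterError(f"need N > Q+1 (N={n}, Q={q})")
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    if y_ss <= 0:
        raise DegenerateDataError("score vector is constant")
    xc = scores - scores.mean(axis=0)
    sv = scipy.linalg.svdvals(xc)
    if sv[0] <= 0 or sv[-1] < RANK_TOL * sv[0]:
        raise ConditioningError("reduced score columns are collinear")

    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    u = xc @ beta
    u_norm = float(np.linalg.norm(u))
    y_norm = float(np.sqrt(y_ss))
    if u_norm == 0.0:
        # y exactly orthogonal to the column space: zero canonical correlation
        r = 0.0
        weights_x = beta
        variate_x = u
    else:
        r = float(u @ yc) / (u_norm * y_norm)  # >= 0: u is the OLS projection
        sd_u = u_norm / np.sqrt(n - 1)
        weights_x = beta / sd_u
        variate_x = u / sd_u
    sd_y = y_norm / np.sqrt(n - 1)
    weight_y = 1.0 / sd_y
    variate_y = yc / sd_y
    return CCASolution(
        weights_x=weights_x,
        weight_y=weight_y,
        variate_x=variate_x,
        variate_y=variate_y,
        correlation=min(max(r, 0.0), 1.0),
    )


def backproject(weights_x: np.ndarray, basis: ReducedBasis) -> np.ndarray:
    """Map canonical weights from component space back to voxel space.

    ``voxel_weights = components @ weights_x``; projecting the centered
    feature matrix onto this vector reproduces the canonical variate U.
    """
    weights_x = np.asarray(weights_x, dtype=float).ravel()
    if weights_x.size != basis.q:
        raise ParameterError(
            f"weights length {weights_x.size} != basis dimension {basis.q}"
        )
    return basis.components @ weights_x
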