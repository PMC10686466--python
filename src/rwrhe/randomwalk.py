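"""Network normalization, the bi-random walk, and the seeded restart walk.

Normalization. A similarity matrix S is Laplacian-normalized in two steps:
S'(i,j) = S(i,j)/sqrt(D(i)*D(j)) with D(i) the row sum of S, then each row
of S' is divided by its own sum, making S'' row-stochastic. The binary
association matrix A is normalized by its global sum so all entries sum
to 1.

Bi-random walk. Starting from RT_0 = A', two independent restart
recursions are iterated to a fixed point (elementwise max-abs residual
below tolerance):

    left:   RT_t = alpha * RT_{t-1} @ St'' + (1 - alpha) * A'
    right:  RT_t = alpha * Sr'' @ RT_{t-1} + (1 - alpha) * A'

and the prediction is their average RT = (leftRT + rightRT) / 2. With
restart probability alpha < 1 each recursion is a contraction whose unique
fixed point is the Neumann series (1-alpha) * A' * (I - alpha*St'')^-1
(resp. the left-multiplied analogue); :func:`rwr_closed_form` computes it
directly and serves as the test oracle.

Seeded walk. Disease-target scores come from a random walk with restart
started from a uniform distribution over seed targets:

    P_t = alpha * (St'')^T @ P_{t-1} + (1 - alpha) * P_0.

The transpose keeps the iterate a probability vector (rows of St'' sum
to 1, so columns of its transpose do).
"""

from __future__ import annotations

import logging

import numpy as np

from .config import RunConfig
from .containers import (
    AssociationMatrix,
    NormalizedMatrix,
    ScoreMatrix,
    SimilarityMatrix,
    TargetScoreVector,
)
from .errors import AlignmentError, ConvergenceError, DegenerateInputError

logger = logging.getLogger(__name__)


def laplacian_normalize(S: SimilarityMatrix) -> NormalizedMatrix:
    """Two-step Laplacian normalization yielding a row-stochastic matrix."""
    values = np.asarray(S.values, dtype=float)
    if np.any(values < 0):
        raise ValueError("Laplacian normalization requires a non-negative matrix")
    d = values.sum(axis=1)
    zero = d == 0
    if zero.any():
        logger.warning(
            "%d all-zero rows remain all-zero after normalization (walker stalls)",
            int(zero.sum()),
        )
    safe_d = np.where(zero, 1.0, d)
    s1 = values / np.sqrt(safe_d[:, None] * safe_d[None, :])
    row_sums = s1.sum(axis=1)
    safe_rs = np.where(row_sums == 0, 1.0, row_sums)
    s2 = s1 / safe_rs[:, None]
    return NormalizedMatrix(ids=list(S.ids), values=s2, normalization="laplacian")


def normalize_association(A: AssociationMatrix) -> NormalizedMatrix:
    """Divide the binary association matrix by its global sum."""
    total = A.values.sum()
    if total == 0:
        raise DegenerateInputError("association matrix has no associations")
    return NormalizedMatrix(
        ids=(list(A.row_ids), list(A.col_ids)),
        values=A.values.astype(float) / total,
        normalization="global_sum",
    )


def _iterate(
    step, x0: np.ndarray, tolerance: float, max_iterations: int
) -> tuple[np.ndarray, list[float]]:
    """Fixed-point iteration with elementwise max-abs stopping rule."""
    x = x0
    residuals: list[float] = []
    for _ in range(max_iterations):
        x_next = step(x)
        residual = float(np.abs(x_next - x).max())
        residuals.append(residual)
        x = x_next
        if residual < tolerance:
            return x, residuals
    raise ConvergenceError(
        f"no convergence within {max_iterations} iterations "
        f"(last residual {residuals[-1]:.3e})",
        last_residual=residuals[-1],
    )


def bi_random_walk(
    Sr_norm: NormalizedMatrix,
    St_norm: NormalizedMatrix,
    A_norm: NormalizedMatrix,
    cfg: RunConfig,
) -> ScoreMatrix:
    """Run the left and right restart walks from RT_0 = A' and average them."""
    row_ids, col_ids = A_norm.ids
    if list(Sr_norm.ids) != list(row_ids):
        raise AlignmentError("ingredient similarity index does not match A rows")
    if list(St_norm.ids) != list(col_ids):
        raise AlignmentError("target similarity index does not match A columns")
    a = A_norm.values
    alpha = cfg.alpha
    st = St_norm.values
    sr = Sr_norm.values

    left, left_res = _iterate(
        lambda rt: alpha * (rt @ st) + (1.0 - alpha) * a,
        a, cfg.tolerance, cfg.max_iterations,
    )
    right, right_res = _iterate(
        lambda rt: alpha * (sr @ rt) + (1.0 - alpha) * a,
        a, cfg.tolerance, cfg.max_iterations,
    )
    rt = 0.5 * (left + right)
    return ScoreMatrix(
        row_ids=list(row_ids),
        col_ids=list(col_ids),
        values=rt,
        meta={
            "left_iterations": len(left_res),
            "right_iterations": len(right_res),
            "left_residuals": left_res,
            "right_residuals": right_res,
        },
    )


def seeded_rwr(
    St_norm: NormalizedMatrix, seeds: list[str], cfg: RunConfig
) -> TargetScoreVector:
    """Random walk with restart from a uniform distribution over seeds.

    Iterates P_t = alpha * M^T P_{t-1} + (1-alpha) P_0 with M the
    row-stochastic normalized target similarity; the total probability mass
    stays 1 throughout (asserted).
    """
    ids = list(St_norm.ids)
    if not seeds:
        raise ValueError("seed set is empty")
    index = {t: i for i, t in enumerate(ids)}
    missing = [s for s in seeds if s not in index]
    if missing:
        raise KeyError(f"seed targets not in the target index: {missing}")
    p0 = np.zeros(len(ids))
    p0[[index[s] for s in seeds]] = 1.0 / len(seeds)
    mt = St_norm.values.T
    alpha = cfg.alpha
    p, residuals = _iterate(
        lambda p_: alpha * (mt @ p_) + (1.0 - alpha) * p0,
        p0, cfg.tolerance, cfg.max_iterations,
    )
    total = p.sum()
    assert abs(total - 1.0) < 1e-8, f"probability mass drifted to {total}"
    return TargetScoreVector(
        ids=ids, values=p, meta={"iterations": len(residuals), "residuals": residuals}
    )


def rwr_closed_form(
    M: np.ndarray, p0: np.ndarray, alpha: float
) -> np.ndarray:
    """Exact restart-walk fixed point P = (1-alpha) (I - alpha M)^-1 P_0.

    ``M`` is applied on the left exactly as in the iteration it mirrors
    (pass ``St''.T`` for the seeded walk). Intended for tests and small
    instances; the iterative solvers are the production path.
    """
    n = M.shape[0]
    return (1.0 - alpha) * np.linalg.solve(np.eye(n) - alpha * M, p0)


def bi_walk_closed_form(
    Sr_norm: np.ndarray, St_norm: np.ndarray, A_norm: np.ndarray, alpha: float
) -> np.ndarray:
    """Exact fixed points of both walks by direct linear solves, averaged."""
    nr, nt = A_norm.shape
    left = (1.0 - alpha) * np.linalg.solve(
        (np.eye(nt) - alpha * St_norm).T, A_norm.T
    ).T
    right = (1.0 - alpha) * np.linalg.solve(np.eye(nr) - alpha * Sr_norm, A_norm)
    return 0.5 * (left + right)
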