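"""Forward and backward first-order vector autoregressive fits.

The forward model is x_t = A_f x_{t-1} + e_t; the backward model regresses
each state on its successor, x_t = A_b x_{t+1} + e_t.  Both are estimated by
ordinary least squares over transition pairs pooled across subject blocks,
excluding the pairs that straddle a block junction.  No intercept is fitted:
inputs are expected to be z-scored per subject.

The solver is QR-based rather than normal-equation inversion; a
rank-deficient predictor matrix raises instead of falling back to a
pseudo-inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data_model import CohortSeries

__all__ = ["VARFit", "fit_var1", "pooled_ols"]

DIRECTIONS = ("forward", "backward")


@dataclass
class VARFit:
    """OLS fit of one direction: coefficients plus per-pair residuals.

    ``residuals`` has shape (n_regions, used_pairs), columns ordered by block
    then by time within block, matching the retained transition pairs 1:1.
    """

    direction: str
    A: np.ndarray
    residuals: np.ndarray
    used_pairs: int

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]


def pooled_ols(predictors: np.ndarray, responses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve responses ~ A @ predictors by QR least squares.

    Both arguments are (n_regions, n_pairs).  Returns (A, residuals) with
    residuals = responses - A @ predictors.  Raises ``LinAlgError`` when the
    predictor matrix is rank deficient.
    """
    n_regions, n_pairs = predictors.shape
    if n_pairs <= n_regions:
        raise ValueError(
            f"underdetermined system: {n_pairs} transition pairs for "
            f"{n_regions} regions"
        )
    P = predictors.T  # n_pairs x R
    Q, R = np.linalg.qr(P)
    diag = np.abs(np.diag(R))
    if diag.min() <= diag.max() * n_pairs * np.finfo(float).eps:
        raise np.linalg.LinAlgError(
            "rank-deficient predictor matrix; refusing pseudo-inverse fallback"
        )
    QtY = Q.T @ responses.T
    coef = scipy.linalg.solve_triangular(R, QtY)  # R x R, rows=predictor regions
    residuals = (responses.T - Q @ QtY).T
    return coef.T, residuals


def _transition_pairs(
    c: CohortSeries, direction: str
) -> tuple[np.ndarray, np.ndarray]:
    pred_slices: list[np.ndarray] = []
    resp_slices: list[np.ndarray] = []
    for a, b in c.blocks():
        if b - a < 2:  # a truncation stub contributes no pairs
            continue
        block = c.data[:, a:b]
        if direction == "forward":
            pred_slices.append(block[:, :-1])
            resp_slices.append(block[:, 1:])
        else:
            pred_slices.append(block[:, 1:])
            resp_slices.append(block[:, :-1])
    if not pred_slices:
        raise ValueError("no usable transition pairs (all blocks shorter than 2)")
    return np.concatenate(pred_slices, axis=1), np.concatenate(resp_slices, axis=1)


def fit_var1(
    c: CohortSeries, direction: str = "forward", sample_limit: int | None = None
) -> VARFit:
    """Fit a VAR(1) in the given direction on pooled within-block pairs.

    ``sample_limit`` truncates to the first that many concatenated time
    points (columns) before pair construction; a subject block cut mid-way is
    kept as a partial block.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if sample_limit is not None:
        c = c.truncate(sample_limit)
    predictors, responses = _transition_pairs(c, direction)
    A, residuals = pooled_ols(predictors, responses)
    return VARFit(direction, A, residuals, predictors.shape[1])
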