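"""Small closed-form least-squares helpers.

These back the mediation and MR estimators (where the formulas themselves
are the point) and the Monte-Carlo calibration loops, where a full
statsmodels fit per replicate would be needlessly slow. Association fits
that users see go through statsmodels instead.
"""
from __future__ import annotations

import numpy as np

from .errors import ModelError

__all__ = ["add_intercept", "ols"]


def add_intercept(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    return np.column_stack([np.ones(X.shape[0]), X])


def ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Ordinary least squares.

    Parameters
    ----------
    X : (n, k) design matrix, intercept column included by the caller.
    y : (n,) response.

    Returns
    -------
    beta, se, residuals, df_resid — the usual OLS quantities with the
    unbiased residual-variance estimate (n - k denominator).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ModelError(f"need more observations ({n}) than parameters ({k})")
    if np.linalg.matrix_rank(X) < k:
        raise ModelError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta, se, resid, df
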