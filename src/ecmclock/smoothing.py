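"""Local polynomial (LOESS) regression with tricube weights.

Local *quadratic* regression (degree 2, span 0.75 — the defaults of the
classic LOESS implementation) smoothed over a shared predictor.  Because
every protein in a cohort is smoothed against the same ages, the
weighted normal equations at each evaluation point are shared across
response columns, so a whole proteome is smoothed in one pass per grid
point.
"""

from __future__ import annotations

import numpy as np


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_matrix(
    x: np.ndarray,
    Y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """LOESS-smooth each column of ``Y`` against ``x`` at ``x_eval``.

    Parameters
    ----------
    x : (n,) predictor (e.g., ages).
    Y : (n, p) responses sharing the predictor.
    x_eval : (m,) evaluation grid.
    span : fraction of points in each local neighbourhood.
    degree : local polynomial degree (2 = local quadratic).

    Returns an (m, p) matrix of fitted values.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = x.size
    if Y.shape[0] != n:
        raise ValueError("Y rows must match x")
    q = int(np.floor(span * n + 1e-9))
    q = max(q, degree + 1)
    q = min(q, n)
    if np.unique(x).size < degree + 1:
        raise ValueError(f"need at least {degree + 1} distinct x values")

    out = np.empty((x_eval.size, Y.shape[1]))
    for i, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(x - x0)
        dq = np.sort(d)[q - 1]
        if dq == 0:
            # All nearest neighbours coincide with x0: average them.
            mask = d == 0
            out[i] = Y[mask].mean(axis=0)
            continue
        w = _tricube(d / dq)
        dx = x - x0
        A = np.vander(dx, degree + 1, increasing=True)  # [1, dx, dx^2, ...]
        Aw = A * w[:, None]
        G = A.T @ Aw
        B = Aw.T @ Y
        coef = np.linalg.solve(G, B)
        out[i] = coef[0]  # value at dx = 0
    return out


def loess(x, y, x_eval, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Convenience single-response LOESS (see :func:`loess_matrix`)."""
    return loess_matrix(np.asarray(x), np.asarray(y), np.asarray(x_eval), span, degree)[:, 0]
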