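"""Natural cubic spline basis used by the pseudotime gene test and curve smoothing.

The basis follows the standard truncated-power construction with linearity
constraints beyond the boundary knots.  ``df`` non-intercept columns are
produced from ``df + 1`` knots placed at quantiles of the input.
"""

from __future__ import annotations

import numpy as np


def _truncated_cubed(x: np.ndarray, knot: float) -> np.ndarray:
    return np.clip(x - knot, 0.0, None) ** 3


def natural_spline_basis(
    x: np.ndarray, df: int = 3, knots: np.ndarray | None = None
) -> np.ndarray:
    """Natural cubic spline basis matrix (no intercept column).

    Parameters
    ----------
    x
        1-D array of evaluation points.
    df
        Number of basis columns; ``df + 1`` knots are used.
    knots
        Explicit knot vector (sorted, length ``df + 1``).  When omitted, knots
        sit at equally spaced quantiles of ``x`` including the extremes.

    Returns
    -------
    ``(len(x), df)`` array: a linear column plus ``df - 1`` curvature terms.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if knots is None:
        qs = np.linspace(0.0, 1.0, df + 1)
        knots = np.quantile(x, qs)
    knots = np.asarray(knots, dtype=float)
    if np.unique(knots).size < knots.size:
        # degenerate input (e.g. many ties): fall back to spreading knots
        knots = np.linspace(knots[0], knots[-1] + 1e-9, knots.size)
    if df == 1:
        return x[:, None]

    xi_last = knots[-1]
    xi_penult = knots[-2]

    def d(k: int) -> np.ndarray:
        return (_truncated_cubed(x, knots[k]) - _truncated_cubed(x, xi_last)) / (
            xi_last - knots[k]
        )

    d_penult = (_truncated_cubed(x, xi_penult) - _truncated_cubed(x, xi_last)) / (
        xi_last - xi_penult
    )
    cols = [x]
    for k in range(knots.size - 2):
        cols.append(d(k) - d_penult)
    return np.column_stack(cols[:df])


def spline_design(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Design matrix ``[1 | natural-spline basis]`` for least-squares fits."""
    basis = natural_spline_basis(x, df=df)
    return np.column_stack([np.ones(len(basis)), basis])


def fit_smooth_curves(
    t: np.ndarray, values: np.ndarray, grid: np.ndarray, df: int = 3
) -> np.ndarray:
    """Least-squares natural-spline fit of each row of ``values`` against ``t``.

    ``values`` is features x cells; the fitted curves are evaluated on ``grid``
    and returned as features x len(grid).
    """
    t = np.asarray(t, dtype=float)
    qs = np.linspace(0.0, 1.0, df + 1)
    knots = np.quantile(t, qs)
    if np.unique(knots).size < knots.size:
        knots = np.linspace(t.min(), t.max() + 1e-9, df + 1)
    X = np.column_stack([np.ones(t.size), natural_spline_basis(t, df=df, knots=knots)])
    G = np.column_stack(
        [np.ones(grid.size), natural_spline_basis(np.asarray(grid, float), df=df, knots=knots)]
    )
    coef, *_ = np.linalg.lstsq(X, np.asarray(values, dtype=float).T, rcond=None)
    return (G @ coef).T
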