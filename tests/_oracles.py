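"""Independent oracles for the REML solver tests.

These evaluate the restricted log-likelihood by direct dense linear
algebra on the marginal covariance V (inversion + slogdet), deliberately
avoiding the mixed-model-equations path used by the implementation, and
locate its maximiser by a zooming grid search.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.linalg import inv, slogdet, solve


def neg2_reml_direct(
    y: np.ndarray,
    acc: np.ndarray,
    yr: np.ndarray,
    n_acc: int,
    n_yr: int,
    sigma2_year: float,
    sigma2_e_by_year: np.ndarray,
    sigma2_G: float | None = None,
) -> float:
    """-2 x restricted log-likelihood (up to constant) via dense V."""
    n = len(y)
    Zg = np.zeros((n, n_acc))
    Zg[np.arange(n), acc] = 1.0
    Za = np.zeros((n, n_yr))
    Za[np.arange(n), yr] = 1.0
    V = sigma2_year * Za @ Za.T + np.diag(sigma2_e_by_year[yr])
    if sigma2_G is None:
        X = Zg
    else:
        V = V + sigma2_G * Zg @ Zg.T
        X = np.ones((n, 1))
    Vi = inv(V)
    XtViX = X.T @ Vi @ X
    XtViy = X.T @ Vi @ y
    beta = solve(XtViX, XtViy)
    yPy = float(y @ Vi @ y - XtViy @ beta)
    return float(slogdet(V)[1] + slogdet(XtViX)[1] + yPy)


def grid_search_reml(
    y: np.ndarray,
    acc: np.ndarray,
    yr: np.ndarray,
    n_acc: int,
    n_yr: int,
    lo: float,
    hi: float,
    n_points: int = 15,
    n_zooms: int = 7,
) -> tuple[float, float, float]:
    """Zooming 3-D grid search for (sigma2_G, sigma2_year, sigma2_e), homoscedastic.

    Starts from a log-spaced grid on [lo, hi]^3 and repeatedly refines
    around the incumbent; the final spacing is far below 1e-3 relative.
    """
    bounds = [(lo, hi)] * 3

    def objective(g, a, e):
        return neg2_reml_direct(
            y, acc, yr, n_acc, n_yr, a, np.full(n_yr, e), sigma2_G=g
        )

    best = None
    for _ in range(n_zooms):
        axes = [np.geomspace(b[0], b[1], n_points) for b in bounds]
        vals = {}
        for g, a, e in itertools.product(*axes):
            vals[(g, a, e)] = objective(g, a, e)
        best = min(vals, key=vals.get)
        new_bounds = []
        for axis, b in zip(axes, best):
            i = int(np.argmin(np.abs(axis - b)))
            lo_i = axis[max(i - 1, 0)]
            hi_i = axis[min(i + 1, len(axis) - 1)]
            new_bounds.append((lo_i, hi_i))
        bounds = new_bounds
    return best


def anova_ems_estimates(y_table: np.ndarray) -> tuple[float, float, float]:
    """Closed-form expected-mean-square estimators for a balanced two-way
    layout with one observation per cell (genotype x year, both random).

    Returns (sigma2_G, sigma2_year, sigma2_e); valid when non-negative.
    """
    p, q = y_table.shape
    grand = y_table.mean()
    row_means = y_table.mean(axis=1)
    col_means = y_table.mean(axis=0)
    msa = q * ((row_means - grand) ** 2).sum() / (p - 1)
    msb = p * ((col_means - grand) ** 2).sum() / (q - 1)
    resid = y_table - row_means[:, None] - col_means[None, :] + grand
    mse = (resid**2).sum() / ((p - 1) * (q - 1))
    return (msa - mse) / q, (msb - mse) / p, mse
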