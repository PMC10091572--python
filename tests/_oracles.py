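"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (pure-python
elimination, textbook formulas) so it shares no code path with the package
implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def gauss_solve(A, b):
    """Solve A x = b by Gaussian elimination with partial pivoting.

    Pure python on lists of floats; independent of numpy.linalg.
    """
    n = len(A)
    M = [[float(v) for v in row] + [float(b[i])] for i, row in enumerate(A)]
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(M[r][col]))
        if abs(M[piv][col]) < 1e-14:
            raise ValueError("singular system")
        M[col], M[piv] = M[piv], M[col]
        for r in range(col + 1, n):
            f = M[r][col] / M[col][col]
            for c in range(col, n + 1):
                M[r][c] -= f * M[col][c]
    x = [0.0] * n
    for r in range(n - 1, -1, -1):
        s = M[r][n] - sum(M[r][c] * x[c] for c in range(r + 1, n))
        x[r] = s / M[r][r]
    return x


def ols_via_elimination(X, y):
    """OLS coefficients (intercept first) by forming and solving the
    normal equations with :func:`gauss_solve`."""
    X = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    A = (X.T @ X).tolist()
    b = (X.T @ np.asarray(y, dtype=float)).tolist()
    return np.array(gauss_solve(A, b))


def r_squared_via_lstsq(X, y):
    """Coefficient of determination computed directly from residuals."""
    X = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    y = np.asarray(y, dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))


def hoyt_alpha(mat):
    """Reliability via the two-way (persons x items) ANOVA decomposition:
    alpha = 1 - MS_error / MS_persons (Hoyt's method)."""
    mat = np.asarray(mat, dtype=float)
    n, k = mat.shape
    grand = mat.mean()
    ss_total = ((mat - grand) ** 2).sum()
    ss_rows = k * ((mat.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((mat.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return 1.0 - ms_err / ms_rows


def closed_form_effects(r_xm, r_xy, r_my, sd_x, sd_m, sd_y):
    """Mediation decomposition from the three-variable moment system via
    the partial-regression closed forms (no data, no least squares)."""
    a = r_xm * sd_m / sd_x
    b = (r_my - r_xy * r_xm) / (1.0 - r_xm**2) * sd_y / sd_m
    c = r_xy * sd_y / sd_x
    indirect = a * b
    return {
        "a": a,
        "b": b,
        "total": c,
        "indirect": indirect,
        "direct": c - indirect,
        "proportion": 100.0 * indirect / c,
    }


def reference_bc_bounds(boot, point, level=0.95, method="bias_corrected"):
    """Percentile / bias-corrected percentile bounds, re-derived from the
    definition: z0 is the probit of the fraction of bootstrap draws below
    the point estimate (ties counting half), bounds sit at the
    Phi(2 z0 + z_{alpha/2}) and Phi(2 z0 + z_{1-alpha/2}) empirical
    quantiles (linear interpolation)."""
    boot = np.asarray(boot, dtype=float)
    bsz = boot.size
    alpha = 1.0 - level
    if method == "percentile":
        qs = [alpha / 2.0, 1.0 - alpha / 2.0]
    else:
        p_below = (np.sum(boot < point) + 0.5 * np.sum(boot == point)) / bsz
        p_below = min(max(p_below, 1.0 / (2 * bsz)), 1.0 - 1.0 / (2 * bsz))
        z0 = norm.ppf(p_below)
        qs = [
            norm.cdf(2.0 * z0 + norm.ppf(alpha / 2.0)),
            norm.cdf(2.0 * z0 + norm.ppf(1.0 - alpha / 2.0)),
        ]
    return tuple(np.quantile(boot, qs, method="linear"))


def count_pairs_u(x, y):
    """Mann-Whitney U for sample x against y by exhaustive pair counting."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u
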