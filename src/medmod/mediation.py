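"""Simple mediation X -> M -> Y with bootstrap inference.

The model is the classic product-of-coefficients decomposition estimated by
three OLS regressions sharing one covariate set:

    M ~ X + covariates            -> a  (first-stage path)
    Y ~ X + M + covariates        -> b  (second-stage path), c' (direct)
    Y ~ X + covariates            -> c  (total effect)

With identical covariates in all three equations the OLS algebra guarantees
c = c' + a*b exactly, so the indirect effect a*b is also c - c'.  The
proportion mediated is 100 * a*b / c, reported only when |c| clears a small
floor.

Inference on the effects uses the nonparametric bootstrap: whole rows are
resampled with replacement (size n), all three regressions are refit on each
resample, and confidence bounds are read from the empirical distribution of
each effect.  Two interval flavours are produced:

* percentile — bounds at the (alpha/2, 1-alpha/2) empirical quantiles;
* bias-corrected percentile — quantile positions shifted by the probit of
  the fraction of bootstrap estimates below the point estimate,
  z0 = Phi^-1(#{theta* < theta_hat}/B), with bounds at the
  Phi(2*z0 + z_{alpha/2}) and Phi(2*z0 + z_{1-alpha/2}) quantiles.
  Estimates exactly tied with the point estimate count as half below, which
  keeps z0 finite under heavy ties; with z0 = 0 the bias-corrected bounds
  reduce to the percentile bounds exactly.

Empirical quantiles use the inclusive linear-interpolation convention
(numpy's default), which matters when bounds are read at two decimals.

The bootstrap loop solves the normal equations for all resamples in batched
linear algebra rather than refitting a model object per resample; a test
pins the batched solver to the reference OLS output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats_core import ols_fit

__all__ = [
    "MediationResult",
    "BootstrapInterval",
    "fit_mediation",
    "bootstrap_effects",
    "bootstrap_indices",
    "batched_ols_coefs",
    "bc_interval",
]

PROPORTION_FLOOR = 1e-8
_METHODS = ("percentile", "bias_corrected")


# ---------------------------------------------------------------------------
# Bootstrap engine (shared with the moderated-mediation module)
# ---------------------------------------------------------------------------


def bootstrap_indices(rng: np.random.Generator, n: int, n_boot: int) -> np.ndarray:
    """The resample index stream: ``n_boot`` rows of n draws with replacement.

    Drawn in a single ``rng.integers(0, n, size=(n_boot, n))`` call before
    any other use of ``rng``, so an external re-implementation seeded the
    same way sees the identical stream.
    """
    return rng.integers(0, n, size=(n_boot, n))


def batched_ols_coefs(
    X: np.ndarray,
    ys: np.ndarray,
    idx: np.ndarray,
    rng: np.random.Generator | None = None,
    chunk: int = 512,
) -> tuple[np.ndarray, int]:
    """OLS coefficients for every resample, via batched normal equations.

    ``X`` is the (n, p) design (intercept included), ``ys`` an (n, q) stack
    of outcome vectors fitted against the same design, ``idx`` the
    (n_boot, n) resample indices.  Returns (n_boot, p, q) coefficients and
    the number of degenerate (rank-deficient) resamples that had to be
    redrawn; redraws consume ``rng`` and are replaced in ``idx`` in place.
    """
    n_boot = idx.shape[0]
    p, q = X.shape[1], ys.shape[1]
    coefs = np.empty((n_boot, p, q))
    redraws = 0
    for start in range(0, n_boot, chunk):
        sl = slice(start, min(start + chunk, n_boot))
        rows = idx[sl]
        Xb = X[rows]
        XtX = np.einsum("bni,bnj->bij", Xb, Xb)
        Xty = np.einsum("bni,bnq->biq", Xb, ys[rows])
        try:
            sol = np.linalg.solve(XtX, Xty)
            if not np.all(np.isfinite(sol)):
                raise np.linalg.LinAlgError
            coefs[sl] = sol
        except np.linalg.LinAlgError:
            for j in range(rows.shape[0]):
                while True:
                    Xj = X[rows[j]]
                    try:
                        sol_j = np.linalg.solve(Xj.T @ Xj, Xj.T @ ys[rows[j]])
                        if not np.all(np.isfinite(sol_j)):
                            raise np.linalg.LinAlgError
                        coefs[start + j] = sol_j
                        break
                    except np.linalg.LinAlgError:
                        if rng is None:
                            raise ValueError(
                                "degenerate bootstrap resample and no rng to redraw from"
                            ) from None
                        rows[j] = rng.integers(0, X.shape[0], size=X.shape[0])
                        redraws += 1
            idx[sl] = rows
    return coefs, redraws


@dataclass(frozen=True)
class BootstrapInterval:
    """One bootstrap confidence interval for one effect."""

    method: str
    level: float
    lower: float
    upper: float
    n_boot: int
    seed: int | None
    z0: float

    @property
    def excludes_zero(self) -> bool:
        return self.lower > 0.0 or self.upper < 0.0


def bc_interval(
    boot: np.ndarray,
    point: float,
    level: float = 0.95,
    method: str = "bias_corrected",
    n_boot: int | None = None,
    seed: int | None = None,
) -> BootstrapInterval:
    """Percentile or bias-corrected percentile interval from bootstrap draws."""
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    boot = np.asarray(boot, dtype=float)
    b = boot.size
    alpha = 1.0 - level
    prop_below = (np.sum(boot < point) + 0.5 * np.sum(boot == point)) / b
    prop_below = np.clip(prop_below, 1.0 / (2 * b), 1.0 - 1.0 / (2 * b))
    z0 = float(sps.norm.ppf(prop_below))
    if method == "percentile":
        qs = np.array([alpha / 2.0, 1.0 - alpha / 2.0])
    else:
        qs = sps.norm.cdf(2.0 * z0 + sps.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0]))
    lower, upper = np.quantile(boot, qs, method="linear")
    return BootstrapInterval(
        method=method,
        level=level,
        lower=float(lower),
        upper=float(upper),
        n_boot=n_boot if n_boot is not None else b,
        seed=seed,
        z0=z0,
    )


# ---------------------------------------------------------------------------
# Mediation fits
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    """Paths, effect decomposition and (optionally) bootstrap inference.

    ``intervals`` maps effect name ("total" | "indirect" | "direct") to a
    dict with both interval flavours; ``z`` is point estimate / bootstrap SE
    (or the delta-method Sobel SE for the indirect effect when requested).
    """

    x: str
    m: str
    y: str
    covariates: tuple[str, ...]
    n: int
    a: float
    a_se: float
    b: float
    b_se: float
    c: float
    c_se: float
    c_prime: float
    c_prime_se: float
    indirect: float
    proportion_mediated: float | None
    method: str | None = None
    n_boot: int | None = None
    seed: int | None = None
    redraws: int = 0
    boot_se: dict[str, float] = field(default_factory=dict)
    z: dict[str, float] = field(default_factory=dict)
    intervals: dict[str, dict[str, BootstrapInterval]] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.c

    @property
    def direct(self) -> float:
        return self.c_prime

    def to_frame(self) -> pd.DataFrame:
        """Effect-decomposition table: point, bootstrap SE, Z, both CIs."""
        rows = []
        for effect in ("total", "indirect", "direct"):
            point = getattr(self, effect)
            row = {"effect": effect, "point": point}
            row["boot_se"] = self.boot_se.get(effect, np.nan)
            row["z"] = self.z.get(effect, np.nan)
            for method in _METHODS:
                iv = self.intervals.get(effect, {}).get(method)
                key = "bc" if method == "bias_corrected" else "pct"
                row[f"{key}_lower"] = iv.lower if iv else np.nan
                row[f"{key}_upper"] = iv.upper if iv else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def _design_columns(x: str, covariates: Sequence[str], with_m: str | None = None):
    cols = [x] + ([with_m] if with_m else []) + list(covariates)
    return cols


def fit_mediation(
    data: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: Sequence[str] = (),
) -> MediationResult:
    """Point estimates of the a/b/c/c' paths and the effect decomposition."""
    names = [x, m, y, *covariates]
    if len(set(names)) != len(names):
        raise ValueError("x, m, y and covariates must be distinct columns")
    covariates = tuple(covariates)
    fit_m = ols_fit(data, m, _design_columns(x, covariates))
    fit_y = ols_fit(data, y, _design_columns(x, covariates, with_m=m))
    fit_c = ols_fit(data, y, _design_columns(x, covariates))
    a, b = float(fit_m.params[x]), float(fit_y.params[m])
    c, c_prime = float(fit_c.params[x]), float(fit_y.params[x])
    indirect = a * b
    proportion = 100.0 * indirect / c if abs(c) >= PROPORTION_FLOOR else None
    return MediationResult(
        x=x,
        m=m,
        y=y,
        covariates=covariates,
        n=len(data),
        a=a,
        a_se=float(fit_m.bse[x]),
        b=b,
        b_se=float(fit_y.bse[m]),
        c=c,
        c_se=float(fit_c.bse[x]),
        c_prime=c_prime,
        c_prime_se=float(fit_y.bse[x]),
        indirect=indirect,
        proportion_mediated=proportion,
    )


def bootstrap_effects(
    data: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: Sequence[str] = (),
    n_boot: int = 5000,
    method: str = "bias_corrected",
    level: float = 0.95,
    seed: int = 0,
    z_method: str = "bootstrap",
) -> MediationResult:
    """Mediation with bootstrap confidence intervals for all three effects.

    Rows are resampled whole, with replacement, at the original n; all three
    regressions are refit per resample so the decomposition identity holds
    on every draw.  Both percentile and bias-corrected intervals are stored;
    ``method`` marks the primary flavour.  ``z_method='delta'`` swaps the
    indirect effect's Z denominator for the Sobel first-order SE
    sqrt(a^2 se_b^2 + b^2 se_a^2).
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if z_method not in ("bootstrap", "delta"):
        raise ValueError("z_method must be 'bootstrap' or 'delta'")
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    result = fit_mediation(data, x, m, y, covariates)
    n = len(data)
    rng = np.random.default_rng(seed)
    idx = bootstrap_indices(rng, n, n_boot)

    ones = np.ones(n)
    xv = data[x].astype(float).to_numpy()
    mv = data[m].astype(float).to_numpy()
    yv = data[y].astype(float).to_numpy()
    cov = data[list(covariates)].astype(float).to_numpy() if covariates else np.empty((n, 0))
    X_base = np.column_stack([ones, xv, cov])       # for M ~ X and Y ~ X
    X_full = np.column_stack([ones, xv, mv, cov])   # for Y ~ X + M

    coef_base, r1 = batched_ols_coefs(X_base, np.column_stack([mv, yv]), idx, rng)
    coef_full, r2 = batched_ols_coefs(X_full, yv[:, None], idx, rng)
    a_star = coef_base[:, 1, 0]
    c_star = coef_base[:, 1, 1]
    c_prime_star = coef_full[:, 1, 0]
    b_star = coef_full[:, 2, 0]
    draws = {
        "total": c_star,
        "indirect": a_star * b_star,
        "direct": c_prime_star,
    }
    result.method = method
    result.n_boot = n_boot
    result.seed = seed
    result.redraws = r1 + r2
    for effect, boot in draws.items():
        point = getattr(result, effect)
        result.boot_se[effect] = float(boot.std(ddof=1))
        result.intervals[effect] = {
            meth: bc_interval(boot, point, level=level, method=meth, seed=seed)
            for meth in _METHODS
        }
        se = result.boot_se[effect]
        if effect == "indirect" and z_method == "delta":
            se = float(np.sqrt(result.a**2 * result.b_se**2 + result.b**2 * result.a_se**2))
        result.z[effect] = point / se if se > 0 else np.nan
    return result
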