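"""Synthetic participant-level data with known moment and path structure.

The analyses in this package were designed around a large cross-sectional
mental-health survey (n = 6057 Chinese adults) whose raw records are not
public.  What *is* public are the scale-level summary statistics: means,
standard deviations and the pairwise Pearson correlations between childhood
trauma (CTQ total, ``ct``), self-esteem (Rosenberg SES, ``se``), cognitive
reappraisal and expressive suppression (ERQ subscales, ``cr``/``es``),
depression symptoms (PHQ-9, ``phq9``) and anxiety symptoms (GAD-7, ``gad7``),
plus a handful of demographic facts (39.99% women; age median 34, IQR 30-40;
age-depression r = -0.13, age-anxiety r = -0.10).

This module turns those published moments into data three different ways:

* :func:`generate_scale_level` draws multivariate-normal scale totals whose
  population moments equal a :class:`MomentSpec` (optionally forcing the
  *sample* moments to match exactly), with age and sex appended from a
  :class:`DemographicSpec`;
* :func:`generate_item_level` draws Likert item batteries with a
  compound-symmetric latent correlation, so internal-consistency targets
  (Cronbach's alpha) can be hit by construction;
* :func:`generate_structural` draws data from an explicit moderated-mediation
  path model with known coefficients, for parameter-recovery and calibration
  studies.

Printed correlation matrices are rounded to two decimals and, once augmented
with extra variables, need not be positive definite;
:func:`repair_correlation_matrix` restores positive definiteness by
eigenvalue clipping with renormalization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MomentSpec",
    "ItemBatterySpec",
    "StructuralSpec",
    "DemographicSpec",
    "CorrelationRepair",
    "repair_correlation_matrix",
    "study_moment_spec",
    "study_demographics",
    "generate_scale_level",
    "generate_item_level",
    "generate_structural",
    "STUDY_N",
]

# ---------------------------------------------------------------------------
# Study constants: the published sample size, moments and demographics
# ---------------------------------------------------------------------------

STUDY_N = 6057

_SCALE_VARS = ("ct", "se", "cr", "es", "phq9", "gad7")
_SCALE_MEANS = (38.46, 31.09, 26.77, 14.31, 4.194, 3.12)
_SCALE_SDS = (11.67, 5.49, 7.53, 4.82, 4.90, 4.05)

# Lower triangle of the published correlation matrix, keyed by variable pair.
_SCALE_CORR = {
    ("ct", "se"): -0.41,
    ("ct", "cr"): -0.31,
    ("ct", "es"): -0.03,
    ("ct", "phq9"): 0.31,
    ("ct", "gad7"): 0.28,
    ("se", "cr"): 0.28,
    ("se", "es"): -0.05,
    ("se", "phq9"): -0.35,
    ("se", "gad7"): -0.30,
    ("cr", "es"): 0.42,
    ("cr", "phq9"): -0.05,
    ("cr", "gad7"): -0.05,
    ("es", "phq9"): 0.13,
    ("es", "gad7"): 0.09,
    ("phq9", "gad7"): 0.80,
}


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MomentSpec:
    """Named variables with target means, SDs and a correlation matrix.

    This is the generator's contract: :func:`generate_scale_level` promises
    that sample moments converge to these values as n grows.
    """

    variables: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    corr: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        object.__setattr__(self, "corr", np.asarray(self.corr, dtype=float))
        k = len(self.variables)
        if len(set(self.variables)) != k:
            raise ValueError("variable names must be unique")
        if self.means.shape != (k,) or self.sds.shape != (k,):
            raise ValueError("means and sds must each have one entry per variable")
        if self.corr.shape != (k, k):
            raise ValueError("corr must be a square matrix matching the variables")
        if np.any(self.sds <= 0):
            raise ValueError("sds must be strictly positive")
        _check_correlation_matrix(self.corr)

    @property
    def k(self) -> int:
        return len(self.variables)

    def covariance(self) -> np.ndarray:
        """Target covariance matrix implied by sds and corr."""
        return self.corr * np.outer(self.sds, self.sds)

    def index(self, name: str) -> int:
        return self.variables.index(name)


@dataclass(frozen=True)
class ItemBatterySpec:
    """A Likert item battery with a compound-symmetric latent correlation.

    Under compound symmetry (equal variances, one common inter-item
    correlation ``rho``) Cronbach's alpha of the summed scale has the closed
    form ``alpha = k*rho / (1 + (k-1)*rho)``; :attr:`implied_alpha` exposes
    it.  Discretizing the latent scores to Likert categories attenuates the
    realized alpha slightly; ``rho_inflation`` lets callers compensate by
    raising the latent correlation (off by default).
    """

    n_items: int
    inter_item_corr: float
    likert_min: int = 1
    likert_max: int = 5
    thresholds: tuple[float, ...] | None = None
    rho_inflation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_items < 2:
            raise ValueError("n_items must be at least 2")
        if not 0.0 <= self.inter_item_corr < 1.0:
            raise ValueError("inter_item_corr must lie in [0, 1)")
        if self.likert_min >= self.likert_max:
            raise ValueError("likert_min must be below likert_max")
        rho = self.inter_item_corr + self.rho_inflation
        if not 0.0 <= rho < 1.0:
            raise ValueError("inflated latent correlation must lie in [0, 1)")
        if self.thresholds is not None:
            t = np.asarray(self.thresholds, dtype=float)
            if t.size != self.n_categories - 1:
                raise ValueError(
                    "need likert_max - likert_min thresholds, got "
                    f"{t.size} for {self.n_categories} categories"
                )
            if not np.all(np.isfinite(t)):
                raise ValueError("thresholds must be finite (latent support is the real line)")
            if np.any(np.diff(t) <= 0):
                raise ValueError("thresholds must be strictly increasing")
            object.__setattr__(self, "thresholds", tuple(float(x) for x in t))

    @property
    def n_categories(self) -> int:
        return self.likert_max - self.likert_min + 1

    @property
    def implied_alpha(self) -> float:
        """Cronbach's alpha of the continuous latent battery (closed form)."""
        k, rho = self.n_items, self.inter_item_corr
        return k * rho / (1.0 + (k - 1) * rho)

    def effective_thresholds(self) -> np.ndarray:
        """Thresholds in latent (standard-normal) units; equal-probability default."""
        if self.thresholds is not None:
            return np.asarray(self.thresholds, dtype=float)
        probs = np.arange(1, self.n_categories) / self.n_categories
        return stats.norm.ppf(probs)


@dataclass(frozen=True)
class StructuralSpec:
    """Path coefficients of a two-stage moderated-mediation generating model.

    The mediator and outcome are generated as

        m = a*x + a_w*(x*w) + w_to_m*w + e_m,   e_m ~ N(0, sd_m^2)
        y = c_prime*x + b*m + b_w*(m*w) + w_to_y*w + e_y,   e_y ~ N(0, sd_y^2)

    with x ~ N(0, x_sd^2) and w ~ N(0, w_sd^2) independent.  With
    a_w = b_w = 0 this reduces to simple mediation; the indirect effect of x
    on y is then a*b and the total effect c_prime + a*b.
    """

    a: float
    b: float
    c_prime: float
    a_w: float = 0.0
    b_w: float = 0.0
    w_to_m: float = 0.0
    w_to_y: float = 0.0
    sd_m: float = 1.0
    sd_y: float = 1.0
    x_sd: float = 1.0
    w_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sd_m", "sd_y", "x_sd", "w_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def indirect(self) -> float:
        return self.a * self.b

    def implied_moment_spec(self) -> MomentSpec:
        """Analytic moments of (x, w, m, y); requires zero interactions.

        Used to check that this generator and the moment-matching generator
        agree on the covariance structure when the model is linear.
        """
        if self.a_w != 0.0 or self.b_w != 0.0:
            raise ValueError("implied moments are only available with zero interactions")
        vx, vw = self.x_sd**2, self.w_sd**2
        a, b, cp, gm, gy = self.a, self.b, self.c_prime, self.w_to_m, self.w_to_y
        vm = a**2 * vx + gm**2 * vw + self.sd_m**2
        cov_xm = a * vx
        cov_wm = gm * vw
        cov_xy = cp * vx + b * cov_xm
        cov_wy = b * cov_wm + gy * vw
        cov_my = cp * cov_xm + b * vm + gy * cov_wm
        vy = cp * cov_xy + b * cov_my + gy * cov_wy + self.sd_y**2
        cov = np.array(
            [
                [vx, 0.0, cov_xm, cov_xy],
                [0.0, vw, cov_wm, cov_wy],
                [cov_xm, cov_wm, vm, cov_my],
                [cov_xy, cov_wy, cov_my, vy],
            ]
        )
        sds = np.sqrt(np.diag(cov))
        corr = cov / np.outer(sds, sds)
        np.fill_diagonal(corr, 1.0)
        return MomentSpec(("x", "w", "m", "y"), np.zeros(4), sds, corr)


@dataclass(frozen=True)
class DemographicSpec:
    """Sample size, sex split and the age marginal/correlation targets.

    Only age quantiles are published (median 34, IQR 30-40), so the age
    marginal is a monotone piecewise-linear quantile transform of a standard
    normal pinned at those quantiles and truncated at ``age_min``/``age_max``.
    ``age_corr`` maps scale names to target Pearson correlations with age
    (variables not listed are uncorrelated with age).  ``sex_mode='quota'``
    reproduces the published 2422/3635 female/male split exactly at n = 6057;
    ``'bernoulli'`` samples sex instead.
    """

    n: int = STUDY_N
    female_proportion: float = 2422 / 6057
    age_median: float = 34.0
    age_iqr: tuple[float, float] = (30.0, 40.0)
    age_min: float = 18.0
    age_max: float = 70.0
    age_corr: Mapping[str, float] = field(
        default_factory=lambda: {"phq9": -0.13, "gad7": -0.10}
    )
    sex_mode: str = "quota"

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 <= self.female_proportion <= 1.0:
            raise ValueError("female_proportion must lie in [0, 1]")
        lo, hi = self.age_iqr
        if not (self.age_min <= lo <= self.age_median <= hi <= self.age_max):
            raise ValueError("age quantiles must satisfy min <= Q1 <= median <= Q3 <= max")
        if self.sex_mode not in ("quota", "bernoulli"):
            raise ValueError("sex_mode must be 'quota' or 'bernoulli'")

    def age_from_normal(self, z: np.ndarray) -> np.ndarray:
        """Monotone map from standard-normal scores to the age scale."""
        lo, hi = self.age_iqr
        probs = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        quants = np.array([self.age_min, lo, self.age_median, hi, self.age_max])
        return np.interp(stats.norm.cdf(z), probs, quants)


def study_moment_spec() -> MomentSpec:
    """The published scale-level moments of the n = 6057 survey sample."""
    k = len(_SCALE_VARS)
    corr = np.eye(k)
    for (v1, v2), r in _SCALE_CORR.items():
        i, j = _SCALE_VARS.index(v1), _SCALE_VARS.index(v2)
        corr[i, j] = corr[j, i] = r
    return MomentSpec(_SCALE_VARS, _SCALE_MEANS, _SCALE_SDS, corr)


def study_demographics(n: int = STUDY_N) -> DemographicSpec:
    return DemographicSpec(n=n)


# ---------------------------------------------------------------------------
# Positive-definiteness repair
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationRepair:
    """A repaired correlation matrix plus the size of the perturbation."""

    corr: np.ndarray
    max_abs_change: float
    modified: bool


def _check_correlation_matrix(corr: np.ndarray, atol: float = 1e-10) -> None:
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=atol):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=atol):
        raise ValueError("correlation matrix must have unit diagonal")
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    if off.size and (off.min() < -1.0 - atol or off.max() > 1.0 + atol):
        raise ValueError("off-diagonal correlations must lie in [-1, 1]")


def repair_correlation_matrix(
    corr: np.ndarray, floor: float = 1e-6, max_iter: int = 100
) -> CorrelationRepair:
    """Return the nearest-by-clipping positive-definite correlation matrix.

    Eigenvalues below ``floor`` are clipped up to it, the matrix is
    reconstructed and renormalized back to unit diagonal, iterating until the
    smallest eigenvalue clears the floor.  Already-positive-definite inputs
    are returned unchanged (the repair is a no-op and idempotent).
    """
    corr = np.asarray(corr, dtype=float)
    _check_correlation_matrix(corr)
    out = corr.copy()
    for _ in range(max_iter):
        eigval, eigvec = np.linalg.eigh(out)
        if eigval.min() >= floor * (1.0 - 1e-9):
            break
        clipped = np.maximum(eigval, floor)
        out = (eigvec * clipped) @ eigvec.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2.0
        np.fill_diagonal(out, 1.0)
    else:  # pragma: no cover - clipping converges in very few iterations
        raise RuntimeError("correlation repair did not converge")
    delta = float(np.abs(out - corr).max())
    return CorrelationRepair(out, delta, delta > 0.0)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _exact_moment_transform(z: np.ndarray) -> np.ndarray:
    """Rotate a draw so its sample mean is 0 and sample covariance identity."""
    n = z.shape[0]
    if n <= z.shape[1]:
        raise ValueError("exact moment matching needs n > number of variables")
    zc = z - z.mean(axis=0)
    cov = zc.T @ zc / (n - 1)
    chol = np.linalg.cholesky(cov)
    return np.linalg.solve(chol, zc.T).T


def generate_scale_level(
    spec: MomentSpec,
    n: int,
    seed: int,
    demographics: DemographicSpec | None = None,
    exact_moments: bool = False,
    pd_floor: float = 1e-6,
) -> pd.DataFrame:
    """Draw n respondents with scale totals matching ``spec``.

    Scale variables are multivariate normal with the (repaired) target
    correlation.  When ``demographics`` is given, an ``age`` column is
    appended whose latent normal score is correlated with the scales per
    ``DemographicSpec.age_corr`` and then monotonically transformed to the
    published age quantiles, plus a ``sex`` column (1 = female, 0 = male)
    independent of everything else.  ``exact_moments=True`` forces the
    *sample* mean/SD/correlations of the scale columns to equal the target
    exactly (useful for analytic replication), instead of only in
    expectation.

    The PD-repair perturbation applied to the target correlation matrix is
    recorded in ``df.attrs['pd_repair_max_change']``.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    names = list(spec.variables)
    corr = spec.corr.copy()
    if demographics is not None:
        unknown = set(demographics.age_corr) - set(names)
        if unknown:
            raise ValueError(f"age_corr refers to unknown variables: {sorted(unknown)}")
        k = len(names)
        aug = np.eye(k + 1)
        aug[:k, :k] = corr
        for var, r in demographics.age_corr.items():
            i = names.index(var)
            aug[i, k] = aug[k, i] = r
        corr = aug
    repair = repair_correlation_matrix(corr, floor=pd_floor)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, corr.shape[0]))
    if exact_moments:
        z = _exact_moment_transform(z)
    chol = np.linalg.cholesky(repair.corr)
    latent = z @ chol.T

    data: dict[str, np.ndarray] = {"id": np.arange(1, n + 1)}
    if demographics is not None:
        data["age"] = demographics.age_from_normal(latent[:, -1])
        n_female = int(round(n * demographics.female_proportion))
        if demographics.sex_mode == "quota":
            sex = np.zeros(n, dtype=int)
            sex[:n_female] = 1
            data["sex"] = rng.permutation(sex)
        else:
            data["sex"] = rng.binomial(1, demographics.female_proportion, size=n)
    for j, name in enumerate(names):
        data[name] = spec.means[j] + spec.sds[j] * latent[:, j]
    df = pd.DataFrame(data)
    df.attrs["seed"] = seed
    df.attrs["pd_repair_max_change"] = repair.max_abs_change
    return df


def generate_item_level(
    spec: ItemBatterySpec,
    n: int,
    seed: int,
    discretize: bool = True,
    prefix: str = "item",
) -> pd.DataFrame:
    """Draw an n x k item-response battery with compound-symmetric structure.

    Each latent item is ``sqrt(rho)*common + sqrt(1-rho)*unique`` (standard
    normal margins).  With ``discretize=True`` (default) latent scores are cut
    at ``spec.effective_thresholds()`` into integer Likert responses in
    ``[likert_min, likert_max]``; otherwise the continuous latent scores are
    returned, whose Cronbach's alpha matches ``spec.implied_alpha`` exactly in
    population.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rho = spec.inter_item_corr + (spec.rho_inflation if discretize else 0.0)
    rng = np.random.default_rng(seed)
    common = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, spec.n_items))
    latent = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * unique
    cols = [f"{prefix}_{i + 1:02d}" for i in range(spec.n_items)]
    if not discretize:
        return pd.DataFrame(latent, columns=cols)
    cuts = spec.effective_thresholds()
    responses = spec.likert_min + np.digitize(latent, cuts)
    return pd.DataFrame(responses.astype(int), columns=cols)


def generate_structural(
    spec: StructuralSpec,
    n: int,
    seed: int,
    include_covariates: bool = False,
) -> pd.DataFrame:
    """Draw (x, w, m, y) from the moderated-mediation path model.

    ``include_covariates=True`` appends independent standard-normal ``age``
    and Bernoulli(0.5) ``sex`` columns (pure noise covariates) so covariate-
    adjusted pipelines can be exercised against known truth.  The generating
    spec is attached as ``df.attrs['structural_spec']`` for recovery tests.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, spec.x_sd, size=n)
    w = rng.normal(0.0, spec.w_sd, size=n)
    e_m = rng.normal(0.0, spec.sd_m, size=n)
    e_y = rng.normal(0.0, spec.sd_y, size=n)
    m = spec.a * x + spec.a_w * x * w + spec.w_to_m * w + e_m
    y = spec.c_prime * x + spec.b * m + spec.b_w * m * w + spec.w_to_y * w + e_y
    data = {"x": x, "w": w, "m": m, "y": y}
    if include_covariates:
        data["age"] = rng.standard_normal(n)
        data["sex"] = rng.binomial(1, 0.5, size=n)
    df = pd.DataFrame(data)
    df.attrs["structural_spec"] = dataclasses.asdict(spec)
    df.attrs["seed"] = seed
    return df
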