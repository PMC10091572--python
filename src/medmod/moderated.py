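"""Two-stage moderated mediation: interaction fits, simple effects and
bootstrap tests of conditional indirect effects.

The model extends simple mediation X -> M -> Y by letting a moderator W
shift the first-stage path (X -> M), the second-stage path (M -> Y), or
both.  Following standard conditional-process practice, every analysis
variable is z-scored first and interaction products are formed from the
standardized components, so the conventional low/mean/high moderator levels
are exactly w = -1, 0, +1 on the model scale.

Each stage is fit hierarchically:

    stage one  (outcome M):  covariates | + X + W | + X*W
    stage two  (outcome Y):  covariates | + X + W + M | + M*W

with R-squared increments and incremental F per step.  From the final-step
coefficients, the simple (conditional) effects at moderator value w are

    first(w)  = a + w * a_int        second(w) = b + w * b_int

and the conditional indirect effect is their product first(w) * second(w).
Because the model is linear in the interaction, the high-low difference of a
stage's simple effect is exactly (w_high - w_low) * interaction
coefficient.  Significance of the conditional indirect effects and of the
high-low differences comes from the bias-corrected percentile bootstrap:
rows of the (standardized) data are resampled whole, both stage models are
refit per resample, the full simple-effect table is recomputed, and
intervals are read from the empirical distributions.

Two protocols for the simple-effect tests are available: the default
full-sample interaction fit above, and a subgroup approach
(:func:`subgroup_simple_effects`) that dichotomizes the moderator and fits
unmoderated stage models within each half — retained because published
analyses sometimes report it, though it discards information and has lower
power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mediation import (
    BootstrapInterval,
    batched_ols_coefs,
    bc_interval,
    bootstrap_indices,
)
from .stats_core import (
    INTERACTION_SEP,
    HierarchicalFit,
    hierarchical_fit,
    significance_stars,
    zscore,
)

__all__ = [
    "StageModels",
    "ConditionalEffectTable",
    "fit_stage_models",
    "simple_effects",
    "bootstrap_conditional",
    "subgroup_simple_effects",
]

_STAGES = ("first", "second", "both")
DEFAULT_LEVELS = (-1.0, 0.0, 1.0)


@dataclass
class StageModels:
    """Hierarchical fits for both stages plus the extracted path terms."""

    x: str
    m: str
    y: str
    w: str | None
    w_second: str | None
    covariates: tuple[str, ...]
    moderated_stages: str | None
    first: HierarchicalFit
    second: HierarchicalFit
    standardized: bool

    @property
    def first_moderated(self) -> bool:
        return self.w is not None and self.moderated_stages in ("first", "both")

    @property
    def second_moderated(self) -> bool:
        return self.w_second is not None and self.moderated_stages in ("second", "both")

    @property
    def a(self) -> float:
        return float(self.first.final.params[self.x])

    @property
    def a_interaction(self) -> float:
        if not self.first_moderated:
            return 0.0
        return float(self.first.final.params[f"{self.x}{INTERACTION_SEP}{self.w}"])

    @property
    def b(self) -> float:
        return float(self.second.final.params[self.m])

    @property
    def b_interaction(self) -> float:
        if not self.second_moderated:
            return 0.0
        return float(self.second.final.params[f"{self.m}{INTERACTION_SEP}{self.w_second}"])


def _stage_blocks(
    x: str,
    m: str,
    y: str,
    w: str | None,
    w_second: str | None,
    covariates: Sequence[str],
    moderated_stages: str | None,
) -> tuple[list[list[str]], list[list[str]]]:
    covs = list(covariates)
    first_main = [x] + ([w] if w else [])
    second_main = [x] + ([w_second] if w_second else []) + [m]
    first_blocks = ([covs] if covs else []) + [first_main]
    second_blocks = ([covs] if covs else []) + [second_main]
    if w and moderated_stages in ("first", "both"):
        first_blocks.append([f"{x}{INTERACTION_SEP}{w}"])
    if w_second and moderated_stages in ("second", "both"):
        second_blocks.append([f"{m}{INTERACTION_SEP}{w_second}"])
    return first_blocks, second_blocks


def fit_stage_models(
    data: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    w: str | None,
    covariates: Sequence[str] = (),
    moderated_stages: str = "both",
    w_second: str | None = None,
    standardized: bool = True,
) -> StageModels:
    """Fit the hierarchical first- and second-stage models.

    ``w`` moderates the stages named in ``moderated_stages`` ('first',
    'second' or 'both'); pass ``w_second`` to use a different moderator in
    the second stage (default: shared).  ``w=None`` drops the moderator
    entirely, reducing to plain hierarchical mediation (useful as an exact
    cross-check against the simple-mediation module).
    """
    if w is not None and moderated_stages not in _STAGES:
        raise ValueError(f"moderated_stages must be one of {_STAGES}")
    if w_second is None:
        w_second = w
    names = [x, m, y, *covariates] + [c for c in (w, w_second) if c]
    if len(set(names) - {w, w_second}) != len([x, m, y, *covariates]):
        raise ValueError("x, m, y, w and covariates must be distinct columns")
    first_blocks, second_blocks = _stage_blocks(
        x, m, y, w, w_second, covariates, moderated_stages if w else None
    )
    return StageModels(
        x=x,
        m=m,
        y=y,
        w=w,
        w_second=w_second,
        covariates=tuple(covariates),
        moderated_stages=moderated_stages if w else None,
        first=hierarchical_fit(data, m, first_blocks, standardized=standardized),
        second=hierarchical_fit(data, y, second_blocks, standardized=standardized),
        standardized=standardized,
    )


@dataclass
class ConditionalEffectTable:
    """Simple effects and conditional indirect effects at moderator levels.

    ``first``, ``second`` and ``indirect`` are aligned with ``levels``; the
    ``diff_*`` entries are the high-low differences (last level minus first
    level).  After :func:`bootstrap_conditional`, ``intervals`` holds one
    primary-method interval per cell keyed ``"first@-1"``, ``"indirect@0"``,
    ``"diff_second"``, ...
    """

    levels: tuple[float, ...]
    first: np.ndarray
    second: np.ndarray
    indirect: np.ndarray
    diff_first: float
    diff_second: float
    diff_indirect: float
    method: str | None = None
    n_boot: int | None = None
    seed: int | None = None
    redraws: int = 0
    intervals: dict[str, BootstrapInterval] = field(default_factory=dict)
    boot_se: dict[str, float] = field(default_factory=dict)

    def _cells(self):
        for name, values in (("first", self.first), ("second", self.second), ("indirect", self.indirect)):
            for lev, val in zip(self.levels, values):
                yield f"{name}@{lev:g}", float(val)
        yield "diff_first", self.diff_first
        yield "diff_second", self.diff_second
        yield "diff_indirect", self.diff_indirect

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lev, f, s, i in zip(self.levels, self.first, self.second, self.indirect):
            rows.append({"level": lev, "first": f, "second": s, "indirect": i})
        rows.append(
            {
                "level": "high-low",
                "first": self.diff_first,
                "second": self.diff_second,
                "indirect": self.diff_indirect,
            }
        )
        out = pd.DataFrame(rows)
        if self.intervals:
            for col in ("first", "second", "indirect"):
                stars, lowers, uppers = [], [], []
                for lev in self.levels:
                    iv = self.intervals.get(f"{col}@{lev:g}")
                    stars.append("*" if iv and iv.excludes_zero else "")
                    lowers.append(iv.lower if iv else np.nan)
                    uppers.append(iv.upper if iv else np.nan)
                div = self.intervals.get(f"diff_{col}")
                stars.append("*" if div and div.excludes_zero else "")
                lowers.append(div.lower if div else np.nan)
                uppers.append(div.upper if div else np.nan)
                out[f"{col}_lower"] = lowers
                out[f"{col}_upper"] = uppers
                out[f"{col}_sig"] = stars
        return out


def simple_effects(
    fits: StageModels, levels: Sequence[float] = DEFAULT_LEVELS
) -> ConditionalEffectTable:
    """Point simple effects first(w), second(w) and their products.

    first(w) = a + w*a_int and second(w) = b + w*b_int from the final-step
    coefficients; an unmoderated stage is constant across levels.  The
    high-low difference is the effect at the last level minus the effect at
    the first level, which for a linear interaction equals
    (w_high - w_low) * interaction.
    """
    w = np.asarray(list(levels), dtype=float)
    if w.size < 2:
        raise ValueError("need at least two moderator levels")
    first = fits.a + w * fits.a_interaction
    second = fits.b + w * fits.b_interaction
    indirect = first * second
    return ConditionalEffectTable(
        levels=tuple(float(v) for v in w),
        first=first,
        second=second,
        indirect=indirect,
        diff_first=float(first[-1] - first[0]),
        diff_second=float(second[-1] - second[0]),
        diff_indirect=float(indirect[-1] - indirect[0]),
    )


def _standardize_frame(data: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    out = pd.DataFrame(index=data.index)
    for col in columns:
        out[col] = zscore(data[col].astype(float).to_numpy())
    return out


def bootstrap_conditional(
    data: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    w: str | None,
    covariates: Sequence[str] = (),
    moderated_stages: str = "both",
    w_second: str | None = None,
    levels: Sequence[float] = DEFAULT_LEVELS,
    n_boot: int = 5000,
    method: str = "bias_corrected",
    level: float = 0.95,
    seed: int = 0,
) -> ConditionalEffectTable:
    """Simple-effect table with bootstrap intervals and difference tests.

    Variables are standardized once on the full sample; rows of the
    standardized data are then resampled whole (the identical index stream
    convention as the simple-mediation bootstrap) and both final-step stage
    models are refit per resample, recomputing every cell of the table.
    Intervals (primary ``method``) are attached for each conditional effect
    and for the three high-low differences; a cell is flagged significant
    when its interval excludes zero.
    """
    fits = fit_stage_models(
        data, x, m, y, w, covariates, moderated_stages, w_second, standardized=True
    )
    table = simple_effects(fits, levels)
    if w_second is None:
        w_second = w
    base_cols = [c for c in dict.fromkeys([x, m, y, w, w_second, *covariates]) if c]
    zd = _standardize_frame(data, base_cols)
    n = len(zd)
    w_arr = np.asarray(list(levels), dtype=float)

    # final-step designs on the standardized scale
    ones = np.ones(n)
    covs = zd[list(covariates)].to_numpy() if covariates else np.empty((n, 0))
    first_cols = [ones, covs, zd[x].to_numpy()]
    first_names = ["const", *covariates, x]
    if w:
        first_cols.append(zd[w].to_numpy())
        first_names.append(w)
    if fits.first_moderated:
        first_cols.append(zd[x].to_numpy() * zd[w].to_numpy())
        first_names.append("xw")
    X1 = np.column_stack(first_cols)
    second_cols = [ones, covs, zd[x].to_numpy()]
    second_names = ["const", *covariates, x]
    if w_second:
        second_cols.append(zd[w_second].to_numpy())
        second_names.append(w_second)
    second_cols.append(zd[m].to_numpy())
    second_names.append(m)
    if fits.second_moderated:
        second_cols.append(zd[m].to_numpy() * zd[w_second].to_numpy())
        second_names.append("mw")
    X2 = np.column_stack(second_cols)

    rng = np.random.default_rng(seed)
    idx = bootstrap_indices(rng, n, n_boot)
    coef1, r1 = batched_ols_coefs(X1, zd[m].to_numpy()[:, None], idx, rng)
    coef2, r2 = batched_ols_coefs(X2, zd[y].to_numpy()[:, None], idx, rng)
    a_star = coef1[:, first_names.index(x), 0]
    a_int_star = coef1[:, first_names.index("xw"), 0] if fits.first_moderated else 0.0
    b_star = coef2[:, second_names.index(m), 0]
    b_int_star = coef2[:, second_names.index("mw"), 0] if fits.second_moderated else 0.0

    first_star = a_star[:, None] + w_arr[None, :] * np.atleast_1d(a_int_star)[:, None]
    second_star = b_star[:, None] + w_arr[None, :] * np.atleast_1d(b_int_star)[:, None]
    indirect_star = first_star * second_star

    draws: dict[str, np.ndarray] = {}
    for name, stars in (("first", first_star), ("second", second_star), ("indirect", indirect_star)):
        for j, lev in enumerate(table.levels):
            draws[f"{name}@{lev:g}"] = stars[:, j]
        draws[f"diff_{name}"] = stars[:, -1] - stars[:, 0]

    points = dict(table._cells())
    table.method = method
    table.n_boot = n_boot
    table.seed = seed
    table.redraws = r1 + r2
    for key, boot in draws.items():
        table.boot_se[key] = float(boot.std(ddof=1))
        table.intervals[key] = bc_interval(
            boot, points[key], level=level, method=method, seed=seed
        )
    return table


def subgroup_simple_effects(
    data: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    w: str,
    covariates: Sequence[str] = (),
    split: str = "mean",
) -> pd.DataFrame:
    """Subgroup protocol: dichotomize W and fit unmoderated models per half.

    ``split`` is 'mean' or 'median'.  Variables are standardized on the full
    sample first (so subgroup coefficients stay on the common scale), then
    each subgroup gets plain stage fits without interaction terms.  Returns
    a table of a, b and a*b per subgroup plus their high-low differences.
    Lower-powered than the full-sample interaction fit; kept for comparison.
    """
    if split not in ("mean", "median"):
        raise ValueError("split must be 'mean' or 'median'")
    wv = data[w].astype(float)
    cut = wv.mean() if split == "mean" else wv.median()
    base_cols = [x, m, y, *covariates]
    zd = _standardize_frame(data, base_cols)
    rows = []
    for label, mask in (("low", wv <= cut), ("high", wv > cut)):
        sub = zd[mask.to_numpy()]
        fits = fit_stage_models(
            sub, x, m, y, w=None, covariates=covariates, standardized=False
        )
        rows.append(
            {"group": label, "n": len(sub), "a": fits.a, "b": fits.b, "indirect": fits.a * fits.b}
        )
    out = pd.DataFrame(rows).set_index("group")
    out.loc["high-low"] = out.loc["high"] - out.loc["low"]
    return out
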