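"""Descriptives, correlation inference, group comparison and OLS machinery.

This module is the computational substrate for the path analyses: plain and
hierarchical (blockwise) least-squares fits with optional standardization,
plus the descriptive statistics and bivariate tests reported alongside them.

Conventions, applied everywhere:

* SDs and variances use the n-1 denominator, including inside
  standardization.
* Standardized fits z-score the raw variables first and then form
  interaction products from the standardized components; the product column
  itself is *not* re-standardized.  This makes "one SD above/below the mean"
  of a moderator exactly +/-1 on the model scale.
* Interaction terms are written ``"a:b"`` (product of columns a and b).
* p-values are two-sided; significance stars use the 0.05/0.01/0.001
  thresholds.

Because the fits behind published hierarchical tables are run on z-scored
variables, coefficient tables label the coefficient column ``B`` but it
should be read as a standardized coefficient whenever ``standardized=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "describe",
    "pearson_matrix",
    "PearsonResult",
    "mann_whitney_u",
    "MannWhitneyResult",
    "ols_fit",
    "RegressionFit",
    "hierarchical_fit",
    "HierarchicalFit",
    "BlockResult",
    "zscore",
    "build_design",
    "significance_stars",
    "INTERACTION_SEP",
]

INTERACTION_SEP = ":"


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def zscore(values: pd.Series | np.ndarray) -> np.ndarray:
    """(x - mean) / sd with the n-1 denominator."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Descriptives and bivariate statistics
# ---------------------------------------------------------------------------


def describe(data: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-variable mean, SD (n-1), median and IQR bounds."""
    cols = list(columns) if columns is not None else list(data.columns)
    if len(data) < 2:
        raise ValueError("descriptives need at least 2 rows")
    sub = data[cols].astype(float)
    out = pd.DataFrame(
        {
            "mean": sub.mean(),
            "sd": sub.std(ddof=1),
            "median": sub.median(),
            "iqr_low": sub.quantile(0.25),
            "iqr_high": sub.quantile(0.75),
        }
    )
    out.index.name = "variable"
    return out


class PearsonResult(NamedTuple):
    r: pd.DataFrame
    p: pd.DataFrame
    n: int


def pearson_matrix(
    data: pd.DataFrame, columns: Sequence[str] | None = None
) -> PearsonResult:
    """Pairwise Pearson correlations with two-sided p-values.

    p-values come from the exact t transform ``t = r*sqrt((n-2)/(1-r^2))``
    on n-2 degrees of freedom; the diagonal is (r=1, p=0).
    """
    cols = list(columns) if columns is not None else list(data.columns)
    sub = data[cols].astype(float)
    n = len(sub)
    if n < 3:
        raise ValueError("correlation inference needs at least 3 rows")
    if (sub.std(ddof=1) == 0).any():
        bad = sub.columns[sub.std(ddof=1) == 0].tolist()
        raise ValueError(f"constant columns have undefined correlations: {bad}")
    r = sub.corr(method="pearson")
    rv = r.to_numpy().copy()
    np.fill_diagonal(rv, 0.0)  # avoid division by zero in the t transform
    with np.errstate(divide="ignore"):
        t = rv * np.sqrt((n - 2) / np.clip(1.0 - rv**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rv) >= 1.0 - 1e-15] = 0.0  # perfectly collinear pairs
    np.fill_diagonal(p, 0.0)
    return PearsonResult(r, pd.DataFrame(p, index=r.index, columns=r.columns), n)


class MannWhitneyResult(NamedTuple):
    u: float
    p: float
    n1: int
    n2: int


def mann_whitney_u(values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test for a binary grouping.

    U is reported for the higher-coded group (so for 0/1 coding, the number
    of (group-1, group-0) pairs in which the group-1 value wins, counting
    ties as half).  Uses the tie-corrected normal approximation for large
    samples via scipy.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"grouping must be binary, found levels {levels!r}")
    x = v[g == levels[1]]
    y = v[g == levels[0]]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), x.size, y.size)


# ---------------------------------------------------------------------------
# OLS with standardization and interaction terms
# ---------------------------------------------------------------------------


def build_design(
    data: pd.DataFrame, terms: Sequence[str], standardized: bool = False
) -> pd.DataFrame:
    """Design matrix (no intercept column) for a term list.

    Base columns are taken from ``data`` (z-scored first when
    ``standardized``); a term ``"a:b"`` is the elementwise product of the
    (possibly standardized) base columns a and b.
    """
    base: dict[str, np.ndarray] = {}

    def column(name: str) -> np.ndarray:
        if name not in base:
            if name not in data.columns:
                raise KeyError(f"term {name!r} not found in data")
            col = data[name].astype(float).to_numpy()
            base[name] = zscore(col) if standardized else col
        return base[name]

    out: dict[str, np.ndarray] = {}
    for term in terms:
        if term in out:
            raise ValueError(f"duplicate term {term!r}")
        if INTERACTION_SEP in term:
            parts = term.split(INTERACTION_SEP)
            prod = column(parts[0]).copy()
            for part in parts[1:]:
                prod = prod * column(part)
            out[term] = prod
        else:
            out[term] = column(term)
    return pd.DataFrame(out, index=data.index)


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(x, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = [design.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [design.columns[j] for j in piv[len(diag):]]
        raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")


@dataclass
class RegressionFit:
    """One least-squares fit: coefficients, inference and fit statistics.

    ``params`` etc. are indexed by term name plus ``"const"``.  ``std_coef``
    holds B_j * SD(x_j) / SD(y) computed from the design columns (for a fit
    that was already run on standardized variables this is essentially the
    coefficient itself, up to the non-re-standardized interaction columns).
    """

    outcome: str
    terms: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    std_coef: pd.Series
    r_squared: float
    f_stat: float
    f_pvalue: float
    df_resid: float
    n: int
    standardized: bool

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "B": self.params,
                "SE": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "std_B": self.std_coef,
            }
        )
        out["stars"] = [significance_stars(p) for p in out["p"]]
        out.index.name = "term"
        return out


def ols_fit(
    data: pd.DataFrame,
    outcome: str,
    terms: Sequence[str],
    standardized: bool = False,
) -> RegressionFit:
    """Ordinary least squares of ``outcome`` on ``terms`` (plus intercept).

    With ``standardized=True`` the outcome and every base variable are
    z-scored before the design (including interaction products) is built.
    """
    design = build_design(data, terms, standardized=standardized)
    n, p = design.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows to fit {p} terms, have {n}")
    _check_full_rank(design)
    y = data[outcome].astype(float).to_numpy()
    if standardized:
        y = zscore(y)
    X = sm.add_constant(design, has_constant="add")
    res = sm.OLS(y, X).fit()
    sd_y = y.std(ddof=1)
    std_coef = pd.Series(
        {
            term: res.params[term] * design[term].std(ddof=1) / sd_y
            for term in design.columns
        },
        name="std_B",
    )
    std_coef["const"] = np.nan
    return RegressionFit(
        outcome=outcome,
        terms=tuple(terms),
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        std_coef=std_coef.reindex(res.params.index),
        r_squared=float(res.rsquared),
        f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df_resid=float(res.df_resid),
        n=n,
        standardized=standardized,
    )


@dataclass
class BlockResult:
    """One step of a hierarchical fit: the cumulative model plus increments."""

    block_terms: tuple[str, ...]
    fit: RegressionFit
    delta_r2: float
    incremental_f: float
    incremental_f_pvalue: float
    df_num: int
    df_den: float


@dataclass
class HierarchicalFit:
    outcome: str
    blocks: list[BlockResult]
    standardized: bool

    @property
    def final(self) -> RegressionFit:
        return self.blocks[-1].fit

    def to_frame(self) -> pd.DataFrame:
        """Long-format step x term table in the layout of published tables."""
        rows = []
        for step, blk in enumerate(self.blocks, start=1):
            fit = blk.fit
            for term in fit.params.index:
                if term == "const":
                    continue
                rows.append(
                    {
                        "step": step,
                        "term": term,
                        "B": fit.params[term],
                        "SE": fit.bse[term],
                        "t": fit.tvalues[term],
                        "p": fit.pvalues[term],
                        "stars": significance_stars(fit.pvalues[term]),
                    }
                )
            rows.append(
                {
                    "step": step,
                    "term": "R2",
                    "B": fit.r_squared,
                    "SE": np.nan,
                    "t": np.nan,
                    "p": np.nan,
                    "stars": "",
                }
            )
            rows.append(
                {
                    "step": step,
                    "term": "F",
                    "B": fit.f_stat,
                    "SE": np.nan,
                    "t": np.nan,
                    "p": fit.f_pvalue,
                    "stars": significance_stars(fit.f_pvalue),
                }
            )
            rows.append(
                {
                    "step": step,
                    "term": "incremental_F",
                    "B": blk.incremental_f,
                    "SE": np.nan,
                    "t": np.nan,
                    "p": blk.incremental_f_pvalue,
                    "stars": significance_stars(blk.incremental_f_pvalue),
                }
            )
        return pd.DataFrame(rows)


def hierarchical_fit(
    data: pd.DataFrame,
    outcome: str,
    blocks: Sequence[Sequence[str]],
    standardized: bool = True,
) -> HierarchicalFit:
    """Blockwise (hierarchical) OLS with per-block R-squared increments.

    Blocks are entered cumulatively; for each step the increment over the
    previous step is tested with
    ``F = (dR2/q) / ((1 - R2_step) / (n - p_step - 1))`` on (q, n-p_step-1)
    degrees of freedom, where q is the number of terms the step adds.
    """
    block_lists = [list(b) for b in blocks]
    flat = [t for b in block_lists for t in b]
    if len(set(flat)) != len(flat):
        raise ValueError("blocks must be disjoint term lists")
    results: list[BlockResult] = []
    cumulative: list[str] = []
    prev_r2 = 0.0
    for block in block_lists:
        cumulative = cumulative + block
        fit = ols_fit(data, outcome, cumulative, standardized=standardized)
        q = len(block)
        delta = fit.r_squared - prev_r2
        df_den = fit.df_resid
        if fit.r_squared >= 1.0 - 1e-14:
            inc_f, inc_p = np.inf, 0.0
        else:
            inc_f = (delta / q) / ((1.0 - fit.r_squared) / df_den)
            inc_p = float(stats.f.sf(inc_f, q, df_den))
        results.append(
            BlockResult(
                block_terms=tuple(block),
                fit=fit,
                delta_r2=delta,
                incremental_f=float(inc_f),
                incremental_f_pvalue=inc_p,
                df_num=q,
                df_den=df_den,
            )
        )
        prev_r2 = fit.r_squared
    return HierarchicalFit(outcome=outcome, blocks=results, standardized=standardized)
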