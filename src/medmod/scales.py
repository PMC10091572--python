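"""Questionnaire scoring and internal-consistency reliability.

Scoring rules for the five instruments used in the analysis:

* CTQ-28 — childhood trauma, 28 items on a 1-5 frequency scale; five
  5-item trauma subscales (emotional/physical/sexual abuse,
  emotional/physical neglect, each totalling 5-25) plus three
  minimization/denial items that are accepted but never enter totals.
* ERQ-10 — emotion regulation, 10 items on 1-7; two subscales: cognitive
  reappraisal (6 items, 6-42) and expressive suppression (4 items, 4-28).
* SES-10 — Rosenberg self-esteem, 10 items on 1-4 with five reverse-keyed
  items, total 10-40.
* PHQ-9 / GAD-7 — depression and anxiety symptoms.  Default coding is the
  standard 0-3 per item, summed (totals 0-27 / 0-21), which is the coding
  consistent with the published sample descriptives; a 1-4 coding with
  mean scoring is available as a variant.

Reverse-keyed responses are transformed as ``min + max - response`` before
aggregation.  Reliability is Cronbach's alpha,
``alpha = k/(k-1) * (1 - sum(item variances)/variance(total))`` with n-1
variance denominators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ScaleDefinition",
    "AlphaResult",
    "score_scale",
    "cronbach_alpha",
    "builtin_scale",
    "BUILTIN_SCALES",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """Declarative description of how a questionnaire is scored."""

    name: str
    items: tuple[str, ...]
    response_min: int
    response_max: int
    reverse_items: frozenset[str] = frozenset()
    subscales: dict[str, tuple[str, ...]] = field(default_factory=dict)
    unscored_items: frozenset[str] = frozenset()
    scoring: str = "sum"

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "reverse_items", frozenset(self.reverse_items))
        object.__setattr__(self, "unscored_items", frozenset(self.unscored_items))
        object.__setattr__(
            self, "subscales", {k: tuple(v) for k, v in self.subscales.items()}
        )
        if len(set(self.items)) != len(self.items):
            raise ValueError(f"{self.name}: duplicate item labels")
        if self.response_min >= self.response_max:
            raise ValueError(f"{self.name}: response_min must be below response_max")
        if self.scoring not in ("sum", "mean"):
            raise ValueError(f"{self.name}: scoring must be 'sum' or 'mean'")
        item_set = set(self.items)
        if not self.reverse_items <= item_set:
            raise ValueError(f"{self.name}: reverse_items must be a subset of items")
        if not self.unscored_items <= item_set:
            raise ValueError(f"{self.name}: unscored_items must be a subset of items")
        seen: set[str] = set()
        for sub, sub_items in self.subscales.items():
            s = set(sub_items)
            if not s <= item_set:
                raise ValueError(f"{self.name}: subscale {sub} uses unknown items")
            if s & seen:
                raise ValueError(f"{self.name}: items may belong to at most one subscale")
            if s & self.unscored_items:
                raise ValueError(f"{self.name}: unscored items cannot sit in a subscale")
            seen |= s

    @property
    def scored_items(self) -> tuple[str, ...]:
        return tuple(i for i in self.items if i not in self.unscored_items)

    @property
    def valid_range(self) -> tuple[float, float]:
        """Attainable (min, max) of the total under the scoring method."""
        k = len(self.scored_items)
        if self.scoring == "sum":
            return (k * self.response_min, k * self.response_max)
        return (float(self.response_min), float(self.response_max))

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "items": list(self.items),
            "response_min": self.response_min,
            "response_max": self.response_max,
            "reverse_items": sorted(self.reverse_items),
            "subscales": {k: list(v) for k, v in self.subscales.items()},
            "unscored_items": sorted(self.unscored_items),
            "scoring": self.scoring,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScaleDefinition":
        d = json.loads(text)
        return cls(
            name=d["name"],
            items=tuple(d["items"]),
            response_min=int(d["response_min"]),
            response_max=int(d["response_max"]),
            reverse_items=frozenset(d.get("reverse_items", ())),
            subscales={k: tuple(v) for k, v in d.get("subscales", {}).items()},
            unscored_items=frozenset(d.get("unscored_items", ())),
            scoring=d.get("scoring", "sum"),
        )


def _labels(prefix: str, numbers) -> tuple[str, ...]:
    return tuple(f"{prefix}_{i:02d}" for i in numbers)


def _ctq() -> ScaleDefinition:
    # Canonical CTQ-SF layout: five 5-item trauma subscales plus three
    # minimization/denial items (10, 16, 22) that never enter totals.
    return ScaleDefinition(
        name="ctq",
        items=_labels("ctq", range(1, 29)),
        response_min=1,
        response_max=5,
        reverse_items=frozenset(_labels("ctq", (2, 5, 7, 13, 19, 26, 28))),
        subscales={
            "emotional_abuse": _labels("ctq", (3, 8, 14, 18, 25)),
            "physical_abuse": _labels("ctq", (9, 11, 12, 15, 17)),
            "sexual_abuse": _labels("ctq", (20, 21, 23, 24, 27)),
            "emotional_neglect": _labels("ctq", (5, 7, 13, 19, 28)),
            "physical_neglect": _labels("ctq", (1, 2, 4, 6, 26)),
        },
        unscored_items=frozenset(_labels("ctq", (10, 16, 22))),
    )


def _erq() -> ScaleDefinition:
    return ScaleDefinition(
        name="erq",
        items=_labels("erq", range(1, 11)),
        response_min=1,
        response_max=7,
        subscales={
            "cr": _labels("erq", (1, 3, 5, 7, 8, 10)),
            "es": _labels("erq", (2, 4, 6, 9)),
        },
    )


def _ses() -> ScaleDefinition:
    return ScaleDefinition(
        name="ses",
        items=_labels("ses", range(1, 11)),
        response_min=1,
        response_max=4,
        reverse_items=frozenset(_labels("ses", (3, 5, 8, 9, 10))),
    )


def _phq9(coding: str = "0-3", scoring: str = "sum") -> ScaleDefinition:
    lo, hi = (0, 3) if coding == "0-3" else (1, 4)
    return ScaleDefinition(
        name="phq9",
        items=_labels("phq", range(1, 10)),
        response_min=lo,
        response_max=hi,
        scoring=scoring,
    )


def _gad7(coding: str = "0-3", scoring: str = "sum") -> ScaleDefinition:
    lo, hi = (0, 3) if coding == "0-3" else (1, 4)
    return ScaleDefinition(
        name="gad7",
        items=_labels("gad", range(1, 8)),
        response_min=lo,
        response_max=hi,
        scoring=scoring,
    )


BUILTIN_SCALES = {
    "ctq": _ctq,
    "erq": _erq,
    "ses": _ses,
    "phq9": _phq9,
    "gad7": _gad7,
}


def builtin_scale(name: str, **kwargs) -> ScaleDefinition:
    """Return one of the built-in instrument definitions by name.

    ``phq9`` and ``gad7`` accept ``coding`` ('0-3' default, or '1-4') and
    ``scoring`` ('sum' default, or 'mean').
    """
    try:
        factory = BUILTIN_SCALES[name]
    except KeyError:
        raise KeyError(
            f"unknown scale {name!r}; available: {sorted(BUILTIN_SCALES)}"
        ) from None
    return factory(**kwargs)


def score_scale(items: pd.DataFrame, definition: ScaleDefinition) -> pd.DataFrame:
    """Score a scale: per-respondent total plus one column per subscale.

    Responses must be complete and within the declared range; reverse-keyed
    items are transformed as ``min + max - response`` before aggregation.
    Column order in ``items`` is irrelevant; extra columns are ignored.
    """
    missing = [i for i in definition.items if i not in items.columns]
    if missing:
        raise ValueError(f"{definition.name}: item columns not found: {missing}")
    mat = items.loc[:, list(definition.items)].astype(float)
    if mat.isna().any().any():
        bad = mat.isna().stack()
        row, col = bad[bad].index[0]
        raise ValueError(f"{definition.name}: missing response at row {row!r}, item {col!r}")
    out_of_range = (mat < definition.response_min) | (mat > definition.response_max)
    if out_of_range.any().any():
        bad = out_of_range.stack()
        row, col = bad[bad].index[0]
        raise ValueError(
            f"{definition.name}: response out of range "
            f"[{definition.response_min}, {definition.response_max}] "
            f"at row {row!r}, item {col!r} (value {mat.loc[row, col]:g})"
        )
    rev = list(definition.reverse_items)
    if rev:
        mat[rev] = definition.response_min + definition.response_max - mat[rev]

    agg = (lambda d: d.sum(axis=1)) if definition.scoring == "sum" else (
        lambda d: d.mean(axis=1)
    )
    scores = pd.DataFrame(index=items.index)
    scores["total"] = agg(mat[list(definition.scored_items)])
    for sub, sub_items in definition.subscales.items():
        scores[sub] = agg(mat[list(sub_items)])
    return scores


class AlphaResult(NamedTuple):
    alpha: float
    k: int
    n: int


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> AlphaResult:
    """Cronbach's alpha of an item matrix (rows = respondents).

    alpha = k/(k-1) * (1 - sum_j var(item_j) / var(total)), with n-1
    variance denominators.  Requires >= 2 items, >= 3 respondents and a
    nonzero total variance.
    """
    mat = np.asarray(items, dtype=float)
    if mat.ndim != 2:
        raise ValueError("item matrix must be two-dimensional")
    n, k = mat.shape
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    if n < 3:
        raise ValueError("Cronbach's alpha needs at least 3 respondents")
    if np.isnan(mat).any():
        raise ValueError("item matrix must be complete (no missing responses)")
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha is undefined")
    item_var = mat.var(axis=0, ddof=1).sum()
    alpha = k / (k - 1) * (1.0 - item_var / total_var)
    return AlphaResult(float(alpha), k, n)
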