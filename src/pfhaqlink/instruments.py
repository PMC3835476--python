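"""Deterministic scoring of the PF-10 and HAQ-DI.

The SF-36 physical functioning scale (PF-10) has 10 items answered on a
3-point scale, 1 = "yes, limited a lot" to 3 = "no, not limited at all".
The raw scale score is the item sum linearly rescaled to 0-100 (higher =
better function); a norm-based T-score (mean 50, SD 10 in the 1998 US
general population) is available as a companion metric.

The HAQ disability index (HAQ-DI) has 20 items on a 0-3 scale
(0 = "without any difficulty", 3 = "unable to do") grouped into eight
categories of daily living.  The index is the mean of the eight category
scores (each the maximum of its items), so it takes 25 values between 0
and 3 in steps of 0.125; higher = more disability.  Under standard
scoring (SDI) a category score below 2 is raised to 2 when aids/devices
or help from another person are used for that category; alternative
scoring (ADI) ignores the aids/devices sections.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ScaleId",
    "HaqMethod",
    "NormCoefficients",
    "DEFAULT_NORM_COEFFICIENTS",
    "HAQ_CATEGORIES",
    "HAQ_CATEGORY_SIZES",
    "MISSING",
    "score_pf10_raw",
    "pf10_norm_based",
    "reverse_pf10_items",
    "score_haq_categories",
    "score_haq_total",
    "attainable_scores",
]

#: Sentinel for a missing item response in integer matrices.
MISSING: int = -1


class ScaleId(str, Enum):
    """Identifiers for the four score metrics handled by the package."""

    PF10_RAW = "PF10_RAW"
    PF10_NORM = "PF10_NORM"
    HAQ_SDI = "HAQ_SDI"
    HAQ_ADI = "HAQ_ADI"


class HaqMethod(str, Enum):
    """HAQ-DI scoring method: standard (SDI) or alternative (ADI)."""

    SDI = "SDI"
    ADI = "ADI"


@dataclass(frozen=True)
class NormCoefficients:
    """Reference-population mean and SD of the 0-100 PF-10 raw score.

    The norm-based score is ``50 + 10 * (raw - mu) / sigma``.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


# 1998 US general-population coefficients recovered from the 21 published
# (raw, norm-based) score pairs by minimax fit; regenerate with
# scripts/fit_norm_coefficients.py.
DEFAULT_NORM_COEFFICIENTS = NormCoefficients(mu=83.2625, sigma=23.75)

#: Standard partition of the 20 HAQ-DI items into the eight categories of
#: daily living, in index order of the item columns.
HAQ_CATEGORIES: tuple[tuple[str, tuple[int, ...]], ...] = (
    ("dressing_grooming", (0, 1)),
    ("rising", (2, 3)),
    ("eating", (4, 5, 6)),
    ("walking", (7, 8)),
    ("hygiene", (9, 10, 11)),
    ("reach", (12, 13)),
    ("grip", (14, 15, 16)),
    ("activities", (17, 18, 19)),
)

HAQ_CATEGORY_SIZES: tuple[int, ...] = tuple(len(ix) for _, ix in HAQ_CATEGORIES)

N_PF10_ITEMS = 10
N_HAQ_ITEMS = 20
N_HAQ_CATEGORIES = 8


def _as_items(items: Sequence[int] | np.ndarray, n: int, name: str) -> np.ndarray:
    arr = np.asarray(items)
    if arr.shape != (n,):
        raise ValueError(f"{name} requires exactly {n} items, got shape {arr.shape}")
    return arr.astype(int)


def score_pf10_raw(items: Sequence[int] | np.ndarray) -> float:
    """Traditional 0-100 PF-10 score from the 10 raw item responses.

    Items are coded 1-3 (higher = better function).  The sum (10-30) is
    linearly transformed to the 0-100 metric in steps of 5.  Missing
    responses are not allowed here; drop incomplete records first
    (complete-case scoring).
    """
    arr = _as_items(items, N_PF10_ITEMS, "PF-10")
    missing = np.flatnonzero(arr == MISSING)
    if missing.size:
        raise ValueError(f"PF-10 item(s) {missing.tolist()} missing; complete responses required")
    if not np.all((arr >= 1) & (arr <= 3)):
        raise ValueError("PF-10 item responses must be in {1, 2, 3}")
    return float((arr.sum() - 10) / 20 * 100)


def pf10_norm_based(
    raw: float, coef: NormCoefficients = DEFAULT_NORM_COEFFICIENTS
) -> float:
    """Norm-based (T-metric) PF-10 score, reported to one decimal."""
    attain = attainable_scores(ScaleId.PF10_RAW)
    if not np.isclose(attain, raw).any():
        raise ValueError(f"raw score {raw} is not an attainable PF-10 score")
    return round(50 + 10 * (raw - coef.mu) / coef.sigma, 1)


def reverse_pf10_items(items: Sequence[int] | np.ndarray) -> np.ndarray:
    """Reverse-code PF-10 items to the disability direction (0, 1, 2).

    The calibration convention is that higher category scores mean worse
    function, so item value v maps to 3 - v.  Missing values pass through.
    """
    arr = np.asarray(items, dtype=int)
    out = np.where(arr == MISSING, MISSING, 3 - arr)
    if not np.all((out == MISSING) | ((out >= 0) & (out <= 2))):
        raise ValueError("PF-10 item responses must be in {1, 2, 3} (or missing)")
    return out


def score_haq_categories(
    items: Sequence[int] | np.ndarray,
    aid_flags: Sequence[bool] | np.ndarray,
    method: HaqMethod | str = HaqMethod.SDI,
    *,
    categories: tuple[tuple[str, tuple[int, ...]], ...] = HAQ_CATEGORIES,
    allow_missing_categories: bool = False,
) -> np.ndarray:
    """Eight HAQ-DI category scores from the 20 item responses.

    Each category scores the maximum of its items.  Under SDI, a category
    flagged for aids/devices or personal help is raised to 2 when its
    maximum is below 2; under ADI the flags are ignored.  The standard
    item-to-category partition can be overridden via ``categories``.
    With ``allow_missing_categories`` a fully missing category yields the
    MISSING sentinel instead of an error (see :func:`score_haq_total`).
    """
    method = HaqMethod(method)
    arr = _as_items(items, N_HAQ_ITEMS, "HAQ-DI")
    flags = np.asarray(aid_flags, dtype=bool)
    if flags.shape != (len(categories),):
        raise ValueError(f"need {len(categories)} aid flags, got shape {flags.shape}")
    scores = np.empty(len(categories), dtype=int)
    for c, (name, idx) in enumerate(categories):
        vals = arr[list(idx)]
        vals = vals[vals != MISSING]
        if vals.size == 0:
            if allow_missing_categories:
                scores[c] = MISSING
                continue
            raise ValueError(f"all items of HAQ category '{name}' are missing")
        if not np.all((vals >= 0) & (vals <= 3)):
            raise ValueError(f"HAQ category '{name}' has responses outside 0..3")
        s = int(vals.max())
        if method is HaqMethod.SDI and flags[c] and s < 2:
            s = 2
        scores[c] = s
    return scores


def score_haq_total(
    category_scores: Sequence[int] | np.ndarray, *, min_categories: int | None = None
) -> float:
    """HAQ-DI total: mean of the eight category scores (0-3, step 0.125).

    Complete-case by default.  Passing ``min_categories`` (conventionally
    6) enables the optional missing-category rule: the total is the mean
    over present categories provided at least that many of the eight are
    scored; note the result then need not be a multiple of 0.125.
    """
    arr = _as_items(category_scores, N_HAQ_CATEGORIES, "HAQ category scores")
    present = arr != MISSING
    if min_categories is None:
        if not present.all():
            raise ValueError("missing category scores; complete responses required "
                             "(pass min_categories to enable the partial-scoring rule)")
    elif present.sum() < min_categories:
        raise ValueError(
            f"only {int(present.sum())} of {N_HAQ_CATEGORIES} categories scored; "
            f"need at least {min_categories}"
        )
    vals = arr[present]
    if not np.all((vals >= 0) & (vals <= 3)):
        raise ValueError("category scores must be in 0..3")
    return float(vals.mean())


def attainable_scores(scale_id: ScaleId | str, *, best_first: bool = False) -> np.ndarray:
    """All attainable values of a scale, sorted.

    By default values are in ascending numeric order (for both scales the
    worst-function end of PF-10 comes first and the best-function end of
    HAQ-DI comes first).  With ``best_first=True`` the ordering is by
    function level, best first, on either scale.
    """
    scale_id = ScaleId(scale_id)
    if scale_id in (ScaleId.PF10_RAW, ScaleId.PF10_NORM):
        vals = np.arange(0.0, 101.0, 5.0)
        if scale_id is ScaleId.PF10_NORM:
            vals = np.array([pf10_norm_based(v) for v in vals])
        if best_first:
            vals = vals[::-1]
        return vals
    vals = np.arange(0, 25) * 0.125
    return vals
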