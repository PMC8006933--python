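"""Anthropometric and body-image scoring.

BMI (kg/m^2) with the WHO four-category classification, Stunkard
figure-rating (nine silhouettes, 1 = very thin ... 9 = very big) body-image
dissatisfaction, and categorical weight (mis)perception scores.

Category boundaries are half-open and lower-inclusive: [18.5, 25) is normal
weight, [25, 30) overweight, >= 30 obese.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidFigureError, InvalidMeasurementError

#: Ordered weight-status categories; list index + 1 is the category rank.
CATEGORIES = ("underweight", "normal", "overweight", "obese")

#: BMI cut-offs between successive categories (kg/m^2), lower-inclusive.
BMI_CUTOFFS = (18.5, 25.0, 30.0)

#: Stunkard silhouettes mapped to weight-status categories.
_FIGURE_CATEGORY = {
    1: "underweight",
    2: "underweight",
    3: "normal",
    4: "normal",
    5: "overweight",
    6: "overweight",
    7: "overweight",
    8: "obese",
    9: "obese",
}

_RANK = {c: i + 1 for i, c in enumerate(CATEGORIES)}


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, weight (kg) / height (m) squared.

    Raises
    ------
    InvalidMeasurementError
        If weight or height is not strictly positive (or not finite).
    """
    if not np.isfinite(weight) or weight <= 0:
        raise InvalidMeasurementError(f"weight must be > 0 kg, got {weight!r}")
    if not np.isfinite(height) or height <= 0:
        raise InvalidMeasurementError(f"height must be > 0 m, got {height!r}")
    return weight / height**2


def classify_bmi(bmi: float) -> str:
    """Weight-status category for a BMI value.

    underweight < 18.5 <= normal < 25 <= overweight < 30 <= obese.
    """
    if not np.isfinite(bmi) or bmi <= 0:
        raise InvalidMeasurementError(f"bmi must be > 0 kg/m^2, got {bmi!r}")
    idx = int(np.searchsorted(BMI_CUTOFFS, bmi, side="right"))
    return CATEGORIES[idx]


def stunkard_category(figure: int) -> str:
    """Weight-status category implied by a Stunkard silhouette (1-9)."""
    _check_figure(figure)
    return _FIGURE_CATEGORY[int(figure)]


def category_rank(category: str) -> int:
    """Ordinal rank of a weight-status category (underweight=1 ... obese=4)."""
    try:
        return _RANK[category]
    except KeyError:
        raise InvalidMeasurementError(f"unknown category {category!r}") from None


@dataclass(frozen=True)
class BodyImage:
    """Body-image dissatisfaction derived from current vs preferred silhouette.

    ``bid`` is signed (current - preferred): positive means the respondent
    desires to be thinner.  ``degree`` is |bid|, the magnitude reported in
    descriptive tables.
    """

    current_figure: int
    preferred_figure: int
    bid: int
    degree: int
    bid_group: str


def body_image_dissatisfaction(current: int, preferred: int) -> BodyImage:
    """Signed silhouette discrepancy and satisfaction group.

    current == preferred -> satisfied; current > preferred -> desires_thinner;
    current < preferred -> desires_heavier.
    """
    _check_figure(current)
    _check_figure(preferred)
    bid = int(current) - int(preferred)
    if bid == 0:
        group = "satisfied"
    elif bid > 0:
        group = "desires_thinner"
    else:
        group = "desires_heavier"
    return BodyImage(int(current), int(preferred), bid, abs(bid), group)


def weight_perception(current_figure: int, bmi: float) -> int:
    """Categorical weight-perception score.

    Rank of the silhouette-implied category minus rank of the measured BMI
    category.  Negative: perceives self thinner than measured; positive:
    weightier; zero: correct perception.
    """
    return category_rank(stunkard_category(current_figure)) - category_rank(
        classify_bmi(bmi)
    )


def score_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived anthropometric columns to a subject table.

    Requires columns ``weight_kg``, ``height_m``, ``stunkard_current``,
    ``stunkard_preferred``; adds ``bmi``, ``bmi_category``, ``bid``,
    ``bid_degree``, ``bid_group``, ``perception_score``,
    ``correct_perception``.
    """
    out = df.copy()
    out["bmi"] = [
        compute_bmi(w, h) for w, h in zip(df["weight_kg"], df["height_m"])
    ]
    out["bmi_category"] = [classify_bmi(b) for b in out["bmi"]]
    images = [
        body_image_dissatisfaction(c, p)
        for c, p in zip(df["stunkard_current"], df["stunkard_preferred"])
    ]
    out["bid"] = [im.bid for im in images]
    out["bid_degree"] = [im.degree for im in images]
    out["bid_group"] = [im.bid_group for im in images]
    out["perception_score"] = [
        weight_perception(c, b) for c, b in zip(df["stunkard_current"], out["bmi"])
    ]
    out["correct_perception"] = (out["perception_score"] == 0).astype(int)
    return out


def _check_figure(figure: int) -> None:
    if not float(figure).is_integer() or not 1 <= int(figure) <= 9:
        raise InvalidFigureError(
            f"silhouette figure must be an integer in 1..9, got {figure!r}"
        )
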