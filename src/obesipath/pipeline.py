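"""Subject-level scoring orchestration shared by the CLI and library users.

Takes raw survey rows (the column contract of ``cohort.generate_cohort``)
and appends every derived variable the path model consumes: BMI and its
category, ATOP/BAOP scores, body-image dissatisfaction, weight perception,
and the prospect-theory parameters inverted from the 35 lottery choices.
Subjects with non-monotone lottery choice vectors cannot be bracketed and
are excluded with a logged warning (mirroring the discard of incomplete
surveys in field practice).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import anthropometrics, elicitation, scales
from .errors import InconsistencyError, MultipleSwitchError, ShapeError

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "age", "female", "married", "university", "income_low", "diet",
    "weight_kg", "height_m", "stunkard_current", "stunkard_preferred",
)


def score_subjects(
    df: pd.DataFrame,
    design: elicitation.LotteryDesign | None = None,
) -> tuple[pd.DataFrame, int]:
    """Fully scored subject table and the number of excluded subjects."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ShapeError(f"missing required column(s): {missing}")
    design = design or elicitation.default_design()
    out = anthropometrics.score_frame(df)
    out = scales.score_frame(out)
    out = out.rename(columns={"atop_score": "atop", "baop_score": "baop"})

    choice_cols = [f"choice_{i}" for i in range(1, 36)]
    missing = [c for c in choice_cols if c not in df.columns]
    if missing:
        raise ShapeError(f"missing required column(s): {missing}")
    records, keep = [], []
    for idx, row in zip(df.index, df[choice_cols].to_numpy(dtype=int)):
        try:
            cv = elicitation.ChoiceVector(tuple(int(c) for c in row))
            est = elicitation.estimate_from_choices(cv, design)
        except (MultipleSwitchError, InconsistencyError) as exc:
            log.warning("subject %s excluded: %s", idx, exc)
            continue
        keep.append(idx)
        records.append({
            "risk_aversion": est.params.sigma,
            "loss_aversion": est.params.lam,
            "prob_weighting": est.params.gamma,
            "risk_category": est.risk_category,
            "loss_category": est.loss_category,
        })
    n_excluded = len(df) - len(keep)
    if n_excluded:
        log.warning("excluded %d of %d subjects (non-invertible choices)",
                    n_excluded, len(df))
    scored = out.loc[keep].copy()
    for col in ("risk_aversion", "loss_aversion", "prob_weighting",
                "risk_category", "loss_category"):
        scored[col] = [r[col] for r in records]
    return scored, n_excluded


def descriptive_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Sample description: category percentages, then Mean/Min/Max/Std. Dev."""
    rows = []
    for label, col in (
        ("Gender (Female = 1)", "female"),
        ("Marital status (Married = 1)", "married"),
        ("Education (University = 1)", "university"),
        ("Income Levels (<1,500 = 1)", "income_low"),
        ("Number of respondents on Diet", "diet"),
    ):
        rows.append({"Variable": label,
                     "Percentage": 100.0 * scored[col].mean(),
                     "Mean": np.nan, "Min": np.nan, "Max": np.nan,
                     "Std. Dev.": np.nan})
    for label, col in (
        ("Age", "age"),
        ("Average risk aversion coefficient", "risk_aversion"),
        ("Average loss aversion coefficient", "loss_aversion"),
        ("Body mass index", "bmi"),
        ("Degree of body image dissatisfaction", "bid_degree"),
        ("Belief about Obese People (BAOP)", "baop"),
        ("Attitude toward Obese Persons (ATOP)", "atop"),
    ):
        s = scored[col].astype(float)
        rows.append({"Variable": label, "Percentage": np.nan,
                     "Mean": s.mean(), "Min": s.min(), "Max": s.max(),
                     "Std. Dev.": s.std(ddof=1)})
    for cat in anthropometrics.CATEGORIES:
        rows.append({
            "Variable": f"Weight status: {cat}",
            "Percentage": 100.0 * (scored["bmi_category"] == cat).mean(),
            "Mean": np.nan, "Min": np.nan, "Max": np.nan, "Std. Dev.": np.nan,
        })
    return pd.DataFrame(rows)
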