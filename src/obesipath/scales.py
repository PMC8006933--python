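"""Scoring of the ATOP and BAOP Likert instruments.

Both instruments are scored by the same three-step rule: reverse-keyed items
are multiplied by -1, all item values are summed, and a fixed offset is added
so the score is non-negative.  For ATOP (Attitudes Toward Obese Persons, 20
items, offset 60) higher scores mean more positive attitudes; for BAOP
(Beliefs About Obese Persons, 8 items, offset 24) higher scores mean a
stronger belief that obesity is not under volitional control.

Items are answered on the 6-point scale {-3, -2, -1, +1, +2, +3}; a neutral
0 can be admitted via ``allow_zero=True`` when building a definition.  With
the 6-point scale the attainable ranges are exactly 0-120 (ATOP) and 0-48
(BAOP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidResponseError, ShapeError

_SIX_POINT = frozenset({-3, -2, -1, 1, 2, 3})


@dataclass(frozen=True)
class ScaleDefinition:
    """A Likert instrument: item count, reverse-keyed items, score offset."""

    name: str
    n_items: int
    reversed_items: frozenset[int]
    offset: int
    admissible_responses: frozenset[int] = field(default=_SIX_POINT)

    def __post_init__(self) -> None:
        if not self.reversed_items <= set(range(1, self.n_items + 1)):
            raise ValueError(
                f"{self.name}: reversed items {sorted(self.reversed_items)} "
                f"outside 1..{self.n_items}"
            )

    @property
    def max_score(self) -> int:
        m = max(abs(r) for r in self.admissible_responses)
        return self.n_items * m + self.offset

    def with_zero(self) -> "ScaleDefinition":
        """Same instrument admitting a neutral 0 response."""
        return ScaleDefinition(
            self.name,
            self.n_items,
            self.reversed_items,
            self.offset,
            self.admissible_responses | {0},
        )


#: ATOP: reverse-keyed items 2-6, 10-12, 14-16, 19, 20; offset 60.
ATOP = ScaleDefinition(
    "ATOP", 20, frozenset({2, 3, 4, 5, 6, 10, 11, 12, 14, 15, 16, 19, 20}), 60
)

#: BAOP: reverse-keyed items 1, 3-6, 8; offset 24.
BAOP = ScaleDefinition("BAOP", 8, frozenset({1, 3, 4, 5, 6, 8}), 24)


@dataclass(frozen=True)
class ScaleScore:
    raw_sum: int  # post-reversal sum of item responses
    score: int  # raw_sum + offset


def score_scale(responses, definition: ScaleDefinition) -> ScaleScore:
    """Apply the three-step scoring rule to one response vector."""
    resp = np.asarray(responses)
    if resp.ndim != 1 or resp.shape[0] != definition.n_items:
        raise ShapeError(
            f"{definition.name} expects {definition.n_items} responses, "
            f"got shape {resp.shape}"
        )
    if not np.all(np.isin(resp, list(definition.admissible_responses))):
        bad = resp[~np.isin(resp, list(definition.admissible_responses))]
        raise InvalidResponseError(
            f"{definition.name}: inadmissible response(s) {bad.tolist()}"
        )
    signs = np.ones(definition.n_items, dtype=int)
    signs[[i - 1 for i in definition.reversed_items]] = -1
    raw = int(np.sum(signs * resp))
    return ScaleScore(raw, raw + definition.offset)


def score_atop(responses) -> ScaleScore:
    """ATOP score (0-120); higher = more positive attitudes toward obese persons."""
    return score_scale(responses, ATOP)


def score_baop(responses) -> ScaleScore:
    """BAOP score (0-48); higher = stronger belief obesity is uncontrollable."""
    return score_scale(responses, BAOP)


def score_frame(df: pd.DataFrame, atop: ScaleDefinition = ATOP,
                baop: ScaleDefinition = BAOP) -> pd.DataFrame:
    """Append ``atop_score`` and ``baop_score`` to a table with item columns
    ``atop_1..atop_{n}`` / ``baop_1..baop_{n}``."""
    out = df.copy()
    for definition, prefix, col in (
        (atop, "atop", "atop_score"),
        (baop, "baop", "baop_score"),
    ):
        cols = [f"{prefix}_{i}" for i in range(1, definition.n_items + 1)]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ShapeError(f"missing item columns: {missing}")
        out[col] = [
            score_scale(row, definition).score
            for row in df[cols].to_numpy()
        ]
    return out
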