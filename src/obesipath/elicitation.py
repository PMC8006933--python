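"""Prospect-theory risk/loss-aversion elicitation from lottery menus.

The instrument is a three-series multiple price list in the tradition of
Tanaka, Camerer and Nguyen: series 1 and 2 each present 14 binary choices
between a safe Plan A and a risky Plan B whose high payoff escalates down the
rows; series 3 presents 7 mixed gain/loss choices at 50/50 odds.  A rational
subject chooses Plan A for some rows and then switches to Plan B; the pair of
switch rows in series 1 and 2 identifies the value-curvature sigma and the
Prelec probability-weighting exponent gamma, and the series-3 switch row
brackets the loss-aversion multiplier lambda.

Preferences follow the prospect-theory value function

    v(z) = z**sigma            for z >= 0
    v(z) = -lam * (-z)**sigma  for z < 0

with Prelec decision weights w(p) = exp(-(-ln p)**gamma).  For a binary
prospect whose outcomes share a sign, w(p) is applied to the stated
probability of the first (larger-magnitude) outcome and 1 - w(p) to the
other; for a mixed gain/loss prospect the gain part is weighted by w(p) and
the loss part by w(1 - p), as in cumulative prospect theory.  Because every
series-3 row has p = 0.5 in both plans, the mixed-prospect weights cancel in
the comparison and lambda inference does not depend on gamma.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import optimize

from .errors import (
    InconsistencyError,
    InvalidParameterError,
    InvalidProbabilityError,
    MultipleSwitchError,
    ShapeError,
)

log = logging.getLogger(__name__)

#: Plausibility bounds used for interval clipping and the inversion grid.
SIGMA_BOUNDS = (0.05, 2.0)
GAMMA_BOUNDS = (0.05, 2.0)
LAMBDA_BOUNDS = (0.0, 12.0)
_GRID_STEP = 0.01


@dataclass(frozen=True)
class Prospect:
    """Binary prospect: payoff ``x`` with probability ``p``, else ``y``."""

    x: float
    y: float
    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise InvalidProbabilityError(f"p must lie in [0, 1], got {self.p}")


@dataclass(frozen=True)
class PTParams:
    """Prospect-theory parameters: curvature, loss aversion, prob. weighting."""

    sigma: float
    lam: float
    gamma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if not np.isfinite(self.lam) or self.lam < 0:
            raise InvalidParameterError(f"lam must be >= 0, got {self.lam}")
        if not np.isfinite(self.gamma) or not 0 < self.gamma <= 2:
            raise InvalidParameterError(
                f"gamma must lie in (0, 2], got {self.gamma}"
            )


def prelec_weight(p, gamma: float):
    """Prelec probability weight w(p) = exp(-(-ln p)**gamma); w(0)=0, w(1)=1."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    pos = p > 0
    with np.errstate(divide="ignore"):
        out[pos] = np.exp(-((-np.log(p[pos])) ** gamma))
    return out if out.ndim else float(out)


def value_function(z, sigma: float, lam: float):
    """Prospect-theory value: z**sigma for gains, -lam*(-z)**sigma for losses."""
    z = np.asarray(z, dtype=float)
    out = np.where(z >= 0, np.abs(z) ** sigma, -lam * np.abs(z) ** sigma)
    return out if out.ndim else float(out)


def prospect_value(pr: Prospect, params: PTParams) -> float:
    """Subjective value of a binary prospect under (sigma, lam, gamma).

    With sigma = lam = gamma = 1 this reduces exactly to expected value.
    """
    w = prelec_weight(pr.p, params.gamma)
    vx = value_function(pr.x, params.sigma, params.lam)
    vy = value_function(pr.y, params.sigma, params.lam)
    if pr.x * pr.y < 0:  # mixed gain/loss: separate weights per sign rank
        wy = prelec_weight(1.0 - pr.p, params.gamma)
        return float(w * vx + wy * vy)
    return float(w * vx + (1.0 - w) * vy)


@dataclass(frozen=True)
class LotteryRow:
    plan_a: Prospect
    plan_b: Prospect


@dataclass
class LotteryDesign:
    """Three series of Plan A / Plan B rows (14 + 14 + 7 by default)."""

    series1: list[LotteryRow]
    series2: list[LotteryRow]
    series3: list[LotteryRow]
    _switch_cache: dict | None = field(default=None, repr=False, compare=False)

    @property
    def series(self) -> tuple[list[LotteryRow], ...]:
        return (self.series1, self.series2, self.series3)

    @property
    def n_rows(self) -> int:
        return sum(len(s) for s in self.series)

    def to_dict(self) -> dict:
        def row(r: LotteryRow) -> dict:
            return {
                "xA": r.plan_a.x, "yA": r.plan_a.y, "pA": r.plan_a.p,
                "xB": r.plan_b.x, "yB": r.plan_b.y, "pB": r.plan_b.p,
            }

        return {f"series{i+1}": [row(r) for r in s]
                for i, s in enumerate(self.series)}

    def save(self, path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def from_dict(cls, d: dict) -> "LotteryDesign":
        def rows(lst) -> list[LotteryRow]:
            return [
                LotteryRow(
                    Prospect(r["xA"], r["yA"], r["pA"]),
                    Prospect(r["xB"], r["yB"], r["pB"]),
                )
                for r in lst
            ]

        return cls(rows(d["series1"]), rows(d["series2"]), rows(d["series3"]))

    @classmethod
    def load(cls, path) -> "LotteryDesign":
        path = Path(path)
        d = (json.loads(path.read_text()) if path.suffix == ".json"
             else yaml.safe_load(path.read_text()))
        return cls.from_dict(d)


def default_design() -> LotteryDesign:
    """Bundled three-series design (euro payoffs).

    Series 1: Plan A pays 4.0 with p=0.30 else 1.0; Plan B pays an escalating
    high amount with p=0.10 else 0.50.  Series 2: Plan A pays 4.0 with p=0.90
    else 3.0; Plan B escalates with p=0.70 else 0.50.  Series 3 mixes gains
    and losses at 50/50 odds in both plans.
    """
    s1_high = [6.8, 7.5, 8.3, 9.3, 10.6, 12.5, 15.0, 18.5,
               22.0, 30.0, 40.0, 60.0, 100.0, 170.0]
    s2_high = [4.2, 4.4, 4.6, 4.8, 5.0, 5.2, 5.4, 5.6,
               6.0, 6.5, 7.0, 8.0, 9.0, 11.0]
    s3 = [  # (gain A, loss A, gain B, loss B)
        (2.5, -0.4, 3.0, -2.1),
        (0.4, -0.4, 3.0, -2.1),
        (0.1, -0.4, 3.0, -2.1),
        (0.1, -0.4, 3.0, -1.6),
        (0.1, -0.8, 3.0, -1.6),
        (0.1, -0.8, 3.0, -1.4),
        (0.1, -0.8, 3.0, -1.1),
    ]
    series1 = [
        LotteryRow(Prospect(4.0, 1.0, 0.30), Prospect(h, 0.5, 0.10))
        for h in s1_high
    ]
    series2 = [
        LotteryRow(Prospect(4.0, 3.0, 0.90), Prospect(h, 0.5, 0.70))
        for h in s2_high
    ]
    series3 = [
        LotteryRow(Prospect(ga, la, 0.5), Prospect(gb, lb, 0.5))
        for ga, la, gb, lb in s3
    ]
    return LotteryDesign(series1, series2, series3)


@dataclass(frozen=True)
class ChoiceVector:
    """35 binary choices (0 = Plan A, 1 = Plan B) in design row order."""

    choices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.choices) != 35 or any(c not in (0, 1) for c in self.choices):
            raise ShapeError("ChoiceVector needs 35 binary (0/1) choices")

    def by_series(self, design: LotteryDesign) -> list[tuple[int, ...]]:
        out, k = [], 0
        for s in design.series:
            out.append(self.choices[k:k + len(s)])
            k += len(s)
        return out


def simulate_choices(
    design: LotteryDesign,
    params: PTParams,
    noise: float = 0.0,
    seed: int | None = None,
) -> ChoiceVector:
    """Choices implied by ``params`` on every design row.

    With ``noise == 0`` the choice is the deterministic argmax of prospect
    value, with indifference resolved to Plan A (the safe plan).  With
    ``noise > 0`` Plan B is chosen with logistic probability
    ``1 / (1 + exp(-(V_B - V_A)/noise))``, reproducibly under ``seed``.
    """
    if noise < 0:
        raise InvalidParameterError(f"noise must be >= 0, got {noise}")
    rng = np.random.default_rng(seed)
    out: list[int] = []
    for series in design.series:
        for row in series:
            diff = prospect_value(row.plan_b, params) - prospect_value(
                row.plan_a, params
            )
            if noise == 0:
                out.append(1 if diff > 0 else 0)
            else:
                out.append(int(rng.random() < 1.0 / (1.0 + np.exp(-diff / noise))))
    return ChoiceVector(tuple(out))


def infer_switchpoints(
    choices: ChoiceVector, design: LotteryDesign | None = None
) -> tuple[int, int, int]:
    """First Plan-B row per series (1-based); ``n+1`` if Plan B is never chosen.

    Raises
    ------
    MultipleSwitchError
        If any series is not of the form A...A B...B (including all-A or
        all-B) — a subject who switches back cannot be bracketed.
    """
    design = design or default_design()
    points = []
    for i, series_choices in enumerate(choices.by_series(design), start=1):
        arr = np.asarray(series_choices)
        first_b = int(np.argmax(arr)) + 1 if arr.any() else len(arr) + 1
        if arr.any() and not np.all(arr[first_b - 1:] == 1):
            raise MultipleSwitchError(
                f"series {i}: non-monotone choice pattern {arr.tolist()}"
            )
        points.append(first_b)
    return tuple(points)


@dataclass(frozen=True)
class PTEstimate:
    """Point estimates plus interval bounds recovered from switch rows."""

    params: PTParams
    sigma_interval: tuple[float, float]
    gamma_interval: tuple[float, float]
    lam_interval: tuple[float, float]
    switchpoints: tuple[int, int, int]
    censored: bool  # any series all-A or all-B

    @property
    def risk_category(self) -> str:
        """Interval-aware: neutral whenever the sigma interval straddles 1."""
        lo, hi = self.sigma_interval
        if lo <= 1.0 <= hi:
            return "risk_neutral"
        return "risk_averse" if hi < 1.0 else "risk_loving"

    @property
    def loss_category(self) -> str:
        return "loss_averse" if self.params.lam >= 1.0 else "not_loss_averse"


def categorize(params: PTParams) -> tuple[str, str]:
    """Point categorisation with thresholds exactly at 1."""
    if params.sigma < 1:
        risk = "risk_averse"
    elif params.sigma == 1:
        risk = "risk_neutral"
    else:
        risk = "risk_loving"
    loss = "loss_averse" if params.lam >= 1 else "not_loss_averse"
    return risk, loss


def _gain_series_values(series: list[LotteryRow], sigma, gamma):
    """V_A - V_B per row on a (sigma, gamma) grid; shapes broadcast."""
    diffs = []
    for row in series:
        da = _plan_value(row.plan_a, sigma, gamma)
        db = _plan_value(row.plan_b, sigma, gamma)
        diffs.append(da - db)
    return diffs


def _plan_value(pr: Prospect, sigma, gamma):
    w = np.exp(-((-np.log(pr.p)) ** gamma)) if pr.p > 0 else 0.0
    vx = np.sign(pr.x) * np.abs(pr.x) ** sigma  # gains only in series 1/2
    vy = np.sign(pr.y) * np.abs(pr.y) ** sigma
    return w * vx + (1.0 - w) * vy


def _switch_table(design: LotteryDesign):
    """Implied (s1, s2) switch rows over the (sigma, gamma) inversion grid.

    Cached on the design instance; the grid spans the plausibility bounds at
    step 0.01 and uses exactly the same preference rule as simulate_choices
    (ties to Plan A).
    """
    if design._switch_cache is not None:
        return design._switch_cache
    sig = np.round(np.arange(SIGMA_BOUNDS[0], SIGMA_BOUNDS[1] + 1e-9, _GRID_STEP), 10)
    gam = np.round(np.arange(GAMMA_BOUNDS[0], GAMMA_BOUNDS[1] + 1e-9, _GRID_STEP), 10)
    S, G = np.meshgrid(sig, gam, indexing="ij")
    tables = []
    for series in (design.series1, design.series2):
        diffs = np.stack(_gain_series_values(series, S, G))  # rows x grid
        prefers_b = diffs < 0  # strict, ties go to Plan A
        first_b = np.where(
            prefers_b.any(axis=0),
            prefers_b.argmax(axis=0) + 1,
            len(series) + 1,
        )
        tables.append(first_b)
    design._switch_cache = (sig, gam, tables[0], tables[1])
    return design._switch_cache


def _lambda_bounds(design: LotteryDesign, sigma: float) -> np.ndarray:
    """Per-row lambda indifference bound in series 3 (given sigma).

    Plan A is preferred at row r iff lam >= b_r; the bounds increase down the
    rows, so a switch at row s brackets lam in [b_{s-1}, b_s].
    """
    b = []
    for row in design.series3:
        gain_gap = abs(row.plan_b.x) ** sigma - abs(row.plan_a.x) ** sigma
        loss_gap = abs(row.plan_b.y) ** sigma - abs(row.plan_a.y) ** sigma
        b.append(gain_gap / loss_gap)
    return np.asarray(b)


def estimate_params(
    switchpoints: Sequence[int], design: LotteryDesign | None = None
) -> PTEstimate:
    """Invert switch rows to (sigma, gamma, lambda) with interval bounds.

    (sigma, gamma) intervals enumerate the grid cells whose implied series-1/2
    switch rows reproduce the observed ones; the point estimate solves the two
    switch-row indifference equations where possible and is clipped into the
    feasible box.  lambda is bracketed by the series-3 adjacent-row
    inequalities at the sigma point estimate and reported as the interval
    midpoint.  Censored (never/always switch) series yield one-sided
    intervals with a boundary-plus-half-cell point convention.
    """
    design = design or default_design()
    s1, s2, s3 = (int(s) for s in switchpoints)
    n1, n2, n3 = (len(s) for s in design.series)
    if not (1 <= s1 <= n1 + 1 and 1 <= s2 <= n2 + 1 and 1 <= s3 <= n3 + 1):
        raise InconsistencyError(f"switch rows {switchpoints} out of range")

    sig, gam, t1, t2 = _switch_table(design)
    mask = (t1 == s1) & (t2 == s2)
    if not mask.any():
        raise InconsistencyError(
            f"no (sigma, gamma) in the plausibility region reproduces "
            f"switch rows s1={s1}, s2={s2}"
        )
    S, G = np.meshgrid(sig, gam, indexing="ij")
    # pad by one grid step: the continuous cell boundary can overhang the
    # outermost matching grid point by up to one step
    sig_lo = max(float(S[mask].min()) - _GRID_STEP, SIGMA_BOUNDS[0])
    sig_hi = min(float(S[mask].max()) + _GRID_STEP, SIGMA_BOUNDS[1])
    gam_lo = max(float(G[mask].min()) - _GRID_STEP, GAMMA_BOUNDS[0])
    gam_hi = min(float(G[mask].max()) + _GRID_STEP, GAMMA_BOUNDS[1])
    censored = s1 in (1, n1 + 1) or s2 in (1, n2 + 1)

    sigma_pt, gamma_pt = _point_estimate(
        design, s1, s2, (sig_lo, sig_hi), (gam_lo, gam_hi), censored
    )

    # lambda inequalities hold at the (unknown) true sigma: evaluate the
    # switch-row bounds across the whole sigma interval
    sig_span = np.linspace(sig_lo, sig_hi, 50)
    all_bounds = np.array([_lambda_bounds(design, s) for s in sig_span])
    bounds_pt = _lambda_bounds(design, sigma_pt)
    if s3 == 1:  # always Plan B: lam below the first bound
        lam_lo, lam_hi = LAMBDA_BOUNDS[0], float(all_bounds[:, 0].max())
        lam_pt = 0.5 * (LAMBDA_BOUNDS[0] + float(bounds_pt[0]))
        lam_censored = True
    elif s3 == n3 + 1:  # never switched: lam above the last finite bound
        lam_lo, lam_hi = float(all_bounds[:, -1].min()), LAMBDA_BOUNDS[1]
        half_cell = 0.5 * float(bounds_pt[-1] - bounds_pt[-2])
        lam_pt = min(float(bounds_pt[-1]) + half_cell, LAMBDA_BOUNDS[1])
        lam_censored = True
    else:
        lam_lo = float(all_bounds[:, s3 - 2].min())
        lam_hi = float(all_bounds[:, s3 - 1].max())
        lam_pt = 0.5 * (float(bounds_pt[s3 - 2]) + float(bounds_pt[s3 - 1]))
        lam_censored = False

    params = PTParams(sigma_pt, lam_pt, gamma_pt)
    return PTEstimate(
        params=params,
        sigma_interval=(sig_lo, sig_hi),
        gamma_interval=(gam_lo, gam_hi),
        lam_interval=(lam_lo, lam_hi),
        switchpoints=(s1, s2, s3),
        censored=censored or lam_censored,
    )


def _point_estimate(design, s1, s2, sig_iv, gam_iv, censored):
    """Solve the switch-row indifference system; fall back to the box centre."""
    centre = (0.5 * (sig_iv[0] + sig_iv[1]), 0.5 * (gam_iv[0] + gam_iv[1]))
    n1, n2 = len(design.series1), len(design.series2)
    if censored or s1 > n1 or s2 > n2:
        return centre

    row1, row2 = design.series1[s1 - 1], design.series2[s2 - 1]

    def system(theta):
        sg, gm = theta
        if sg <= 0 or gm <= 0:
            return [1e3, 1e3]
        return [
            _plan_value(row1.plan_a, sg, gm) - _plan_value(row1.plan_b, sg, gm),
            _plan_value(row2.plan_a, sg, gm) - _plan_value(row2.plan_b, sg, gm),
        ]

    try:
        sol, info, ier, _ = optimize.fsolve(system, centre, full_output=True)
        if ier == 1:
            sigma_pt = float(np.clip(sol[0], *sig_iv))
            gamma_pt = float(np.clip(sol[1], *gam_iv))
            return sigma_pt, gamma_pt
    except Exception:  # pragma: no cover - fsolve rarely raises
        pass
    log.debug("indifference solve failed at s1=%d s2=%d; using box centre", s1, s2)
    return centre


def estimate_from_choices(
    choices: ChoiceVector, design: LotteryDesign | None = None
) -> PTEstimate:
    """Convenience: infer switch rows then invert them."""
    design = design or default_design()
    return estimate_params(infer_switchpoints(choices, design), design)
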