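"""Seed-reproducible synthetic survey cohorts with known ground truth.

Two layers are provided.

``simulate_paths`` draws standardized variables from a declared structural
edge list (linear / quadratic / s-curve / exponential parent transforms).
Residual noise is sample-orthogonalized against each equation's transformed
parents and scaled so every endogenous column has sample variance exactly
one; the configured coefficients are then *exact* standardized path
coefficients of the generating equations, which makes parameter-recovery
tests sharp.

``generate_cohort`` builds full survey records around that machinery:
demographics matching the marginals of the adult cohort the default model
targets (70% female, 69% married, mean age 45.8, mean BMI 25.17, ...),
ATOP/BAOP item vectors whose scored totals track latent attitude levels,
Stunkard silhouettes consistent with measured BMI up to configurable
misperception noise, and 35 lottery choices simulated from per-subject true
prospect-theory parameters.  The ground truth (per-edge coefficients and
forms, per-subject sigma/lambda/gamma, latent scale levels) is exported
alongside every cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import elicitation
from .anthropometrics import BMI_CUTOFFS
from .errors import ConfigError
from .scales import ATOP, BAOP, ScaleDefinition
from .warp import _standardize_vec

#: Supported generating transforms of a standardized parent, and the shape
#: label each should produce in relationship-curve classification.
FORMS = {
    "linear": (lambda z: z, "linear"),
    "quadratic": (lambda z: z**2, "U"),
    "inverted_u": (lambda z: -(z**2), "inverted-U"),
    "s_curve": (lambda z: z**3 - 1.5 * z, "S"),
    "cubic": (lambda z: z**3 - 1.5 * z, "S"),
    "exponential": (lambda z: np.exp(0.9 * z), "exponential-like"),
}


@dataclass(frozen=True)
class StructuralEdge:
    source: str
    target: str
    coef: float
    form: str = "linear"

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ConfigError(f"unknown form {self.form!r}")


def _transform(z: np.ndarray, form: str) -> np.ndarray:
    g, _ = FORMS[form]
    out = g(z)
    return _standardize_vec(out) if form != "linear" else out


def simulate_paths(
    edges: list[StructuralEdge],
    n: int,
    seed: int | None = None,
    noise_scale: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Standardized data from a structural edge list, plus exact ground truth.

    With ``noise_scale = 1`` the residual of each equation tops the variance
    up to exactly one, so the configured coefficients are the true
    standardized path coefficients.  With ``noise_scale = 0`` the equations
    are deterministic and the implied standardized coefficients (reported in
    the returned truth) are the configured ones divided by the sd of the
    deterministic part.
    """
    if noise_scale < 0:
        raise ConfigError(f"noise_scale must be >= 0, got {noise_scale}")
    if n < 10:
        raise ConfigError(f"need n >= 10, got {n}")
    rng = np.random.default_rng(seed)
    targets: dict[str, list[StructuralEdge]] = {}
    for e in edges:
        targets.setdefault(e.target, []).append(e)
    variables: list[str] = []
    for e in edges:
        for v in (e.source, e.target):
            if v not in variables:
                variables.append(v)
    exogenous = [v for v in variables if v not in targets]

    # Kahn topological order over endogenous variables
    order: list[str] = list(exogenous)
    remaining = dict(targets)
    while remaining:
        ready = [t for t, parents in remaining.items()
                 if all(p.source in order for p in parents)]
        if not ready:
            raise ConfigError(f"structural edges contain a cycle: {sorted(remaining)}")
        for t in sorted(ready):
            order.append(t)
            del remaining[t]

    cols: dict[str, np.ndarray] = {}
    truth_edges = []
    for v in order:
        if v in exogenous:
            cols[v] = _standardize_vec(rng.standard_normal(n))
            continue
        parents = targets[v]
        G = np.column_stack([
            _transform(cols[p.source], p.form) for p in parents
        ])
        c = np.array([p.coef for p in parents])
        lin = G @ c
        v_det = float(lin.var(ddof=1))
        if noise_scale > 0:
            resid_var = noise_scale**2 * max(1.0 - v_det, 0.0)
            if v_det >= 1.0:
                raise ConfigError(
                    f"{v}: deterministic variance {v_det:.3f} >= 1; "
                    "reduce coefficients"
                )
            u = rng.standard_normal(n)
            basis = np.column_stack([np.ones(n), G])
            u = u - basis @ np.linalg.lstsq(basis, u, rcond=None)[0]
            u = _standardize_vec(u)
            y = lin + np.sqrt(resid_var) * u
            scale = float(y.std(ddof=1))
            y = y / scale
        else:
            scale = float(lin.std(ddof=1))
            y = lin / scale
        cols[v] = y
        for p in parents:
            truth_edges.append({
                "source": p.source, "target": p.target, "form": p.form,
                "coef": p.coef, "standardized_coef": p.coef / scale,
                "expected_shape": FORMS[p.form][1] if p.coef > 0 else
                _flip_shape(FORMS[p.form][1]),
            })
    data = pd.DataFrame({v: cols[v] for v in variables})
    truth = {"edges": truth_edges, "n": n, "seed": seed,
             "noise_scale": noise_scale}
    return data, truth


def _flip_shape(label: str) -> str:
    flips = {"U": "inverted-U", "inverted-U": "U", "S": "inverted-S",
             "inverted-S": "S"}
    return flips.get(label, label)


@dataclass
class CohortConfig:
    """Defaults mirror the marginals of the target adult survey population."""

    n_subjects: int = 172
    seed: int | None = None
    share_female: float = 0.70
    share_married: float = 0.69
    share_university: float = 0.36
    share_low_income: float = 0.32
    diet_base_rate: float = 0.24
    age_range: tuple[float, float] = (20.0, 70.0)
    age_mean: float = 45.8
    age_sd: float = 11.22
    bmi_mean: float = 25.17
    bmi_sd: float = 4.21
    sigma_mean: float = 0.58
    sigma_sd: float = 0.37
    lam_mean_log: float = 1.0
    lam_sd_log: float = 0.85
    gamma_mean: float = 0.70
    gamma_sd: float = 0.15
    atop_mean: float = 65.33
    atop_sd: float = 14.93
    baop_mean: float = 21.65
    baop_sd: float = 4.31
    bid_mean: float = 1.19
    bid_sd: float = 1.07
    misperception_rate: float = 0.30
    item_jitter: float = 1.5
    choice_noise: float = 0.0
    #: structural coefficients of the BMI equation (standardized scale)
    bmi_effects: dict = field(default_factory=lambda: {
        "age": (0.18, "s_curve"),
        "female": (-0.21, "linear"),
        "income_low": (0.12, "linear"),
        "married": (0.14, "linear"),
        "university": (-0.10, "linear"),
        "atop": (0.26, "s_curve"),
        "baop": (0.14, "s_curve"),
        "misperception": (0.12, "linear"),
        "risk_aversion": (0.16, "inverted_u"),
        "loss_aversion": (-0.05, "linear"),
    })
    bid_effect: float = 0.69  # BMI -> body-image dissatisfaction (exponential)
    diet_effect: float = 0.55  # BID -> dieting propensity (logit slope)
    atop_baop_effect: float = 0.35  # BAOP -> ATOP (exponential)
    lam_sigma_effect: float = -0.45  # risk aversion -> loss aversion (log scale)

    def validate(self) -> None:
        shares = {
            "share_female": self.share_female,
            "share_married": self.share_married,
            "share_university": self.share_university,
            "share_low_income": self.share_low_income,
            "diet_base_rate": self.diet_base_rate,
            "misperception_rate": self.misperception_rate,
        }
        for name, value in shares.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.n_subjects < 10:
            raise ConfigError(f"n_subjects must be >= 10, got {self.n_subjects}")
        for name in ("age_sd", "bmi_sd", "sigma_sd", "gamma_sd", "atop_sd",
                     "baop_sd", "bid_sd", "item_jitter", "choice_noise"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)


def _items_for_score(rng, score, definition: ScaleDefinition, jitter: float):
    """Raw item responses whose 3-step score approximates ``score``.

    Post-reversal values are drawn around score/n_items with uniform jitter,
    quantized to the admissible 6-point set, then un-reversed.
    """
    raw_target = score - definition.offset
    base = raw_target / definition.n_items
    vals = base + rng.uniform(-jitter, jitter, size=definition.n_items)
    vals = np.clip(np.round(vals), -3, 3).astype(int)
    zero = vals == 0
    vals[zero] = rng.choice([-1, 1], size=int(zero.sum()))
    signs = np.ones(definition.n_items, dtype=int)
    signs[[i - 1 for i in definition.reversed_items]] = -1
    return vals * signs  # reversal is its own inverse


_FIGURES_BY_RANK = {1: (1, 2), 2: (3, 4), 3: (5, 6, 7), 4: (8, 9)}


def _figure_for_bmi(bmi: float, rank_shift: int) -> int:
    rank = int(np.searchsorted(BMI_CUTOFFS, bmi, side="right")) + 1
    rank = int(np.clip(rank + rank_shift, 1, 4))
    figures = _FIGURES_BY_RANK[rank]
    edges = [0.0, *BMI_CUTOFFS, 50.0]
    lo, hi = edges[rank - 1], edges[rank]
    frac = np.clip((bmi - lo) / (hi - lo), 0.0, 0.999)
    return figures[int(frac * len(figures))]


def generate_cohort(config: CohortConfig | None = None):
    """Full synthetic survey table plus ground truth.

    Returns ``(subjects, truth)`` where ``subjects`` is one row per
    respondent in the shared column contract (demographics, weight/height,
    silhouettes, 20 + 8 item responses, 35 lottery choices) and ``truth``
    records everything the generator knew.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    female = (rng.random(n) < config.share_female).astype(int)
    married = (rng.random(n) < config.share_married).astype(int)
    university = (rng.random(n) < config.share_university).astype(int)
    income_low = (rng.random(n) < config.share_low_income).astype(int)
    age = _truncated_normal(rng, config.age_mean, config.age_sd,
                            *config.age_range, n)

    sigma = _truncated_normal(rng, config.sigma_mean, config.sigma_sd,
                              0.05, 1.5, n)
    gamma = _truncated_normal(rng, config.gamma_mean, config.gamma_sd,
                              0.35, 1.0, n)
    sigma_z = _standardize_vec(sigma)
    rho = config.lam_sigma_effect
    lam_latent = rho * _standardize_vec(sigma**0.5) + np.sqrt(
        max(1 - rho**2, 0.0)
    ) * rng.standard_normal(n)
    lam = np.clip(np.exp(config.lam_mean_log + config.lam_sd_log * lam_latent),
                  0.0, 11.79)

    baop_z = rng.standard_normal(n)
    r = config.atop_baop_effect
    atop_z = r * _standardize_vec(np.exp(0.9 * baop_z)) + np.sqrt(
        1 - r**2
    ) * rng.standard_normal(n)

    mis_rate = config.misperception_rate
    rank_shift = rng.choice(
        [-1, 0, 1], size=n, p=[mis_rate / 2, 1 - mis_rate, mis_rate / 2]
    )

    eff = config.bmi_effects
    drivers = {
        "age": _standardize_vec(age) if config.age_sd > 0 else np.zeros(n),
        "female": _bin_z(female),
        "income_low": _bin_z(income_low),
        "married": _bin_z(married),
        "university": _bin_z(university),
        "atop": _standardize_vec(atop_z),
        "baop": _standardize_vec(baop_z),
        "misperception": _bin_z((rank_shift != 0).astype(int)),
        "risk_aversion": sigma_z,
        "loss_aversion": _standardize_vec(lam),
    }
    contrib = np.zeros(n)
    for name, (coef, form) in eff.items():
        contrib += coef * _transform(drivers[name], form)
    v_det = float(contrib.var(ddof=1))
    if v_det >= 1.0:
        raise ConfigError("BMI structural coefficients imply variance >= 1")
    noise = rng.standard_normal(n)
    bmi_z = _standardize_vec(contrib + np.sqrt(1 - v_det) * noise)
    bmi = np.clip(config.bmi_mean + config.bmi_sd * bmi_z, 17.0, 46.5)

    height = np.where(
        female == 1,
        rng.normal(1.62, 0.06, n),
        rng.normal(1.76, 0.07, n),
    ).round(2)
    weight = (bmi * height**2).round(1)
    bmi = weight / height**2  # measured BMI, after instrument rounding

    b = config.bid_effect
    bid_latent = b * _standardize_vec(np.exp(0.8 * bmi_z)) + np.sqrt(
        1 - b**2
    ) * rng.standard_normal(n)
    bid_signed = np.clip(
        np.round(config.bid_mean + config.bid_sd * bid_latent), -3, 6
    ).astype(int)

    current = np.array([
        _figure_for_bmi(bm, sh) for bm, sh in zip(bmi, rank_shift)
    ])
    preferred = np.clip(current - bid_signed, 1, 9)

    bid_z = _standardize_vec((current - preferred).astype(float))
    logit0 = np.log(config.diet_base_rate / (1 - config.diet_base_rate))
    p_diet = 1.0 / (1.0 + np.exp(-(logit0 + config.diet_effect * bid_z)))
    diet = (rng.random(n) < p_diet).astype(int)

    atop_target = np.clip(
        np.round(config.atop_mean + config.atop_sd * _standardize_vec(atop_z)),
        0, 120,
    ).astype(int)
    baop_target = np.clip(
        np.round(config.baop_mean + config.baop_sd * _standardize_vec(baop_z)),
        0, 48,
    ).astype(int)
    atop_items = np.array([
        _items_for_score(rng, s, ATOP, config.item_jitter) for s in atop_target
    ])
    baop_items = np.array([
        _items_for_score(rng, s, BAOP, config.item_jitter) for s in baop_target
    ])

    design = elicitation.default_design()
    choice_rows = []
    for i in range(n):
        params = elicitation.PTParams(float(sigma[i]), float(lam[i]),
                                      float(gamma[i]))
        cv = elicitation.simulate_choices(
            design, params, noise=config.choice_noise,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        choice_rows.append(cv.choices)
    choices = np.array(choice_rows)

    subjects = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "age": np.round(age, 1),
        "female": female,
        "married": married,
        "university": university,
        "income_low": income_low,
        "diet": diet,
        "weight_kg": weight,
        "height_m": height,
        "stunkard_current": current,
        "stunkard_preferred": preferred,
    })
    for j in range(ATOP.n_items):
        subjects[f"atop_{j+1}"] = atop_items[:, j]
    for j in range(BAOP.n_items):
        subjects[f"baop_{j+1}"] = baop_items[:, j]
    for j in range(35):
        subjects[f"choice_{j+1}"] = choices[:, j]

    truth = {
        "config": _config_dict(config),
        "edges": [
            {"source": s, "target": "bmi", "coef": c, "form": f}
            for s, (c, f) in eff.items()
        ] + [
            {"source": "bmi", "target": "bid", "coef": config.bid_effect,
             "form": "exponential"},
            {"source": "bid", "target": "diet", "coef": config.diet_effect,
             "form": "logit-linear"},
            {"source": "baop", "target": "atop",
             "coef": config.atop_baop_effect, "form": "exponential"},
            {"source": "risk_aversion", "target": "loss_aversion",
             "coef": config.lam_sigma_effect, "form": "log-linear"},
        ],
        "subjects": {
            "sigma": sigma.tolist(),
            "lam": lam.tolist(),
            "gamma": gamma.tolist(),
            "atop_latent": atop_target.tolist(),
            "baop_latent": baop_target.tolist(),
            "rank_shift": rank_shift.tolist(),
        },
    }
    return subjects, truth


def _bin_z(x: np.ndarray) -> np.ndarray:
    """Standardize a 0/1 column, tolerating (rare) degenerate draws."""
    sd = x.std(ddof=1)
    if sd <= 1e-12:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["age_range"] = list(d["age_range"])
    return d


def export_fixture(subjects: pd.DataFrame, truth: dict, outdir) -> dict:
    """Write ``subjects.csv``, ``truth.json`` and ``design.yaml`` to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": outdir / "subjects.csv",
        "truth": outdir / "truth.json",
        "design": outdir / "design.yaml",
    }
    subjects.to_csv(paths["subjects"], index=False)
    paths["truth"].write_text(json.dumps(truth, indent=2))
    elicitation.default_design().save(paths["design"])
    return {k: str(v) for k, v in paths.items()}
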