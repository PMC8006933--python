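"""Robust non-linear ("warped") path analysis on observed variables.

Every variable is standardized (mean 0, sd 1, denominator n-1).  For each
structural equation, each incoming predictor is first *warped*: a low-order
polynomial of the criterion on the predictor is fitted by least squares
(degree 1 for ``linear``, 2 for ``quadratic``, 3 for ``s_curve``), the
predictor is replaced by the fitted function of itself, restandardized and
oriented (along the raw predictor when meaningfully correlated with it,
otherwise along the criterion).  All warped predictors of an equation
then enter one ordinary least-squares regression; its coefficients are the
standardized path coefficients.  Inference is by row resampling: the model is
refitted on B bootstrap samples, the standard error is the bootstrap sd and
the p-value refers beta/se to a t distribution with B-1 degrees of freedom
(two-tailed).

The module also computes the ten global fit and quality indices customary in
robust path analysis: APC, ARS, AARS (with bootstrap p-values), AVIF, AFVIF,
Tenenhaus GoF, SPR, RSCR, SSR and NLBCDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy import stats

from .errors import (
    CollinearityError,
    DegenerateVariableError,
    ModelSpecificationError,
    ShapeError,
)

log = logging.getLogger(__name__)

WARP_MODES = {"linear": 1, "quadratic": 2, "s_curve": 3}

#: Cohen effect-size bands for |beta * r|.
EFFECT_SIZE_BANDS = ((0.02, "small"), (0.15, "medium"), (0.35, "large"))

#: Condition-number threshold above which a warped block is rejected.
_COND_MAX = 1e8

#: Minimum |corr(warped, x)| for orienting the warped predictor along x;
#: below it (symmetric warps such as a pure U) orientation follows the
#: criterion instead, so the coefficient of a U-shaped effect is positive.
_ALIGN_MIN = 0.1


def _orient(w: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    r_x = float(np.corrcoef(w, x)[0, 1])
    if abs(r_x) >= _ALIGN_MIN:
        return -w if r_x < 0 else w
    r_y = float(np.corrcoef(w, y)[0, 1])
    return -w if r_y < 0 else w


def effect_size_label(f2: float) -> str:
    """Cohen band label for an effect size (small/medium/large, else negligible)."""
    label = "negligible"
    for threshold, name in EFFECT_SIZE_BANDS:
        if f2 >= threshold:
            label = name
    return label


@dataclass(frozen=True)
class Edge:
    """One hypothesized directed effect, with its warp mode and metadata."""

    source: str
    target: str
    mode: str = "s_curve"
    expected_sign: str = "any"  # '+', '-', or 'any'; metadata only
    name: str = ""

    def __post_init__(self) -> None:
        if self.mode not in WARP_MODES:
            raise ModelSpecificationError(
                f"unknown warp mode {self.mode!r}; choose from {sorted(WARP_MODES)}"
            )
        if self.expected_sign not in {"+", "-", "any"}:
            raise ModelSpecificationError(
                f"expected_sign must be '+', '-' or 'any', got {self.expected_sign!r}"
            )


@dataclass
class PathModel:
    """A directed edge list over named observed variables."""

    edges: list[Edge]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            key = (e.source, e.target)
            if key in seen:
                raise ModelSpecificationError(f"duplicate edge {key}")
            if e.source == e.target:
                raise ModelSpecificationError(f"self-loop on {e.source!r}")
            seen.add(key)

    @property
    def variables(self) -> list[str]:
        out: list[str] = []
        for e in self.edges:
            for v in (e.source, e.target):
                if v not in out:
                    out.append(v)
        return out

    @property
    def endogenous(self) -> list[str]:
        targets: list[str] = []
        for e in self.edges:
            if e.target not in targets:
                targets.append(e.target)
        return targets

    def predictors_of(self, target: str) -> list[Edge]:
        return [e for e in self.edges if e.target == target]

    def to_records(self) -> list[dict]:
        return [
            {
                "name": e.name,
                "source": e.source,
                "target": e.target,
                "mode": e.mode,
                "expected_sign": e.expected_sign,
            }
            for e in self.edges
        ]

    @classmethod
    def from_records(cls, records) -> "PathModel":
        return cls([
            Edge(
                source=r["source"],
                target=r["target"],
                mode=r.get("mode", "s_curve"),
                expected_sign=r.get("expected_sign", "any"),
                name=r.get("name", ""),
            )
            for r in records
        ])


def standardize(data: pd.DataFrame | np.ndarray):
    """Columns rescaled to mean 0 and sd 1 (denominator n-1).

    Raises
    ------
    DegenerateVariableError
        Naming the offending column if any column is (numerically) constant.
    """
    if isinstance(data, pd.DataFrame):
        arr, cols = data.to_numpy(dtype=float), list(data.columns)
    else:
        arr, cols = np.asarray(data, dtype=float), None
        if arr.ndim == 1:
            arr = arr[:, None]
    if arr.shape[0] < 3:
        raise ShapeError(f"need n >= 3 rows, got {arr.shape[0]}")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    bad = np.where(sd <= 1e-12 * np.maximum(1.0, np.abs(mean)))[0]
    if bad.size:
        name = cols[bad[0]] if cols else f"column {bad[0]}"
        raise DegenerateVariableError(f"zero-variance column: {name}")
    z = (arr - mean) / sd
    if isinstance(data, pd.DataFrame):
        return pd.DataFrame(z, columns=cols, index=data.index)
    return z if np.asarray(data).ndim > 1 else z[:, 0]


def _standardize_vec(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd <= 1e-12:
        raise DegenerateVariableError("zero-variance column")
    return (x - x.mean()) / sd


def warp_fit(x: np.ndarray, y: np.ndarray, mode: str) -> np.ndarray:
    """Polynomial coefficients (ascending) of the least-squares fit of y on x.

    Two-valued predictors are always fitted linearly: a polynomial through two
    support points is degenerate.  Singular higher-degree fits fall back to
    linear with a logged warning.
    """
    degree = WARP_MODES[mode]
    if x.shape[0] != y.shape[0]:
        raise ShapeError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] <= degree + 1:
        raise ShapeError(f"need n > degree + 1 = {degree + 1} observations")
    if degree > 1 and np.unique(x).size <= 2:
        degree = 1
    try:
        with np.errstate(all="ignore"):
            coef = npoly.polyfit(x, y, degree)
        if not np.all(np.isfinite(coef)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        log.warning("singular degree-%d fit; falling back to linear", degree)
        coef = npoly.polyfit(x, y, 1)
    return coef


def warp_edge(x, y, mode: str) -> np.ndarray:
    """Warped predictor: fitted polynomial of y on x, evaluated at x,
    restandardized, and sign-aligned with x.

    In ``linear`` mode the result equals the standardized x (up to sign of the
    slope being folded back, i.e. exactly x), since an affine image
    restandardizes to the original column.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coef = warp_fit(x, y, mode)
    fitted = npoly.polyval(x, coef)
    if fitted.std(ddof=1) <= 1e-12:
        log.warning("flat warp fit; falling back to linear predictor")
        return _standardize_vec(x)
    return _orient(_standardize_vec(fitted), x, y)


@dataclass(frozen=True)
class EdgeFit:
    edge: Edge
    beta: float
    corr: float  # Pearson correlation of warped predictor with criterion
    effect_size: float
    coef: tuple[float, ...]  # warp polynomial (ascending, on standardized x)
    x_range: tuple[float, float]
    se: float | None = None
    p: float | None = None

    @property
    def effect_label(self) -> str:
        return effect_size_label(self.effect_size)


@dataclass
class PathFit:
    model: PathModel
    edges: list[EdgeFit]
    r2: dict[str, float]
    adj_r2: dict[str, float]
    n: int
    indices: "FitIndices | None" = None
    bootstrap: "BootstrapResult | None" = None

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for ef in self.edges:
            rows.append({
                "name": ef.edge.name,
                "source": ef.edge.source,
                "target": ef.edge.target,
                "expected_sign": ef.edge.expected_sign,
                "beta": ef.beta,
                "se": ef.se,
                "p": ef.p,
                "effect_size": ef.effect_size,
                "effect_label": ef.effect_label,
                "stars": significance_stars(ef.p) if ef.p is not None else "",
                "sign_match": _sign_match(ef.beta, ef.edge.expected_sign),
            })
        return pd.DataFrame(rows)


def _sign_match(beta: float, expected: str) -> bool | None:
    if expected == "any":
        return None
    return (beta > 0) == (expected == "+")


def significance_stars(p: float) -> str:
    """Three-level scheme: *** p<0.01, ** p<0.05, * p<0.1."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def _check_model(data: pd.DataFrame, model: PathModel) -> None:
    missing = [v for v in model.variables if v not in data.columns]
    if missing:
        raise ModelSpecificationError(f"missing variables: {missing}")
    if not model.endogenous:
        raise ModelSpecificationError("model has no endogenous variable")


def _fit_arrays(z: dict[str, np.ndarray], model: PathModel, n: int):
    """Core estimator on pre-standardized column arrays."""
    edge_fits: list[EdgeFit] = []
    r2: dict[str, float] = {}
    adj_r2: dict[str, float] = {}
    for target in model.endogenous:
        incoming = model.predictors_of(target)
        y = z[target]
        cols, metas = [], []
        for e in incoming:
            x = z[e.source]
            coef = warp_fit(x, y, e.mode)
            fitted = npoly.polyval(x, coef)
            if fitted.std(ddof=1) <= 1e-12:
                w = x.copy()
                coef = np.array([0.0, 1.0])
            else:
                w = _orient(_standardize_vec(fitted), x, y)
            cols.append(w)
            metas.append((e, coef, x))
        X = np.column_stack(cols)
        if X.shape[1] > 1:
            cond = np.linalg.cond(X.T @ X / (n - 1))
            if cond > _COND_MAX:
                raise CollinearityError(
                    f"warped predictor block for {target!r} is collinear "
                    f"(condition number {cond:.2e})"
                )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sst = float(y @ y)
        r2_t = 1.0 - float(resid @ resid) / sst
        p = X.shape[1]
        r2[target] = r2_t
        adj_r2[target] = 1.0 - (1.0 - r2_t) * (n - 1) / (n - p - 1)
        for b, w, (e, coef, x) in zip(beta, cols, metas):
            r = float(np.dot(w, y) / (np.linalg.norm(w) * np.linalg.norm(y)))
            edge_fits.append(EdgeFit(
                edge=e,
                beta=float(b),
                corr=r,
                effect_size=abs(float(b) * r),
                coef=tuple(np.asarray(coef, dtype=float)),
                x_range=(float(x.min()), float(x.max())),
            ))
    order = {(e.source, e.target): i for i, e in enumerate(model.edges)}
    edge_fits.sort(key=lambda ef: order[(ef.edge.source, ef.edge.target)])
    return edge_fits, r2, adj_r2


def fit_model(data: pd.DataFrame, model: PathModel) -> PathFit:
    """Point estimates of all path coefficients, R^2 and effect sizes.

    ``data`` columns are standardized internally; coefficients are therefore
    standardized path coefficients.
    """
    _check_model(data, model)
    zdf = standardize(data[model.variables])
    n = len(zdf)
    max_in = max(len(model.predictors_of(t)) for t in model.endogenous)
    if n <= max_in + 1:
        raise ShapeError(f"need n > max in-degree + 1 = {max_in + 1}, got {n}")
    z = {v: zdf[v].to_numpy() for v in model.variables}
    edge_fits, r2, adj_r2 = _fit_arrays(z, model, n)
    return PathFit(model=model, edges=edge_fits, r2=r2, adj_r2=adj_r2, n=n)


@dataclass
class BootstrapResult:
    B: int
    seed: int | None
    betas: np.ndarray  # B x n_edges bootstrap path coefficients
    r2: np.ndarray     # B x n_endogenous
    adj_r2: np.ndarray
    se: np.ndarray
    p: np.ndarray


def bootstrap_inference(
    data: pd.DataFrame,
    model: PathModel,
    B: int = 5000,
    seed: int | None = None,
) -> BootstrapResult:
    """Row-resampling bootstrap standard errors and two-tailed t(B-1) p-values.

    Resamples with zero variance in any model variable are redrawn (at most
    10 retries each).  Reproducible under ``seed``.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    _check_model(data, model)
    point = fit_model(data, model)
    arr = data[model.variables].to_numpy(dtype=float)
    n = arr.shape[0]
    rng = np.random.default_rng(seed)
    n_edges = len(model.edges)
    endo = model.endogenous
    betas = np.empty((B, n_edges))
    r2s = np.empty((B, len(endo)))
    ar2s = np.empty((B, len(endo)))
    variables = model.variables
    for b in range(B):
        for attempt in range(11):
            idx = rng.integers(0, n, size=n)
            sample = arr[idx]
            sd = sample.std(axis=0, ddof=1)
            if np.all(sd > 1e-12):
                break
        else:
            raise DegenerateVariableError(
                "bootstrap resample still degenerate after 10 retries"
            )
        zcols = (sample - sample.mean(axis=0)) / sd
        z = {v: zcols[:, j] for j, v in enumerate(variables)}
        try:
            efits, r2, ar2 = _fit_arrays(z, model, n)
        except (CollinearityError, DegenerateVariableError):
            efits, r2, ar2 = None, None, None
        if efits is None:
            betas[b] = np.nan
            r2s[b] = np.nan
            ar2s[b] = np.nan
        else:
            betas[b] = [ef.beta for ef in efits]
            r2s[b] = [r2[t] for t in endo]
            ar2s[b] = [ar2[t] for t in endo]
    se = np.nanstd(betas, axis=0, ddof=1)
    point_betas = np.array([ef.beta for ef in point.edges])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, point_betas / se, np.inf * np.sign(point_betas))
    p = 2.0 * stats.t.sf(np.abs(t), df=B - 1)
    return BootstrapResult(B=B, seed=seed, betas=betas, r2=r2s, adj_r2=ar2s,
                           se=se, p=p)


def vif(block: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column given the others.

    VIF_j = 1 / (1 - R^2_j) from regressing column j on the remaining
    columns; a lone column has VIF 1.
    """
    arr = block.to_numpy(dtype=float) if isinstance(block, pd.DataFrame) else (
        np.asarray(block, dtype=float)
    )
    n, k = arr.shape
    if n <= k + 1:
        raise ShapeError(f"need n > k + 1 = {k + 1}, got n = {n}")
    if k == 1:
        return np.array([1.0])
    names = list(block.columns) if isinstance(block, pd.DataFrame) else [
        f"column {j}" for j in range(k)
    ]
    z = arr - arr.mean(axis=0)
    out = np.empty(k)
    for j in range(k):
        others = np.delete(z, j, axis=1)
        yj = z[:, j]
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        sst = float(yj @ yj)
        if sst <= 0:
            raise DegenerateVariableError(f"zero-variance column: {names[j]}")
        r2 = 1.0 - float(resid @ resid) / sst
        if r2 > 1 - 1e-12:
            raise CollinearityError(
                f"perfect collinearity involving {names[j]}: VIF is infinite"
            )
        out[j] = 1.0 / (1.0 - r2)
    return out


def full_collinearity_vif(data: pd.DataFrame, model: PathModel) -> dict[str, float]:
    """Full-collinearity VIF: each model variable on all the others."""
    _check_model(data, model)
    block = data[model.variables]
    return dict(zip(model.variables, vif(block)))


@dataclass(frozen=True)
class FitIndices:
    apc: float
    ars: float
    aars: float
    avif: float
    afvif: float
    gof: float
    spr: float
    rscr: float
    ssr: float
    nlbcdr: float
    apc_p: float | None = None
    ars_p: float | None = None
    aars_p: float | None = None

    _THRESHOLDS = {
        "apc": "Significant if p < 0.05",
        "ars": "Significant if p < 0.05",
        "aars": "Significant if p < 0.05",
        "avif": "Acceptable if <= 5, ideally <= 3.3",
        "afvif": "Acceptable if <= 5, ideally <= 3.3",
        "gof": "Small >= 0.1, medium >= 0.25, large >= 0.36",
        "spr": "Acceptable if >= 0.7, ideally = 1",
        "rscr": "Acceptable if >= 0.9, ideally = 1",
        "ssr": "Acceptable if >= 0.7",
        "nlbcdr": "Acceptable if >= 0.7",
    }

    def table(self) -> pd.DataFrame:
        labels = {
            "apc": "Average path coefficient (APC)",
            "ars": "Average R-squared (ARS)",
            "aars": "Average adjusted R-squared (AARS)",
            "avif": "Average block VIF (AVIF)",
            "afvif": "Average full collinearity VIF (AFVIF)",
            "gof": "Tenenhaus GoF (GoF)",
            "spr": "Sympson's paradox ratio (SPR)",
            "rscr": "R-squared contribution ratio (RSCR)",
            "ssr": "Statistical suppression ratio (SSR)",
            "nlbcdr": "Non-linear bivariate causality direction ratio (NLBCDR)",
        }
        ps = {"apc": self.apc_p, "ars": self.ars_p, "aars": self.aars_p}
        rows = [
            {
                "index": labels[k],
                "value": getattr(self, k),
                "p": ps.get(k),
                "interpretation": self._THRESHOLDS[k],
            }
            for k in labels
        ]
        return pd.DataFrame(rows)


def _bivariate_r2(x: np.ndarray, y: np.ndarray, mode: str) -> float:
    coef = warp_fit(x, y, mode)
    fitted = npoly.polyval(x, coef)
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - fitted) ** 2).sum())
    return 1.0 - sse / sst


def fit_indices(
    fit: PathFit,
    data: pd.DataFrame,
    bootstrap: BootstrapResult | None = None,
) -> FitIndices:
    """The ten global model fit and quality indices.

    APC = mean |beta|; ARS/AARS = mean (adjusted) R^2 over endogenous
    variables; AVIF averages block VIFs of equations with at least two
    predictors; AFVIF averages full-collinearity VIFs over all model
    variables; GoF = sqrt(mean communality x ARS), with communality 1 for
    single-indicator variables; SPR, RSCR, SSR and NLBCDR are causality
    quality ratios in [0, 1].  APC/ARS/AARS p-values come from the bootstrap
    distribution when one is supplied.
    """
    model = fit.model
    _check_model(data, model)
    betas = np.array([ef.beta for ef in fit.edges])
    corrs = np.array([ef.corr for ef in fit.edges])
    apc = float(np.mean(np.abs(betas)))
    ars = float(np.mean([fit.r2[t] for t in model.endogenous]))
    aars = float(np.mean([fit.adj_r2[t] for t in model.endogenous]))

    zdf = standardize(data[model.variables])
    block_vifs: list[float] = []
    for target in model.endogenous:
        incoming = model.predictors_of(target)
        if len(incoming) < 2:
            continue
        y = zdf[target].to_numpy()
        cols = [warp_edge(zdf[e.source].to_numpy(), y, e.mode) for e in incoming]
        block_vifs.extend(vif(np.column_stack(cols)))
    avif = float(np.mean(block_vifs)) if block_vifs else 1.0
    afvif = float(np.mean(list(full_collinearity_vif(data, model).values())))
    gof = float(np.sqrt(max(ars, 0.0)))  # communality 1 per single indicator

    spr = float(np.mean(np.sign(betas) == np.sign(corrs)))
    contributions = betas * corrs
    denom = float(np.sum(np.abs(contributions)))
    rscr = float(np.sum(contributions[contributions > 0]) / denom) if denom else 1.0
    ssr = float(np.mean(np.abs(betas) <= np.abs(corrs) + 1e-12))

    credits = []
    for ef in fit.edges:
        x = zdf[ef.edge.source].to_numpy()
        y = zdf[ef.edge.target].to_numpy()
        fwd = _bivariate_r2(x, y, ef.edge.mode)
        rev = _bivariate_r2(y, x, ef.edge.mode)
        if abs(fwd - rev) <= 1e-12:
            credits.append(0.5)
        else:
            credits.append(1.0 if fwd > rev else 0.0)
    nlbcdr = float(np.mean(credits))

    apc_p = ars_p = aars_p = None
    if bootstrap is not None:
        apc_p = _index_p(apc, np.nanmean(np.abs(bootstrap.betas), axis=1),
                         bootstrap.B)
        ars_p = _index_p(ars, np.nanmean(bootstrap.r2, axis=1), bootstrap.B)
        aars_p = _index_p(aars, np.nanmean(bootstrap.adj_r2, axis=1),
                          bootstrap.B)
    return FitIndices(apc=apc, ars=ars, aars=aars, avif=avif, afvif=afvif,
                      gof=gof, spr=spr, rscr=rscr, ssr=ssr, nlbcdr=nlbcdr,
                      apc_p=apc_p, ars_p=ars_p, aars_p=aars_p)


def _index_p(value: float, boot: np.ndarray, B: int) -> float:
    se = float(np.nanstd(boot, ddof=1))
    if se <= 0:
        return 0.0
    return float(2.0 * stats.t.sf(abs(value) / se, df=B - 1))


def analyze(
    data: pd.DataFrame,
    model: PathModel,
    B: int = 5000,
    seed: int | None = None,
) -> PathFit:
    """Full pipeline: point fit, bootstrap inference and fit indices."""
    fit = fit_model(data, model)
    boot = bootstrap_inference(data, model, B=B, seed=seed)
    fit.edges = [
        replace(ef, se=float(se), p=float(p))
        for ef, se, p in zip(fit.edges, boot.se, boot.p)
    ]
    fit.bootstrap = boot
    fit.indices = fit_indices(fit, data, bootstrap=boot)
    return fit


# ---------------------------------------------------------------------------
# Relationship curves and shape classification
# ---------------------------------------------------------------------------

SHAPE_LABELS = ("linear", "U", "inverted-U", "S", "inverted-S", "J",
                "exponential-like")


def relationship_curve(edge_fit: EdgeFit, n_points: int = 101) -> pd.DataFrame:
    """Fitted warp polynomial sampled on a grid over the observed x range."""
    if not edge_fit.coef:
        raise ValueError("edge has no fitted warp polynomial")
    lo, hi = edge_fit.x_range
    grid = np.linspace(lo, hi, n_points)
    yhat = npoly.polyval(grid, np.asarray(edge_fit.coef))
    return pd.DataFrame({"x": grid, "y_hat": yhat})


def classify_shape(coef, x_range: tuple[float, float]) -> str:
    """Shape label of a fitted polynomial over an x interval.

    Based on the interior stationary points and derivative signs: two
    stationary points of a cubic give S (positive leading coefficient) or
    inverted-S (negative); one stationary point gives U / inverted-U by
    curvature (J when the dip sits in the left third and the curve is
    convex); monotone curves are linear, exponential-like (convex
    increasing / concave decreasing) or classified by their inflection.
    """
    coef = np.asarray(coef, dtype=float)
    lo, hi = x_range
    span = hi - lo if hi > lo else 1.0
    grid = np.linspace(lo, hi, 201)
    vals = npoly.polyval(grid, coef)
    scale = max(np.ptp(vals), 1e-12)

    # effective degree: drop numerically negligible high-order terms
    eff = coef.copy()
    for d in range(len(eff) - 1, 1, -1):
        if abs(eff[d]) * span**d < 1e-8 * scale:
            eff[d] = 0.0
        else:
            break
    nz = np.nonzero(np.abs(eff) > 0)[0]
    degree = int(nz.max()) if nz.size else 0
    if degree <= 1:
        return "linear"

    deriv = npoly.polyder(eff)
    roots = np.roots(deriv[::-1]) if len(deriv) > 1 else np.array([])
    interior = sorted(
        r.real for r in roots
        if abs(r.imag) < 1e-8 and lo + 1e-9 * span < r.real < hi - 1e-9 * span
    )
    second = npoly.polyder(eff, 2)

    if len(interior) >= 2:
        return "S" if eff[degree] > 0 else "inverted-S"
    if len(interior) == 1:
        s = interior[0]
        curvature = npoly.polyval(s, second)
        if curvature > 0:
            left_third = s < lo + span / 3.0
            return "J" if left_third else "U"
        return "inverted-U"
    # monotone on the range
    d_lo = npoly.polyval(grid, deriv)
    c_vals = npoly.polyval(grid, second)
    increasing = np.mean(d_lo) > 0
    if np.all(c_vals >= -1e-9 * scale / span**2):  # convex throughout
        return "exponential-like" if increasing else "U"
    if np.all(c_vals <= 1e-9 * scale / span**2):  # concave throughout
        return "inverted-U"
    # inflection inside the range, still monotone; dominant convex growth
    # reads as exponential-like, otherwise the half-S of the fitted cubic
    convex_share = float(np.mean(c_vals > 0))
    if increasing and convex_share >= 0.7:
        return "exponential-like"
    return "S" if eff[degree] > 0 else "inverted-S"
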