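"""Survival-curve containers and model fitting (UMA, mixtures, LQ, MT).

A :class:`SurvivalCurve` holds dose points with replicate survival
fractions from a clonogenic assay; per-point means and sample standard
deviations drive the goodness statistics:

* ``R^2 = 1 - RSS/SSS`` on the linear survival scale,
* ``r`` — mean relative residual ``(1/I) sum |S(D_i)-S_i|/S_i``,
* ``e`` — mean relative experimental error ``(1/I') sum dS_i/S_i``
  over the points that carry a replicate SD.

A fit is considered good when R^2 is in [0.9, 1] and r < e: R^2 alone
is insensitive to misfit at high doses where survival is tiny.

The UMA fit exploits the linearisation ``ln(n/S + 1 - n) = D/D0``: for
a candidate activation number n, D0 follows from a through-origin
least-squares regression, and n itself is found by a deterministic
grid-plus-golden-section search minimising the relative residual r.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core_model import LQParams, MixtureParams, UMAParams, uma_survival

__all__ = [
    "SurvivalCurve",
    "GoodnessStats",
    "FitResult",
    "goodness_stats",
    "fit_uma",
    "fit_uma_mixture",
    "fit_lq",
    "fit_mt",
    "FittingError",
]

logger = logging.getLogger(__name__)


class FittingError(RuntimeError):
    """Raised when a curve cannot be fitted under the stated procedure."""

    def __init__(self, message: str, best: Optional["FitResult"] = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class SurvivalCurve:
    """Clonogenic survival curve: doses (Gy) with replicate survival
    fractions per dose point.

    Doses are strictly increasing and >= 0; survivals lie in (0, 1].
    The zero-dose point, if present, is the normalisation anchor: its
    mean is exactly 1 and it carries no error bar.
    """

    doses: Tuple[float, ...]
    replicates: Tuple[Tuple[float, ...], ...]

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        reps = tuple(tuple(float(s) for s in r) for r in self.replicates)
        if len(doses) != len(reps):
            raise ValueError("doses and replicates must align")
        if len(doses) == 0:
            raise ValueError("curve must contain at least one dose point")
        d = np.asarray(doses)
        if np.any(d < 0):
            raise ValueError("doses must be >= 0 Gy")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        for dose, r in zip(doses, reps):
            if len(r) == 0:
                raise ValueError(f"dose point {dose} Gy has no survival values")
            arr = np.asarray(r)
            if np.any(arr <= 0) or np.any(arr > 1):
                raise ValueError(
                    f"survival fractions at {dose} Gy must lie in (0, 1], got {r}"
                )
        if doses[0] == 0.0:
            if abs(float(np.mean(reps[0])) - 1.0) > 1e-12:
                raise ValueError("zero-dose survival must be normalised to 1")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "replicates", reps)

    # -- derived per-point quantities -------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.doses)

    @property
    def means(self) -> np.ndarray:
        return np.array([float(np.mean(r)) for r in self.replicates])

    @property
    def sds(self) -> np.ndarray:
        """Sample SD (ddof=1) per point; NaN where < 2 replicates or at
        the zero-dose anchor, which by convention carries no error bar."""
        out = np.empty(self.n_points)
        for i, (d, r) in enumerate(zip(self.doses, self.replicates)):
            if d == 0.0 or len(r) < 2:
                out[i] = np.nan
            else:
                out[i] = float(np.std(r, ddof=1))
        return out

    # -- construction ------------------------------------------------------
    @classmethod
    def from_points(
        cls,
        points: Sequence[Tuple[float, Sequence[float]]],
        add_zero_dose: bool = True,
    ) -> "SurvivalCurve":
        pts = sorted(((float(d), tuple(r)) for d, r in points), key=lambda p: p[0])
        if add_zero_dose and (not pts or pts[0][0] != 0.0):
            logger.info("zero-dose anchor (0 Gy, S=1) inserted")
            pts.insert(0, (0.0, (1.0,)))
        return cls(tuple(d for d, _ in pts), tuple(r for _, r in pts))

    @classmethod
    def from_model(
        cls, params: Union[UMAParams, MixtureParams], doses: Sequence[float]
    ) -> "SurvivalCurve":
        """Noiseless curve evaluated on a dose grid (one 'replicate' per point)."""
        ds = sorted(set(float(d) for d in doses) | {0.0})
        return cls(tuple(ds), tuple((float(uma_survival(params, d)),) for d in ds))

    @classmethod
    def from_csv(cls, path_or_buffer) -> "SurvivalCurve":
        """Read the survival-curve CSV dialect.

        Header either ``dose_gy,rep1,rep2,...`` (replicates, possibly a
        ragged table with empty trailing cells) or ``dose_gy,mean,sd``.
        A zero-dose row (0, 1.0) is inserted if absent.
        """
        df = pd.read_csv(path_or_buffer)
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        if "dose_gy" not in cols:
            raise ValueError("survival-curve CSV must have a 'dose_gy' column")
        if "mean" in cols:
            # mean/sd dialect: reconstruct two pseudo-replicates mean +/- sd
            # so downstream means and SDs are preserved.
            pts = []
            for _, row in df.iterrows():
                m = float(row["mean"])
                sd = float(row.get("sd", np.nan)) if "sd" in cols else np.nan
                if np.isnan(sd) or sd == 0 or float(row["dose_gy"]) == 0.0:
                    reps: Tuple[float, ...] = (m,)
                else:
                    reps = (m - sd / math.sqrt(2), m + sd / math.sqrt(2))
                pts.append((float(row["dose_gy"]), reps))
            return cls.from_points(pts)
        rep_cols = [c for c in cols if c.startswith("rep")]
        if not rep_cols:
            raise ValueError("expected 'mean' or 'rep*' columns in survival-curve CSV")
        pts = []
        for i, row in df.iterrows():
            reps = tuple(float(row[c]) for c in rep_cols if not pd.isna(row[c]))
            if not reps:
                raise ValueError(f"row {i} ({row['dose_gy']} Gy) has no survival value")
            pts.append((float(row["dose_gy"]), reps))
        return cls.from_points(pts)

    def to_csv(self, path_or_buffer=None) -> Optional[str]:
        """Write the replicate dialect (``dose_gy,rep1,...``)."""
        width = max(len(r) for r in self.replicates)
        rows = []
        for d, r in zip(self.doses, self.replicates):
            row = {"dose_gy": d}
            for j in range(width):
                row[f"rep{j + 1}"] = r[j] if j < len(r) else np.nan
            rows.append(row)
        df = pd.DataFrame(rows)
        return df.to_csv(path_or_buffer, index=False)


@dataclass(frozen=True)
class GoodnessStats:
    """Goodness-of-fit summary on the linear survival scale."""

    r2: float
    rss: float
    sss: float
    r: float
    e: Optional[float]

    @property
    def is_good(self) -> bool:
        """The adopted criterion: R^2 in [0.9, 1] and r < e when e exists."""
        ok_r2 = not math.isnan(self.r2) and 0.9 <= self.r2 <= 1.0
        ok_r = self.e is None or self.r < self.e
        return ok_r2 and ok_r


def goodness_stats(curve: SurvivalCurve, fitted: Sequence[float]) -> GoodnessStats:
    """Compute R^2, RSS, SSS, r and (when SDs exist) e for fitted values
    aligned with the curve's dose points.

    R^2 is NaN (undefined) when all observed means coincide (SSS = 0).
    """
    f = np.asarray(fitted, dtype=float)
    s = curve.means
    if f.shape != s.shape:
        raise ValueError("fitted values must align with curve points")
    rss = float(np.sum((f - s) ** 2))
    sss = float(np.sum((s - s.mean()) ** 2))
    r2 = math.nan if sss == 0.0 else 1.0 - rss / sss
    r = float(np.mean(np.abs(f - s) / s))
    sds = curve.sds
    has_sd = ~np.isnan(sds)
    e = float(np.mean(sds[has_sd] / s[has_sd])) if np.any(has_sd) else None
    return GoodnessStats(r2=r2, rss=rss, sss=sss, r=r, e=e)


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one model to one survival curve."""

    model_kind: str  # "UMA" | "UMA-mixture" | "LQ" | "MT"
    params: Union[UMAParams, MixtureParams, LQParams]
    stats: GoodnessStats
    fitted: Tuple[float, ...]
    residuals: Tuple[float, ...]
    doses: Tuple[float, ...]
    dose_range: Optional[Tuple[float, float]] = None
    warnings: Tuple[str, ...] = ()

    @property
    def r2(self) -> float:
        return self.stats.r2

    @property
    def r(self) -> float:
        return self.stats.r

    @property
    def is_good(self) -> bool:
        return self.stats.is_good

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        if isinstance(self.params, UMAParams):
            p = {"d0": self.params.d0, "n": self.params.n}
        elif isinstance(self.params, MixtureParams):
            p = {
                "components": [
                    {"weight": w, "d0": q.d0, "n": q.n}
                    for w, q in self.params.components
                ]
            }
        else:
            p = {"alpha": self.params.alpha, "beta": self.params.beta,
                 "alpha_beta_ratio": self.params.alpha_beta_ratio}
        return {
            "model_kind": self.model_kind,
            "params": p,
            "r2": self.stats.r2,
            "rss": self.stats.rss,
            "sss": self.stats.sss,
            "r": self.stats.r,
            "e": self.stats.e,
            "is_good": self.is_good,
            "doses": list(self.doses),
            "fitted": list(self.fitted),
            "residuals": list(self.residuals),
            "dose_range": list(self.dose_range) if self.dose_range else None,
            "warnings": list(self.warnings),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        p = d["params"]
        params: Union[UMAParams, MixtureParams, LQParams]
        if "components" in p:
            params = MixtureParams(
                tuple((c["weight"], UMAParams(c["d0"], c["n"])) for c in p["components"])
            )
        elif "alpha" in p:
            params = LQParams(p["alpha"], p["beta"])
        else:
            params = UMAParams(p["d0"], p["n"])
        stats = GoodnessStats(
            r2=d["r2"], rss=d["rss"], sss=d["sss"], r=d["r"], e=d["e"]
        )
        return cls(
            model_kind=d["model_kind"],
            params=params,
            stats=stats,
            fitted=tuple(d["fitted"]),
            residuals=tuple(d["residuals"]),
            doses=tuple(d["doses"]),
            dose_range=tuple(d["dose_range"]) if d.get("dose_range") else None,
            warnings=tuple(d.get("warnings", ())),
        )

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        return cls.from_dict(json.loads(text))


def _result(model_kind, params, curve, model_fn, dose_range=None, warn=()):
    fitted = np.array([float(model_fn(d)) for d in curve.doses])
    stats = goodness_stats(curve, fitted)
    resid = fitted - curve.means
    return FitResult(
        model_kind=model_kind,
        params=params,
        stats=stats,
        fitted=tuple(fitted),
        residuals=tuple(resid),
        doses=curve.doses,
        dose_range=dose_range,
        warnings=tuple(warn),
    )


# ---------------------------------------------------------------------------
# UMA fit
# ---------------------------------------------------------------------------

def _d0_for_n(n: float, doses: np.ndarray, means: np.ndarray) -> Optional[float]:
    """Through-origin regression D0 for a candidate n, or None if infeasible.

    The linearisation y = ln(n/S + 1 - n) satisfies y = D/D0 on exact
    model data; the least-squares slope of y on D through the origin is
    1/D0.  A candidate n making the log argument non-positive anywhere
    is infeasible.
    """
    arg = n / means + 1.0 - n
    if np.any(arg <= 0):
        return None
    y = np.log(arg)
    denom = float(np.dot(doses, y))
    if denom <= 0:
        return None
    d0 = float(np.dot(doses, doses)) / denom
    return d0 if d0 > 0 and math.isfinite(d0) else None


def _uma_objective(n, curve, doses, means):
    d0 = _d0_for_n(n, doses, means)
    if d0 is None:
        return None
    params = UMAParams(d0, n)
    fitted = uma_survival(params, np.asarray(curve.doses))
    stats = goodness_stats(curve, np.atleast_1d(fitted))
    return params, stats


def fit_uma(
    curve: SurvivalCurve,
    n_grid_size: int = 241,
    n_bounds: Tuple[float, float] = (0.05, 200.0),
    r2_floor: float = 0.9,
) -> FitResult:
    """Fit the two-parameter UMA model by linearised search.

    Procedure: (1) initialise D0 and n from the two highest-dose points
    (the straight portion); (2) scan candidate n values on a log-spaced
    grid spanning ``n_bounds`` (always including the initial guess),
    solving D0 for each candidate by the through-origin regression of
    ``ln(n/S_i + 1 - n)`` on D_i; (3) refine the best candidate by
    golden-section search and return the n minimising the mean relative
    residual r, subject to R^2 >= ``r2_floor`` whenever any candidate
    attains it (otherwise the constraint is dropped with a warning).

    Deterministic: same curve, same result.
    """
    doses = np.asarray(curve.doses)
    means = curve.means
    pos = doses > 0
    if int(pos.sum()) < 2 or curve.n_points < 3:
        raise FittingError("UMA fit needs >= 3 dose points with >= 2 at D > 0")

    # step 1: initialisation from the two highest-dose points
    d_hi, d_lo = doses[-1], doses[-2]
    s_hi, s_lo = means[-1], means[-2]
    warn: List[str] = []
    with np.errstate(divide="ignore"):
        denom = math.log(s_hi) - math.log(s_lo)
    if denom < 0:
        d0_init = -(d_hi - d_lo) / denom
        n_init = s_lo * math.exp(d_lo / d0_init)
        n_init = min(max(n_init, n_bounds[0]), n_bounds[1])
    else:
        d0_init, n_init = None, 1.0
        warn.append("high-dose tail not decreasing; grid-only initialisation")

    lo, hi = n_bounds
    grid = np.geomspace(lo, hi, n_grid_size)
    grid = np.unique(np.concatenate([grid, [1.0, n_init]]))

    evals = []
    for n in grid:
        res = _uma_objective(float(n), curve, doses, means)
        if res is not None:
            evals.append((float(n), res))
    if not evals:
        raise FittingError("no feasible activation number n in the search range")

    feasible = [(n, pr) for n, pr in evals
                if not math.isnan(pr[1].r2) and pr[1].r2 >= r2_floor]
    pool = feasible
    if not pool:
        pool = evals
        warn.append(
            f"no candidate reached R^2 >= {r2_floor}; minimising r unconditionally"
        )
        warnings.warn(warn[-1], stacklevel=2)

    def keyed(item):
        n, (params, stats) = item
        return (stats.r, -stats.r2 if not math.isnan(stats.r2) else 0.0, n)

    pool_sorted = sorted(pool, key=keyed)
    best_n = pool_sorted[0][0]

    # step 3: golden-section refinement around the best grid candidate
    grid_sorted = np.sort(np.array([n for n, _ in evals]))
    i = int(np.searchsorted(grid_sorted, best_n))
    a = grid_sorted[max(i - 1, 0)]
    b = grid_sorted[min(i + 1, len(grid_sorted) - 1)]

    def robj(n):
        res = _uma_objective(float(n), curve, doses, means)
        return math.inf if res is None else res[1].r

    invphi = (math.sqrt(5) - 1) / 2
    la, lb = math.log(a), math.log(b)
    for _ in range(80):
        if lb - la < 1e-12:
            break
        c = lb - invphi * (lb - la)
        d = la + invphi * (lb - la)
        if robj(math.exp(c)) <= robj(math.exp(d)):
            lb = d
        else:
            la = c
    n_ref = math.exp((la + lb) / 2)
    cand = [(best_n, pool_sorted[0][1])]
    res_ref = _uma_objective(n_ref, curve, doses, means)
    if res_ref is not None:
        ok = (not feasible) or (
            not math.isnan(res_ref[1].r2) and res_ref[1].r2 >= r2_floor
        )
        if ok:
            cand.append((n_ref, res_ref))
    n_best, (params, stats) = min(cand, key=keyed)

    return _result("UMA", params, curve, lambda d: uma_survival(params, d), warn=warn)


# ---------------------------------------------------------------------------
# Two-population (mixture) fit
# ---------------------------------------------------------------------------

def fit_uma_mixture(
    curve: SurvivalCurve,
    k: int = 2,
    free_weights: bool = False,
    n_starts: int = 12,
    seed: int = 20210216,
    maxiter: int = 2000,
) -> FitResult:
    """Fit a k-component UMA mixture by minimising the relative residual r.

    Default is k = 2 with fixed equal weights (the "one half ... the
    other half" decomposition of irregular shoulders); set
    ``free_weights`` to let the weights vary on the simplex.  Local
    Nelder-Mead searches in log-parameter space are launched from a
    fixed-seed set of starting points, so the fit is reproducible.
    Components are returned sorted by descending D0 (most radioresistant
    first).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if curve.n_points < 2 * k + 1:
        raise FittingError(f"{k}-component mixture fit needs >= {2 * k + 1} dose points")
    if k == 1:
        base = fit_uma(curve)
        return base

    doses = np.asarray(curve.doses)
    means = curve.means
    rng = np.random.default_rng(seed)
    single = None
    try:
        single = fit_uma(curve)
    except FittingError:
        pass

    def unpack(x):
        d0s = np.exp(x[:k])
        ns = np.exp(x[k:2 * k])
        if free_weights:
            z = np.concatenate([x[2 * k:], [0.0]])
            w = np.exp(z - z.max())
            w = w / w.sum()
        else:
            w = np.full(k, 1.0 / k)
        comps = tuple(
            (float(w[i]), UMAParams(float(d0s[i]), float(ns[i]))) for i in range(k)
        )
        return MixtureParams(comps)

    def objective(x):
        if np.any(np.abs(x[:2 * k]) > 8):  # keep parameters in a sane box
            return 1e6
        try:
            mix = unpack(x)
        except (ValueError, OverflowError):
            return 1e6
        fitted = np.atleast_1d(uma_survival(mix, doses))
        return float(np.mean(np.abs(fitted - means) / means))

    starts = []
    if single is not None:
        p0 = single.params
        base = np.concatenate([
            np.log([p0.d0 * f for f in np.linspace(0.8, 1.2, k)]),
            np.log(np.clip([p0.n * f for f in np.geomspace(0.3, 3.0, k)], 0.05, 200)),
        ])
        if free_weights:
            base = np.concatenate([base, np.zeros(k - 1)])
        starts.append(base)
    dim = 2 * k + (k - 1 if free_weights else 0)
    while len(starts) < n_starts:
        x = np.concatenate([
            rng.uniform(math.log(0.5), math.log(7.0), k),
            rng.uniform(math.log(0.2), math.log(60.0), k),
        ])
        if free_weights:
            x = np.concatenate([x, rng.normal(0, 0.5, k - 1)])
        starts.append(x)

    best_x, best_val = None, math.inf
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-9, "fatol": 1e-12})
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
    if best_x is None or not math.isfinite(best_val) or best_val >= 1e6:
        raise FittingError("mixture fit did not converge", best=single)

    mix = unpack(best_x)
    comps = tuple(sorted(mix.components, key=lambda c: -c[1].d0))
    mix = MixtureParams(comps)
    return _result("UMA-mixture", mix, curve, lambda d: uma_survival(mix, d))


# ---------------------------------------------------------------------------
# LQ and MT comparison fits
# ---------------------------------------------------------------------------

def fit_lq(
    curve: SurvivalCurve,
    dose_range: Optional[Tuple[float, float]] = None,
) -> FitResult:
    """Zero-intercept LQ fit: least squares of ln S_i = -alpha*D_i - beta*D_i^2.

    ``dose_range`` restricts the points entering the regression (the
    fitted ratio is notoriously sensitive to this choice); goodness
    statistics are always computed over *all* points, so high-dose
    misfit of a low-dose-only fit remains visible.
    """
    doses = np.asarray(curve.doses)
    means = curve.means
    if dose_range is None:
        mask = np.ones_like(doses, dtype=bool)
    else:
        lo, hi = dose_range
        mask = (doses >= lo) & (doses <= hi)
    d = doses[mask]
    s = means[mask]
    if d.size < 3:
        raise FittingError("LQ fit needs >= 3 points inside the dose range")
    if np.allclose(d, d[0]):
        raise FittingError("degenerate design: all doses equal")
    X = np.column_stack([d, d**2])
    y = -np.log(s)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    params = LQParams(alpha=float(coef[0]), beta=float(coef[1]))

    def model(dd):
        return math.exp(-params.alpha * dd - params.beta * dd**2)

    rng_used = (float(d.min()), float(d.max()))
    return _result("LQ", params, curve, model, dose_range=rng_used)


def fit_mt(curve: SurvivalCurve, min_dose: float = 3.0) -> FitResult:
    """Classical multitarget fit of the straight portion.

    Linear least squares of ln S on D over points with D > ``min_dose``
    gives D0 = -1/slope and n = exp(intercept).  Statistics run over
    all points, exposing the characteristic low-dose overestimate of a
    shouldered curve.
    """
    doses = np.asarray(curve.doses)
    means = curve.means
    mask = doses > min_dose
    if int(mask.sum()) < 2:
        raise FittingError(f"MT fit needs >= 2 points with D > {min_dose} Gy")
    d = doses[mask]
    y = np.log(means[mask])
    slope, intercept = np.polyfit(d, y, 1)
    if slope >= 0:
        raise FittingError("MT fit requires decreasing high-dose survival")
    d0 = -1.0 / float(slope)
    n = float(math.exp(intercept))
    params = UMAParams(d0, n)  # (d0, n) pair in the MT parameterisation

    def model(dd):
        return n * math.exp(-dd / d0)

    return _result("MT", params, curve, model,
                   dose_range=(float(d.min()), float(d.max())))
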