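"""Coefficient estimation from two-species assay tables.

Assay tables are pandas DataFrames with one row per replicate beaker and
columns: assay_type, replicate, n0, n_final, duration_days,
competitor_density, n_herbivores, reset_times.  Assay types:

    mono_1 / mono_2    focal species alone over a density gradient
    inter_1 / inter_2  focal species against a fixed (reset) competitor
    feed_1 / feed_2    24 h feeding assay, herbivore vs control arms

Two estimation methods are provided and recorded in the output:

    "ode-fit" (default)   nonlinear least squares of observed final density
                          against the closed-form solution of the focal
                          species' growth law (competitor held constant);
                          self-consistent with the synthetic generator
    "growth-regression"   closed-form method on per-capita growth rates

Bootstrap confidence intervals resample replicate beakers with replacement
within each (assay_type x density level x herbivore arm) cell.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import logistic_solution
from .types import PARAM_NAMES, CalibrationCurve, EstimationResult, FitnessChange

__all__ = [
    "ASSAY_TYPES",
    "ASSAY_COLUMNS",
    "per_capita_growth",
    "fit_calibration",
    "od_to_cells",
    "estimate_intraspecific",
    "estimate_interspecific",
    "estimate_consumption",
    "estimate_all",
    "bootstrap_params",
    "normalized_fitness",
]

ASSAY_TYPES = ("mono_1", "mono_2", "inter_1", "inter_2", "feed_1", "feed_2")
ASSAY_COLUMNS = (
    "assay_type",
    "replicate",
    "n0",
    "n_final",
    "duration_days",
    "competitor_density",
    "n_herbivores",
    "reset_times",
)


# ---------------------------------------------------------------------------
# elementary statistics


def per_capita_growth(n0, n_final, duration):
    """Average per-capita growth rate ln(n_final/n0)/duration (per day).

    n_final == 0 yields -inf (undefined growth; excluded from regression
    fits by the estimators).  Vectorised.
    """
    n0 = np.asarray(n0, dtype=float)
    nf = np.asarray(n_final, dtype=float)
    dt = np.asarray(duration, dtype=float)
    if np.any(n0 <= 0):
        raise ValueError("n0 must be > 0")
    if np.any(dt <= 0):
        raise ValueError("duration must be > 0")
    if np.any(nf < 0):
        raise ValueError("n_final must be >= 0")
    with np.errstate(divide="ignore"):
        out = np.log(nf / n0) / dt
    if out.ndim == 0:
        return float(out)
    return out


def normalized_fitness(sa_herb: float, sa_ctr: float) -> FitnessChange:
    """Bounded coverage contrast (sa_herb - sa_ctr) / max(sa_herb, sa_ctr).

    Positive iff herbivory increased coverage; antisymmetric in its
    arguments; undefined (raises) when both coverages are 0.
    """
    if sa_herb < 0 or sa_ctr < 0:
        raise ValueError("coverages must be >= 0")
    m = max(sa_herb, sa_ctr)
    if m == 0:
        raise ValueError("normalized fitness undefined: both coverages are 0")
    return FitnessChange(sa_herb, sa_ctr, (sa_herb - sa_ctr) / m)


# ---------------------------------------------------------------------------
# OD calibration


def fit_calibration(points: Iterable | pd.DataFrame, blank_od: float = 0.0) -> CalibrationCurve:
    """Least-squares line through the origin on blank-corrected OD750.

    `points` is a sequence of (od750, cells_per_ml) pairs or a DataFrame
    with those two columns.  Requires at least 3 points.
    """
    if isinstance(points, pd.DataFrame):
        od = points["od750"].to_numpy(dtype=float)
        cells = points["cells_per_ml"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be (od750, cells_per_ml) pairs")
        od, cells = arr[:, 0], arr[:, 1]
    if len(od) < 3:
        raise ValueError(f"calibration needs >= 3 points, got {len(od)}")
    x = od - blank_od
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("calibration failure: all blank-corrected ODs are zero")
    slope = float(np.dot(x, cells)) / sxx
    resid = cells - slope * x
    dof = max(len(od) - 1, 1)
    return CalibrationCurve(
        slope=slope,
        blank_od=blank_od,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n_points=len(od),
    )


def od_to_cells(od, curve: CalibrationCurve):
    """Convert raw OD750 to cells ml^-1 via `curve`, floored at 0."""
    od = np.asarray(od, dtype=float)
    out = np.clip(curve.slope * (od - curve.blank_od), 0.0, None)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# internal array bundle (fast path shared by estimate_all and the bootstrap)


class _Arr:
    __slots__ = ("n0", "nf", "dt", "comp", "nh")

    def __init__(self, df: pd.DataFrame):
        self.n0 = df["n0"].to_numpy(dtype=float)
        self.nf = df["n_final"].to_numpy(dtype=float)
        self.dt = df["duration_days"].to_numpy(dtype=float)
        self.comp = df["competitor_density"].to_numpy(dtype=float)
        self.nh = df["n_herbivores"].to_numpy(dtype=float)

    def take(self, idx: np.ndarray) -> "_Arr":
        new = object.__new__(_Arr)
        new.n0 = self.n0[idx]
        new.nf = self.nf[idx]
        new.dt = self.dt[idx]
        new.comp = self.comp[idx]
        new.nh = self.nh[idx]
        return new


def _split_table(table: pd.DataFrame) -> dict[str, _Arr]:
    missing = [t for t in ASSAY_TYPES if t not in set(table["assay_type"])]
    if missing:
        raise ValueError(f"assay table is missing assay types: {missing}")
    return {t: _Arr(table[table["assay_type"] == t]) for t in ASSAY_TYPES}


def _log_logistic_grads(n0, b, c, t):
    """log N(t) for dN/dt = N(b - c N), plus d(logN)/db and d(logN)/dc.

    Overflow-safe for either sign of b; the removable singularity at b = 0
    is handled by its series limit.
    """
    n0 = np.asarray(n0, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    t = np.asarray(t, float)
    n0, b, c, t = np.broadcast_arrays(n0, b, c, t)
    logn = np.empty(n0.shape)
    db = np.empty(n0.shape)
    dc = np.empty(n0.shape)
    bt = b * t
    with np.errstate(all="ignore"):
        near0 = np.abs(bt) < 1e-7
        if np.any(near0):
            cn0t = c[near0] * n0[near0] * t[near0]
            denom = 1.0 + cn0t
            logn[near0] = np.log(n0[near0] / denom)
            db[near0] = t[near0] - cn0t * t[near0] / (2.0 * denom)
            dc[near0] = -n0[near0] * t[near0] / denom
        pos = (bt >= 0) & ~near0
        if np.any(pos):
            em = np.exp(-bt[pos])
            d = b[pos] * em + c[pos] * n0[pos] * (1.0 - em)
            logn[pos] = np.log(b[pos] * n0[pos] / d)
            db[pos] = 1.0 / b[pos] - em * (1.0 - bt[pos] + c[pos] * n0[pos] * t[pos]) / d
            dc[pos] = -n0[pos] * (1.0 - em) / d
        neg = (bt < 0) & ~near0
        if np.any(neg):
            ep = np.exp(bt[neg])
            d = b[neg] + c[neg] * n0[neg] * (ep - 1.0)
            # b and d share sign here, so b/d > 0
            logn[neg] = np.log(b[neg] * n0[neg] / d) + bt[neg]
            db[neg] = 1.0 / b[neg] + t[neg] - (1.0 + c[neg] * n0[neg] * t[neg] * ep) / d
            dc[neg] = -n0[neg] * (ep - 1.0) / d
    return logn, db, dc


def _lm_fit(resid_jac, x0, project=None, max_iter=100, xtol=1e-14):
    """Tiny Levenberg-Marquardt for 1-2 parameter least squares.

    `resid_jac(x)` returns (residuals, jacobian); non-finite trial costs are
    rejected.  `project` clamps parameters to their valid region.
    """
    x = np.array(x0, float)
    if project is not None:
        x = project(x)
    r, jac = resid_jac(x)
    cost = float(np.dot(r, r))
    if not np.isfinite(cost):
        raise RuntimeError("least-squares fit failed: invalid starting point")
    lam = 1e-8
    for _ in range(max_iter):
        jtj = jac.T @ jac
        jtr = jac.T @ r
        stepped = False
        for _ in range(25):
            a = jtj + lam * np.diag(np.maximum(np.diag(jtj), 1e-300))
            try:
                dx = np.linalg.solve(a, -jtr)
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-12)
                continue
            x_new = x + dx
            if project is not None:
                x_new = project(x_new)
            r_new, jac_new = resid_jac(x_new)
            cost_new = float(np.dot(r_new, r_new))
            if np.isfinite(cost_new) and cost_new <= cost:
                stepped = True
                break
            lam = max(lam * 10.0, 1e-12)
        if not stepped:
            break
        converged = np.all(np.abs(x_new - x) <= xtol * (np.abs(x) + xtol)) or (
            cost - cost_new <= 1e-30 * max(cost, 1.0)
        )
        x, r, jac, cost = x_new, r_new, jac_new, cost_new
        lam = max(lam / 10.0, 1e-12)
        if converged:
            break
    return x


def _growth_regression_mono(a: _Arr) -> tuple[float, float]:
    ok = a.nf > 0
    g = np.log(a.nf[ok] / a.n0[ok]) / a.dt[ok]
    n0 = a.n0[ok]
    if len(np.unique(n0)) < 2:
        raise ValueError(
            "intraspecific fit not identifiable: need >= 2 distinct initial densities"
        )
    slope, intercept = np.polyfit(n0, g, 1)
    r = float(intercept)
    if r <= 0:
        # degenerate regression; fall back to the largest observed growth
        r = max(float(np.max(g)), 1e-6)
    a_ii = float(-slope / r)
    return r, a_ii


def _fit_mono(a: _Arr, method: str) -> tuple[float, float]:
    """Estimate (r, a_ii) from a single-species density gradient."""
    if np.any(a.comp != 0) or np.any(a.nh != 0):
        raise ValueError("mono assay records must have no competitor and no herbivore")
    r0, a0 = _growth_regression_mono(a)
    if method == "growth-regression":
        return r0, a0
    ok = a.nf > 0
    n0, nf, dt = a.n0[ok], a.nf[ok], a.dt[ok]
    log_nf = np.log(nf)

    def resid_jac(x):
        r, aa = x
        logn, db, dc = _log_logistic_grads(n0, r, r * aa, dt)
        # b = r, c = r*a: chain rule for (r, a)
        jac = np.stack([db + dc * aa, dc * r], axis=1)
        return logn - log_nf, jac

    def project(x):
        return np.array([max(x[0], 1e-8), max(x[1], 0.0)])

    x0 = np.array([max(r0, 1e-4), max(a0, 0.0)])
    sol = _lm_fit(resid_jac, x0, project=project)
    return float(sol[0]), float(sol[1])


def _predicted_mono_growth(n0, dt, r, a_ii):
    pred = logistic_solution(n0, r, r * a_ii, dt)
    return np.log(pred / n0) / dt


def _fit_inter(a: _Arr, r: float, a_ii: float, method: str) -> float:
    """Estimate a_ij from a gradient against a fixed competitor density."""
    if np.any(a.comp <= 0):
        raise ValueError("interspecific assay records must have competitor_density > 0")
    ok = a.nf > 0
    n0, nf, dt, comp = a.n0[ok], a.nf[ok], a.dt[ok], a.comp[ok]
    if len(n0) == 0:
        raise ValueError("no usable interspecific records (all collapsed)")
    g_obs = np.log(nf / n0) / dt
    g_wo = _predicted_mono_growth(n0, dt, r, a_ii)
    # closed-form growth-regression value, also the ode-fit starting point
    a_ij0 = float(np.mean((g_wo - g_obs) / (r * comp)))
    if method == "growth-regression":
        return a_ij0
    log_nf = np.log(nf)
    c = r * a_ii

    def resid_jac(x):
        b = r * (1.0 - x[0] * comp)
        logn, db, _ = _log_logistic_grads(n0, b, c, dt)
        return logn - log_nf, (db * (-r * comp))[:, None]

    sol = _lm_fit(resid_jac, np.array([a_ij0]))
    return float(sol[0])


def _fit_feed(a: _Arr, r: float) -> float:
    """Estimate a consumption coefficient beta from a feeding assay.

    Assumes a constant per-capita rate over the (24 h) assay window:
    beta = (mean g_control - mean g_herbivore) / (r * Nh).
    """
    herb = a.nh > 0
    ctrl = a.nh == 0
    if not np.any(herb) or not np.any(ctrl):
        raise ValueError("feeding assay needs both a herbivore arm and a control arm")
    ok = a.nf > 0
    g = np.full(len(a.nf), -np.inf)
    g[ok] = np.log(a.nf[ok] / a.n0[ok]) / a.dt[ok]
    g_h = g[herb & ok]
    g_c = g[ctrl & ok]
    if len(g_h) == 0 or len(g_c) == 0:
        raise ValueError("feeding assay arm has no usable (non-collapsed) replicates")
    nh = np.unique(a.nh[herb])
    if len(nh) != 1:
        raise ValueError("feeding assay herbivore arm must use a single herbivore count")
    beta = (float(np.mean(g_c)) - float(np.mean(g_h))) / (r * float(nh[0]))
    if beta < 0:
        warnings.warn(
            f"negative consumption estimate {beta:.4g} floored at 0", stacklevel=2
        )
        beta = 0.0
    return beta


def _estimate_from_arrays(arrs: dict[str, _Arr], method: str) -> dict[str, float]:
    r1, a11 = _fit_mono(arrs["mono_1"], method)
    r2, a22 = _fit_mono(arrs["mono_2"], method)
    a12 = _fit_inter(arrs["inter_1"], r1, a11, method)
    a21 = _fit_inter(arrs["inter_2"], r2, a22, method)
    beta1 = _fit_feed(arrs["feed_1"], r1)
    beta2 = _fit_feed(arrs["feed_2"], r2)
    return {
        "r1": r1,
        "r2": r2,
        "a11": a11,
        "a12": a12,
        "a21": a21,
        "a22": a22,
        "beta1": beta1,
        "beta2": beta2,
    }


# ---------------------------------------------------------------------------
# public estimators


def estimate_intraspecific(records: pd.DataFrame, method: str = "ode-fit") -> tuple[float, float]:
    """(r, a_ii) from a mono_* density gradient for one species."""
    _check_method(method)
    return _fit_mono(_Arr(records), method)


def estimate_interspecific(
    records: pd.DataFrame, r: float, a_ii: float, method: str = "ode-fit"
) -> float:
    """a_ij from an inter_* gradient, given the focal species' (r, a_ii)."""
    _check_method(method)
    return _fit_inter(_Arr(records), r, a_ii, method)


def estimate_consumption(records: pd.DataFrame, r: float) -> float:
    """beta from a feed_* assay (herbivore vs control arms), given focal r."""
    return _fit_feed(_Arr(records), r)


def _check_method(method: str) -> None:
    if method not in ("ode-fit", "growth-regression"):
        raise ValueError(f"unknown estimation method {method!r}")


def estimate_all(table: pd.DataFrame, method: str = "ode-fit") -> EstimationResult:
    """Point estimates of all eight coefficients from a full assay table.

    Dispatches in dependency order: intraspecific fits first, then the
    interspecific and consumption fits that rely on them.
    """
    _check_method(method)
    arrs = _split_table(table)
    params = _estimate_from_arrays(arrs, method)
    n_excluded = int(sum(np.sum(a.nf == 0) for a in arrs.values()))
    return EstimationResult(params=params, method=method, n_excluded=n_excluded)


def _cells(a: _Arr) -> list[np.ndarray]:
    """Resampling cells: replicate indices grouped by (n0 level, herbivore arm)."""
    keys = np.stack([a.n0, a.nh], axis=1)
    cells = []
    for key in np.unique(keys, axis=0):
        cells.append(np.nonzero((a.n0 == key[0]) & (a.nh == key[1]))[0])
    return cells


def bootstrap_params(
    table: pd.DataFrame,
    n_boot: int = 500,
    seed: int | None = None,
    method: str = "ode-fit",
    max_failure_frac: float = 0.2,
) -> EstimationResult:
    """Percentile bootstrap (95%) of :func:`estimate_all`.

    Replicates are resampled with replacement within each
    (assay_type x density level x herbivore arm) cell, preserving the assay
    design.  Deterministic under a fixed seed.  Coefficients whose CI
    strictly spans 0 are set to 0 in the `zeroed` variant.  Resamples that
    break an estimator are skipped; if more than `max_failure_frac` of them
    fail, the run aborts.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    _check_method(method)
    arrs = _split_table(table)
    point = _estimate_from_arrays(arrs, method)
    cells = {t: _cells(a) for t, a in arrs.items()}
    rng = np.random.default_rng(seed)

    draws = np.empty((n_boot, len(PARAM_NAMES)))
    n_failed = 0
    failures: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_boot):
            res = {}
            for t, a in arrs.items():
                idx = np.concatenate(
                    [c[rng.integers(0, len(c), len(c))] for c in cells[t]]
                )
                res[t] = a.take(idx)
            try:
                est = _estimate_from_arrays(res, method)
                draws[b - n_failed] = [est[k] for k in PARAM_NAMES]
            except Exception as exc:  # noqa: BLE001 - resample diagnostics
                n_failed += 1
                if len(failures) < 5:
                    failures.append(str(exc))
    n_ok = n_boot - n_failed
    if n_failed > max_failure_frac * n_boot:
        raise RuntimeError(
            f"bootstrap aborted: {n_failed}/{n_boot} resamples failed; "
            f"first errors: {failures}"
        )
    q = np.percentile(draws[:n_ok], [2.5, 97.5], axis=0)
    ci = {k: (float(q[0, i]), float(q[1, i])) for i, k in enumerate(PARAM_NAMES)}
    zeroed = {
        k: (0.0 if ci[k][0] < 0.0 < ci[k][1] else point[k]) for k in PARAM_NAMES
    }
    n_excluded = int(sum(np.sum(a.nf == 0) for a in arrs.values()))
    return EstimationResult(
        params=point,
        method=method,
        ci=ci,
        zeroed=zeroed,
        n_boot=n_boot,
        seed=seed,
        n_failed=n_failed,
        n_excluded=n_excluded,
    )
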