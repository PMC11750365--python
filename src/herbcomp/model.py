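"""Deterministic model engine.

Two competing species sharing a constant herbivore population:

    dN1/dt = r1*N1*(1 - a11*N1 - a12*N2 - beta1*Nh)
    dN2/dt = r2*N2*(1 - a22*N2 - a21*N1 - beta2*Nh)

This module provides the right-hand side, an event-accurate simulator with
reset schedules, zero-growth isoclines, the invasion-growth-rate analysis
(does herbivory benefit species 1?), a five-way outcome classification based
on mutual invasibility, and a scan for the minimal herbivore number that
collapses both species.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .types import (
    InvasionReport,
    ModelParams,
    OutcomeClassification,
    PopulationState,
    ResetEvent,
    ResetSchedule,
    Trajectory,
)

__all__ = [
    "rhs",
    "simulate",
    "logistic_solution",
    "isocline_species1",
    "isocline_species2",
    "invasion_analysis",
    "herbivory_benefit",
    "BenefitVerdict",
    "classify_outcome",
    "collapse_search",
    "CollapseScan",
    "EXTINCTION_CLAMP",
]

#: densities below this are clamped to exactly 0 during integration
EXTINCTION_CLAMP = 1e-12


def rhs(state: PopulationState, params: ModelParams) -> tuple[float, float]:
    """Time derivatives (dN1/dt, dN2/dt) at `state`. Exact arithmetic, no clipping."""
    n1, n2 = state.N1, state.N2
    p = params
    d1 = p.r1 * n1 * (1.0 - p.a11 * n1 - p.a12 * n2 - p.beta1 * p.Nh)
    d2 = p.r2 * n2 * (1.0 - p.a22 * n2 - p.a21 * n1 - p.beta2 * p.Nh)
    return d1, d2


def _rhs_vec(t: float, y: np.ndarray, p: ModelParams) -> list[float]:
    n1, n2 = y
    return [
        p.r1 * n1 * (1.0 - p.a11 * n1 - p.a12 * n2 - p.beta1 * p.Nh),
        p.r2 * n2 * (1.0 - p.a22 * n2 - p.a21 * n1 - p.beta2 * p.Nh),
    ]


def simulate(
    params: ModelParams,
    init: PopulationState,
    t_end: float,
    schedule: ResetSchedule | Sequence[ResetEvent] | None = None,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_points: int = 201,
) -> Trajectory:
    """Integrate the two-species system from `init` to `t_end`.

    Reset events stop the integrator, assign the targeted species' density,
    and resume.  Densities below :data:`EXTINCTION_CLAMP` are clamped to 0 at
    segment boundaries and in the reported output; a species at 0 stays at 0.
    """
    if not (t_end > init.t):
        raise ValueError("t_end must exceed init.t")
    if schedule is None:
        schedule = ResetSchedule()
    elif not isinstance(schedule, ResetSchedule):
        schedule = ResetSchedule(schedule)
    for e in schedule:
        if not (init.t < e.time <= t_end):
            raise ValueError(f"reset at t={e.time} outside ({init.t}, {t_end}]")

    if t_eval is None:
        t_eval = np.linspace(init.t, t_end, n_points)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
        if t_eval[0] < init.t or t_eval[-1] > t_end:
            raise ValueError("t_eval outside integration span")

    event_times = schedule.times()
    boundaries = [init.t] + [t for t in event_times if init.t < t <= t_end] + [t_end]
    # drop duplicated final boundary when a reset falls exactly at t_end
    bounds = sorted(set(boundaries))

    ts: list[np.ndarray] = []
    n1s: list[np.ndarray] = []
    n2s: list[np.ndarray] = []
    flags: list[np.ndarray] = []
    applied: list[ResetEvent] = []

    y = np.array([init.N1, init.N2], dtype=float)

    for seg_start, seg_end in zip(bounds[:-1], bounds[1:]):
        mask = (t_eval > seg_start) & (t_eval < seg_end)
        seg_eval = np.concatenate(([seg_start], t_eval[mask], [seg_end]))
        sol = solve_ivp(
            _rhs_vec,
            (seg_start, seg_end),
            y,
            t_eval=seg_eval,
            args=(params,),
            method="RK45",
            rtol=rtol,
            atol=atol,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"integrator failure near t={sol.t[-1]:.6g}: {sol.message}")
        yy = np.clip(sol.y, 0.0, None)
        yy[yy < EXTINCTION_CLAMP] = 0.0
        # a species starting the segment at exactly 0 stays at 0
        for i in (0, 1):
            if y[i] == 0.0:
                yy[i, :] = 0.0
        ts.append(sol.t)
        n1s.append(yy[0])
        n2s.append(yy[1])
        flags.append(np.zeros(len(sol.t), dtype=int))
        y = yy[:, -1].copy()
        # apply any resets scheduled at this segment end
        seg_flag = False
        for e in schedule:
            if e.time == seg_end:
                y[e.species - 1] = e.value
                applied.append(e)
                seg_flag = True
        if seg_flag:
            # overwrite endpoint with post-reset state, flagged
            n1s[-1][-1] = y[0]
            n2s[-1][-1] = y[1]
            flags[-1][-1] = 1

    t_all = np.concatenate(ts)
    n1_all = np.concatenate(n1s)
    n2_all = np.concatenate(n2s)
    f_all = np.concatenate(flags)
    # segment boundaries are duplicated; both rows carry the post-reset
    # state (the earlier one holds the event flag), so keep the first
    keep = np.concatenate(([True], np.diff(t_all) > 0))
    return Trajectory(
        t=t_all[keep],
        N1=n1_all[keep],
        N2=n2_all[keep],
        event_flag=f_all[keep],
        applied_events=applied,
        rtol=rtol,
        atol=atol,
    )


def logistic_solution(n0, b, c, t):
    """Closed-form solution of dN/dt = N*(b - c*N) with N(0) = n0.

    This is the single-species growth law with effective rate ``b`` and
    self-limitation ``c`` (for plain logistic growth, b = r and c = r*a).
    Vectorised over any of the arguments; numerically safe for b of either
    sign and large t.
    """
    n0 = np.asarray(n0, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    t = np.asarray(t, dtype=float)
    n0, b, c, t = np.broadcast_arrays(n0, b, c, t)
    out = np.empty(n0.shape, dtype=float)

    zero_b = b == 0.0
    # b == 0: dN/dt = -c N^2  ->  N = n0 / (1 + c n0 t)
    if np.any(zero_b):
        out[zero_b] = n0[zero_b] / (1.0 + c[zero_b] * n0[zero_b] * t[zero_b])
    nz = ~zero_b
    if np.any(nz):
        bt = b[nz] * t[nz]
        pos = bt >= 0
        res = np.empty(bt.shape, dtype=float)
        # bt >= 0: divide through by e^{bt} to avoid overflow
        e = np.exp(-bt[pos])
        res[pos] = (
            b[nz][pos] * n0[nz][pos] / (c[nz][pos] * n0[nz][pos] * (1 - e) + b[nz][pos] * e)
        )
        neg = ~pos
        e = np.exp(bt[neg])
        res[neg] = (
            b[nz][neg] * n0[nz][neg] * e / (b[nz][neg] + c[nz][neg] * n0[nz][neg] * (e - 1.0))
        )
        out[nz] = res
    out[n0 == 0.0] = 0.0
    if out.ndim == 0:
        return float(out)
    return out


def isocline_species1(params: ModelParams, n2_grid) -> np.ndarray:
    """Zero-net-growth density of species 1 at each competitor density N2.

    N1 = (1 - a12*N2 - beta1*Nh) / a11.  Values may be negative; callers
    decide whether to truncate for plotting.
    """
    n2 = np.asarray(n2_grid, dtype=float)
    return (1.0 - params.a12 * n2 - params.beta1 * params.Nh) / params.a11


def isocline_species2(params: ModelParams, n1_grid) -> np.ndarray:
    """Zero-net-growth density of species 2 at each competitor density N1."""
    n1 = np.asarray(n1_grid, dtype=float)
    return (1.0 - params.a21 * n1 - params.beta2 * params.Nh) / params.a22


def invasion_analysis(params: ModelParams) -> InvasionReport:
    """Invasion growth rate of species 1 into resident species 2, with and
    without the herbivore.

    N2w = (1 - beta2*Nh)/a22 (floored at 0 if the resident collapses under
    herbivory), N2wo = 1/a22, IGRw = r1*(1 - a12*N2w - beta1*Nh),
    IGRwo = r1*(1 - a12*N2wo).  Verdict "benefit" iff IGRw > IGRwo.
    """
    p = params
    n2wo = 1.0 / p.a22
    raw = (1.0 - p.beta2 * p.Nh) / p.a22
    collapsed = raw < 0.0
    n2w = max(0.0, raw)
    igr_w = p.r1 * (1.0 - p.a12 * n2w - p.beta1 * p.Nh)
    igr_wo = p.r1 * (1.0 - p.a12 * n2wo)
    if igr_w > igr_wo:
        verdict = "benefit"
    elif igr_w < igr_wo:
        verdict = "harm"
    else:
        verdict = "neutral"
    if p.beta2 > 0:
        margin = p.a12 / p.a22 - p.beta1 / p.beta2
        undefined = False
    else:
        margin = None
        undefined = True
    return InvasionReport(
        N2w=n2w,
        N2wo=n2wo,
        IGRw=igr_w,
        IGRwo=igr_wo,
        benefit=verdict,
        margin=margin,
        margin_undefined=undefined,
        resident_collapsed=collapsed,
    )


class BenefitVerdict:
    """Result of the density-independent herbivory-benefit inequality."""

    __slots__ = ("verdict", "margin", "margin_undefined")

    def __init__(self, verdict: str, margin: float | None, margin_undefined: bool):
        self.verdict = verdict
        self.margin = margin
        self.margin_undefined = margin_undefined

    def __repr__(self) -> str:
        return f"BenefitVerdict({self.verdict!r}, margin={self.margin})"


def herbivory_benefit(params: ModelParams) -> BenefitVerdict:
    """Does herbivory raise species 1's invasion growth rate?

    Pure coefficient inequality beta1/beta2 < a12/a22, evaluated in the
    cross-multiplied form beta1*a22 < a12*beta2 so that beta2 == 0 still
    yields a verdict (the margin ratio is then flagged undefined).  The
    verdict depends only on the coefficients, not on any density.
    """
    p = params
    lhs = p.beta1 * p.a22
    rhs_ = p.a12 * p.beta2
    if lhs < rhs_:
        verdict = "benefit"
    elif lhs > rhs_:
        verdict = "harm"
    else:
        verdict = "neutral"
    if p.beta2 > 0:
        return BenefitVerdict(verdict, p.a12 / p.a22 - p.beta1 / p.beta2, False)
    return BenefitVerdict(verdict, None, True)


def classify_outcome(params: ModelParams) -> OutcomeClassification:
    """Five-way long-run outcome from directional invasion growth rates.

    IGR1 is species 1's growth rate when rare against resident species 2 at
    its herbivory-adjusted equilibrium (and vice versa for IGR2).  If both
    growth brackets are non-positive regardless of densities, the outcome is
    both_collapse.  Coexistence requires strictly positive mutual
    invasibility; ties break toward the weaker label.
    """
    p = params
    press1 = p.beta1 * p.Nh
    press2 = p.beta2 * p.Nh
    resident2 = max(0.0, 1.0 - press2) / p.a22
    resident1 = max(0.0, 1.0 - press1) / p.a11
    igr1 = p.r1 * (1.0 - p.a12 * resident2 - press1)
    igr2 = p.r2 * (1.0 - p.a21 * resident1 - press2)
    if 1.0 - press1 <= 0.0 and 1.0 - press2 <= 0.0:
        label = "both_collapse"
    elif igr1 > 0.0 and igr2 > 0.0:
        label = "coexistence"
    elif igr1 > 0.0:
        label = "species1_excludes"
    elif igr2 > 0.0:
        label = "species2_excludes"
    else:
        label = "founder_control"
    return OutcomeClassification(label=label, igr1=igr1, igr2=igr2)


class CollapseScan:
    """Outcome of scanning herbivore numbers for joint collapse."""

    __slots__ = ("minimal_nh", "outcomes")

    def __init__(self, minimal_nh: int | None, outcomes: dict[int, OutcomeClassification]):
        self.minimal_nh = minimal_nh
        self.outcomes = outcomes

    @property
    def found(self) -> bool:
        return self.minimal_nh is not None


def collapse_search(params: ModelParams, max_herbivores: int) -> CollapseScan:
    """Smallest integer herbivore number at which both species collapse.

    Scans Nh = 1..max_herbivores with `params`' own Nh ignored; returns the
    minimal Nh classified as both_collapse (or None) along with the outcome
    at every scanned Nh.
    """
    if max_herbivores < 1:
        raise ValueError("max_herbivores must be >= 1")
    outcomes: dict[int, OutcomeClassification] = {}
    minimal: int | None = None
    for nh in range(1, max_herbivores + 1):
        oc = classify_outcome(params.replace(Nh=float(nh)))
        outcomes[nh] = oc
        if minimal is None and oc.label == "both_collapse":
            minimal = nh
    return CollapseScan(minimal, outcomes)
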