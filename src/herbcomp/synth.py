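"""Synthetic-data generation with known ground truth.

Generates every input the estimation pipeline consumes: assay tables over
the laboratory design grid, OD calibration points, microcosm endpoints and
field coverage series.  Noise is multiplicative lognormal (mean-one) with a
user coefficient of variation; species-1 counts can be rounded to integers
(fronds are counted, cell densities are not).

Assay generation uses the closed-form growth law of the focal species with
the competitor held exactly constant (the idealised limit of the frequent
reset schedule) and, for the 24 h feeding assays, a rate frozen at the
initial conditions (constant feeding over the assay window).  This makes
the generator the exact inverse of the "ode-fit" estimators at cv = 0.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import logistic_solution, simulate
from .types import ModelParams, PopulationState

__all__ = [
    "NoiseModel",
    "DesignSpec",
    "gen_assay_table",
    "gen_calibration",
    "gen_microcosm",
    "gen_field_series",
    "coverage_series",
    "write_fixture_dir",
    "DEFAULT_TRUTH",
]

#: ground-truth fixture regime: asymmetric competition (a21 = 0), the
#: benefit inequality holding (beta1/beta2 < a12/a22), coexistence without
#: herbivores, species 1 excluding species 2 at Nh = 1, joint collapse at
#: Nh = 2.  Values are repo fixture choices, not measured coefficients.
DEFAULT_TRUTH = ModelParams(
    r1=0.3,
    r2=0.9,
    a11=0.001,
    a22=0.1,
    a12=0.07,
    a21=0.0,
    beta1=0.6,
    beta2=1.1,
    Nh=0.0,
)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise on final densities.

    cv          coefficient of variation (cv = 0 -> deterministic output)
    integerize  round species-1 counts to integers (minimum 1 unless the
                underlying true density is below 0.5, which reads as 0)
    seed        RNG seed; generation is byte-identical under a fixed seed
    """

    cv: float = 0.1
    integerize: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.cv) or self.cv < 0:
            raise ValueError("cv must be finite and >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(cv=0.0, integerize=False, seed=0)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def multipliers(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.cv == 0.0:
            return np.ones(n)
        sigma = math.sqrt(math.log(1.0 + self.cv**2))
        return np.exp(rng.normal(0.0, sigma, n) - 0.5 * sigma**2)


def _round_counts(noisy: np.ndarray, true: np.ndarray) -> np.ndarray:
    out = np.rint(noisy)
    out[(out < 1) & (true >= 0.5)] = 1.0
    out[true < 0.5] = 0.0
    return out


@dataclass(frozen=True)
class DesignSpec:
    """Assay design grid; defaults mirror the laboratory design.

    Species 1 is counted in fronds, species 2 in 10^6 cells ml^-1.
    """

    mono1_levels: tuple = (5.0, 50.0, 100.0, 300.0, 600.0, 1000.0)
    mono1_reps: int = 3
    mono2_levels: tuple = (0.0095, 0.13, 0.59, 1.64, 3.91, 7.66, 9.24)
    mono2_reps: int = 4
    growth_duration: float = 7.0
    inter1_fixed_density: float = 1.33  # species 2 reset daily to this level
    inter1_reps: int = 3
    inter2_fixed_density: float = 100.0  # species 1 reduced to this on reset days
    inter2_reps: int = 4
    inter2_reset_days: tuple = (2.0, 5.0)
    feed_duration: float = 1.0
    feed1_n0: float = 100.0
    feed1_nh: int = 1
    feed1_herb_reps: int = 6
    feed1_ctrl_reps: int = 4
    feed2_n0: float = 12.6
    feed2_nh: int = 1
    feed2_herb_reps: int = 8
    feed2_ctrl_reps: int = 4

    def __post_init__(self) -> None:
        if len(set(self.mono1_levels)) < 2 or len(set(self.mono2_levels)) < 2:
            raise ValueError("each mono gradient needs >= 2 distinct density levels")
        if any(v <= 0 for v in self.mono1_levels + self.mono2_levels):
            raise ValueError("density levels must be > 0")
        for name in (
            "mono1_reps",
            "mono2_reps",
            "inter1_reps",
            "inter2_reps",
            "feed1_herb_reps",
            "feed1_ctrl_reps",
            "feed2_herb_reps",
            "feed2_ctrl_reps",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.growth_duration <= 0 or self.feed_duration <= 0:
            raise ValueError("durations must be > 0")
        if self.inter1_fixed_density <= 0 or self.inter2_fixed_density <= 0:
            raise ValueError("fixed competitor densities must be > 0")

    def with_replicates(self, n: int) -> "DesignSpec":
        return dataclasses.replace(
            self,
            mono1_reps=n,
            mono2_reps=n,
            inter1_reps=n,
            inter2_reps=n,
            feed1_herb_reps=n,
            feed1_ctrl_reps=n,
            feed2_herb_reps=n,
            feed2_ctrl_reps=n,
        )

    @property
    def inter1_reset_times(self) -> str:
        days = np.arange(1.0, self.growth_duration - 1e-9, 1.0)
        return ";".join(f"{d:g}" for d in days)

    @property
    def inter2_reset_times(self) -> str:
        return ";".join(f"{d:g}" for d in self.inter2_reset_days)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


def _feed_final(n0: float, r: float, a_ii: float, beta: float, nh: float, dt: float) -> float:
    # constant per-capita rate over the short feeding window
    return n0 * math.exp(r * (1.0 - a_ii * n0 - beta * nh) * dt)


def gen_assay_table(
    truth: ModelParams,
    design: DesignSpec | None = None,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Generate a full six-assay-type table from ground-truth parameters."""
    design = design or DesignSpec()
    noise = noise or NoiseModel()
    p = truth
    d = design
    rows: list[dict] = []

    def add(assay, rep, n0, n_true, dur, comp, nh, resets):
        rows.append(
            {
                "assay_type": assay,
                "replicate": rep,
                "n0": n0,
                "n_final": n_true,
                "duration_days": dur,
                "competitor_density": comp,
                "n_herbivores": nh,
                "reset_times": resets,
            }
        )

    for n0 in d.mono1_levels:
        nf = logistic_solution(n0, p.r1, p.r1 * p.a11, d.growth_duration)
        for rep in range(1, d.mono1_reps + 1):
            add("mono_1", rep, n0, nf, d.growth_duration, 0.0, 0, "")
    for n0 in d.mono2_levels:
        nf = logistic_solution(n0, p.r2, p.r2 * p.a22, d.growth_duration)
        for rep in range(1, d.mono2_reps + 1):
            add("mono_2", rep, n0, nf, d.growth_duration, 0.0, 0, "")
    c1 = d.inter1_fixed_density
    for n0 in d.mono1_levels:
        nf = logistic_solution(n0, p.r1 * (1.0 - p.a12 * c1), p.r1 * p.a11, d.growth_duration)
        for rep in range(1, d.inter1_reps + 1):
            add("inter_1", rep, n0, nf, d.growth_duration, c1, 0, d.inter1_reset_times)
    c2 = d.inter2_fixed_density
    for n0 in d.mono2_levels:
        nf = logistic_solution(n0, p.r2 * (1.0 - p.a21 * c2), p.r2 * p.a22, d.growth_duration)
        for rep in range(1, d.inter2_reps + 1):
            add("inter_2", rep, n0, nf, d.growth_duration, c2, 0, d.inter2_reset_times)
    for nh, reps in ((d.feed1_nh, d.feed1_herb_reps), (0, d.feed1_ctrl_reps)):
        nf = _feed_final(d.feed1_n0, p.r1, p.a11, p.beta1, nh, d.feed_duration)
        for rep in range(1, reps + 1):
            add("feed_1", rep, d.feed1_n0, nf, d.feed_duration, 0.0, nh, "")
    for nh, reps in ((d.feed2_nh, d.feed2_herb_reps), (0, d.feed2_ctrl_reps)):
        nf = _feed_final(d.feed2_n0, p.r2, p.a22, p.beta2, nh, d.feed_duration)
        for rep in range(1, reps + 1):
            add("feed_2", rep, d.feed2_n0, nf, d.feed_duration, 0.0, nh, "")

    df = pd.DataFrame(rows)
    rng = noise.rng()
    true = df["n_final"].to_numpy(dtype=float)
    noisy = true * noise.multipliers(rng, len(df))
    if noise.integerize:
        sp1 = df["assay_type"].isin(["mono_1", "inter_1", "feed_1"]).to_numpy()
        noisy[sp1] = _round_counts(noisy[sp1], true[sp1])
    df["n_final"] = noisy
    return df


def gen_calibration(
    slope: float,
    n_points: int = 12,
    noise: NoiseModel | None = None,
    blank_od: float = 0.0,
    max_cells: float = 22.0,
) -> pd.DataFrame:
    """OD750 vs cell-count points on a through-origin line with `slope`.

    Covers 0..`max_cells` (10^6 cells ml^-1) evenly, including the blank
    (zero-cell) point; noise multiplies the cell counts.
    """
    if slope <= 0:
        raise ValueError("slope must be > 0")
    if n_points < 3:
        raise ValueError("need >= 3 calibration points")
    noise = noise or NoiseModel()
    cells = np.linspace(0.0, max_cells, n_points)
    od = blank_od + cells / slope
    noisy = cells * noise.multipliers(noise.rng(), n_points)
    return pd.DataFrame({"od750": od, "cells_per_ml": noisy})


def gen_microcosm(
    truth: ModelParams,
    init: PopulationState,
    days: float = 14.0,
    noise: NoiseModel | None = None,
    nh_levels: Sequence[int] = (0, 1, 2),
    reps: int = 4,
) -> pd.DataFrame:
    """Noisy day-`days` endpoints of three-species beakers per herbivore level.

    Both species are dynamic (full ODE); the herbivore count is the
    treatment variable.
    """
    noise = noise or NoiseModel()
    rows = []
    for nh in nh_levels:
        traj = simulate(truth.replace(Nh=float(nh)), init, init.t + days)
        end = traj.final
        for rep in range(1, reps + 1):
            rows.append(
                {
                    "treatment_nh": nh,
                    "replicate": rep,
                    "n1_0": init.N1,
                    "n2_0": init.N2,
                    "n1_final": end.N1,
                    "n2_final": end.N2,
                    "duration_days": days,
                }
            )
    df = pd.DataFrame(rows)
    rng = noise.rng()
    for col, integer in (("n1_final", True), ("n2_final", False)):
        true = df[col].to_numpy(dtype=float)
        noisy = true * noise.multipliers(rng, len(df))
        if integer and noise.integerize:
            noisy = _round_counts(noisy, true)
        df[col] = noisy
    return df


def coverage_series(
    params: ModelParams,
    nh: float,
    init: PopulationState,
    weeks: int,
    max_coverage: float = 100.0,
) -> np.ndarray:
    """Weekly percent surface coverage of species 1 under `nh` herbivores.

    Coverage is linear in density and saturates at `max_coverage` when the
    population reaches its single-species carrying capacity 1/a11.
    """
    if weeks < 1:
        raise ValueError("weeks must be >= 1")
    t_eval = init.t + 7.0 * np.arange(0, weeks + 1)
    traj = simulate(params.replace(Nh=float(nh)), init, t_eval[-1], t_eval=t_eval)
    return np.minimum(max_coverage, max_coverage * params.a11 * traj.N1)


def gen_field_series(
    sa_herb: Sequence[float],
    sa_ctr: Sequence[float],
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Paired weekly coverage series (herbivory vs control compartment).

    Inputs are the true coverage trajectories, e.g. from
    :func:`coverage_series` with Nh > 0 and Nh = 0; noise multiplies both.
    """
    herb = np.asarray(sa_herb, dtype=float)
    ctr = np.asarray(sa_ctr, dtype=float)
    if herb.shape != ctr.shape or herb.ndim != 1 or len(herb) < 1:
        raise ValueError("sa_herb and sa_ctr must be equal-length 1-D series")
    noise = noise or NoiseModel()
    rng = noise.rng()
    return pd.DataFrame(
        {
            "week": np.arange(len(herb)),
            "sa_herb": herb * noise.multipliers(rng, len(herb)),
            "sa_ctr": ctr * noise.multipliers(rng, len(ctr)),
        }
    )


def write_fixture_dir(
    out_dir: str | Path,
    truth: ModelParams | None = None,
    design: DesignSpec | None = None,
    noise: NoiseModel | None = None,
    calibration_slope: float = 2.0,
) -> Path:
    """Write a complete worked-example directory: six per-assay CSVs, a
    calibration CSV, truth.json and design.json."""
    truth = truth or DEFAULT_TRUTH
    design = design or DesignSpec()
    noise = noise or NoiseModel(seed=0)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = gen_assay_table(truth, design, noise)
    for assay in table["assay_type"].unique():
        table[table["assay_type"] == assay].to_csv(out / f"{assay}.csv", index=False)
    gen_calibration(calibration_slope, noise=noise).to_csv(
        out / "calibration.csv", index=False
    )
    truth.to_json(out / "truth.json")
    (out / "design.json").write_text(json.dumps(design.to_dict(), indent=2) + "\n")
    return out
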