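"""Core domain types shared across the package.

The engine is unit-agnostic: species 1 and species 2 may be counted in
different density units (e.g. fronds vs 10^6 cells ml^-1) because every
cross coefficient absorbs the scale.  All rates are per day.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "PopulationState",
    "ResetEvent",
    "ResetSchedule",
    "Trajectory",
    "InvasionReport",
    "OutcomeClassification",
    "OUTCOME_LABELS",
    "CalibrationCurve",
    "EstimationResult",
    "FitnessChange",
]

PARAM_NAMES = ("r1", "r2", "a11", "a12", "a21", "a22", "beta1", "beta2")


@dataclass(frozen=True)
class ModelParams:
    """The eight model coefficients plus the (constant) herbivore abundance.

    r1, r2      intrinsic growth rates (per day)
    a11, a22    intraspecific competition (per density unit of own species)
    a12, a21    interspecific competition (per density unit of the other)
    beta1, beta2  per-herbivore consumption coefficients (dimensionless
                  inside the growth bracket)
    Nh          herbivore abundance (individuals, held constant)
    """

    r1: float
    r2: float
    a11: float
    a22: float
    a12: float = 0.0
    a21: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    Nh: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "a11", "a22"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("a12", "a21", "beta1", "beta2", "Nh"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def replace(self, **kwargs) -> "ModelParams":
        d = self.to_dict()
        d.update(kwargs)
        return ModelParams(**d)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_NAMES + ("Nh",)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        extra = set(d) - set(PARAM_NAMES) - {"Nh"}
        if extra:
            raise ValueError(f"unknown parameter keys: {sorted(extra)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class PopulationState:
    """Densities of the two species at a given time (days)."""

    t: float
    N1: float
    N2: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise ValueError("t must be finite")
        for name in ("N1", "N2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class ResetEvent:
    """Instantaneous density assignment: at `time`, set species `species` to `value`."""

    time: float
    species: int
    value: float

    def __post_init__(self) -> None:
        if self.species not in (1, 2):
            raise ValueError("species must be 1 or 2")
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError("reset value must be finite and >= 0")
        if not math.isfinite(self.time):
            raise ValueError("reset time must be finite")


class ResetSchedule:
    """An ordered list of :class:`ResetEvent` with strictly increasing times.

    Multiple events (one per species) may share a time; the same species may
    not be reset twice at the same instant.
    """

    def __init__(self, events: Iterable[ResetEvent] = ()) -> None:
        evs = sorted(events, key=lambda e: (e.time, e.species))
        seen = set()
        for e in evs:
            key = (e.time, e.species)
            if key in seen:
                raise ValueError(f"duplicate reset for species {e.species} at t={e.time}")
            seen.add(key)
        self.events: list[ResetEvent] = evs

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __bool__(self) -> bool:
        return bool(self.events)

    def times(self) -> list[float]:
        return sorted({e.time for e in self.events})

    @classmethod
    def daily(cls, species: int, value: float, t_end: float, start: float = 1.0) -> "ResetSchedule":
        times = np.arange(start, t_end + 1e-9, 1.0)
        return cls(ResetEvent(float(t), species, value) for t in times if t < t_end + 1e-9)


@dataclass
class Trajectory:
    """Time-ordered population states plus applied reset events.

    event_flag is 1 on rows whose state is the post-reset value at a reset
    time, 0 elsewhere.
    """

    t: np.ndarray
    N1: np.ndarray
    N2: np.ndarray
    event_flag: np.ndarray
    applied_events: list[ResetEvent] = field(default_factory=list)
    rtol: float = float("nan")
    atol: float = float("nan")

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.N1 = np.asarray(self.N1, dtype=float)
        self.N2 = np.asarray(self.N2, dtype=float)
        self.event_flag = np.asarray(self.event_flag, dtype=int)
        if not (len(self.t) == len(self.N1) == len(self.N2) == len(self.event_flag)):
            raise ValueError("trajectory arrays must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def final(self) -> PopulationState:
        return PopulationState(float(self.t[-1]), float(self.N1[-1]), float(self.N2[-1]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "N1": self.N1, "N2": self.N2, "event_flag": self.event_flag}
        )


@dataclass(frozen=True)
class InvasionReport:
    """Invasion-growth-rate analysis of species 1 against resident species 2.

    margin is (a12/a22) - (beta1/beta2); None (with margin_undefined=True)
    when beta2 == 0.  resident_collapsed flags 1 - beta2*Nh < 0, in which
    case N2w is floored at 0.
    """

    N2w: float
    N2wo: float
    IGRw: float
    IGRwo: float
    benefit: str  # "benefit" | "harm" | "neutral"
    margin: float | None
    margin_undefined: bool = False
    resident_collapsed: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


OUTCOME_LABELS = (
    "coexistence",
    "species1_excludes",
    "species2_excludes",
    "founder_control",
    "both_collapse",
)


@dataclass(frozen=True)
class OutcomeClassification:
    """Predicted long-run outcome plus the directional invasion growth rates."""

    label: str
    igr1: float
    igr2: float

    def __post_init__(self) -> None:
        if self.label not in OUTCOME_LABELS:
            raise ValueError(f"unknown outcome label {self.label!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CalibrationCurve:
    """Through-origin OD750 -> cell count line fitted on blank-corrected ODs."""

    slope: float  # cells ml^-1 per blank-corrected OD unit
    blank_od: float
    residual_sd: float
    n_points: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope) or self.slope <= 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope!r}")


@dataclass
class EstimationResult:
    """Point estimates for the eight coefficients, with optional bootstrap CIs.

    `zeroed` differs from `params` only for coefficients whose 95% CI
    strictly spans 0 (those are set to 0).
    """

    params: dict[str, float]
    method: str
    ci: dict[str, tuple[float, float]] | None = None
    zeroed: dict[str, float] | None = None
    n_boot: int | None = None
    seed: int | None = None
    n_failed: int = 0
    n_excluded: int = 0  # replicates with n_final == 0 excluded from log fits

    def to_model_params(self, Nh: float = 0.0) -> ModelParams:
        return ModelParams(Nh=Nh, **{k: self.params[k] for k in PARAM_NAMES})

    def to_dict(self) -> dict:
        d = {
            "params": self.params,
            "method": self.method,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_failed": self.n_failed,
            "n_excluded": self.n_excluded,
        }
        if self.ci is not None:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        if self.zeroed is not None:
            d["zeroed"] = self.zeroed
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "EstimationResult":
        ci = d.get("ci")
        if ci is not None:
            ci = {k: (float(v[0]), float(v[1])) for k, v in ci.items()}
        return cls(
            params={k: float(v) for k, v in d["params"].items()},
            method=d["method"],
            ci=ci,
            zeroed=d.get("zeroed"),
            n_boot=d.get("n_boot"),
            seed=d.get("seed"),
            n_failed=d.get("n_failed", 0),
            n_excluded=d.get("n_excluded", 0),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EstimationResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FitnessChange:
    """Normalized fitness contrast between herbivory and control coverage."""

    sa_herb: float
    sa_ctr: float
    value: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.value <= 1.0:
            raise ValueError("normalized fitness must lie in [-1, 1]")
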