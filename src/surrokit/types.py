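"""Domain types shared by every stage of the surrogacy pipeline.

Times are months, real-valued, measured from randomization; intervals are
half-open ``[t, t + dt)``.  Endpoint quantiles that the Kaplan-Meier curve
never crosses within follow-up are represented as ``None`` (printed ``NR``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented type invariant."""


class DrugClass(str, Enum):
    ICI = "ICI"
    MKI = "MKI"


class TreatmentLine(str, Enum):
    FIRST = "first"
    SECOND = "second"
    MIXED = "mixed"


class Phase(str, Enum):
    I_II = "I_II"
    III = "III"


class Endpoint(str, Enum):
    OS = "OS"
    PFS = "PFS"


def _check_quantiles(name: str, q1, med, q3) -> None:
    # only enforce ordering when all three are reported
    if q1 is not None and med is not None and q3 is not None:
        if not (q1 <= med <= q3):
            raise ValidationError(
                f"{name} quantiles out of order: q1={q1}, median={med}, q3={q3}"
            )


@dataclass(frozen=True)
class ArmRecord:
    """Summary statistics for one treatment arm, as published."""

    trial_id: str
    arm_id: str
    drug_class: DrugClass
    line: TreatmentLine
    n: int
    phase: Phase
    controlled: bool
    median_os: Optional[float] = None
    q1_os: Optional[float] = None
    q3_os: Optional[float] = None
    median_pfs: Optional[float] = None
    q1_pfs: Optional[float] = None
    q3_pfs: Optional[float] = None
    hr_os: Optional[float] = None
    hr_pfs: Optional[float] = None
    orr_pct: Optional[float] = None
    os_rate_end_fu_pct: Optional[float] = None
    followup_mo: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"arm {self.arm_id}: n must be >= 1, got {self.n}")
        _check_quantiles(f"arm {self.arm_id} OS", self.q1_os, self.median_os, self.q3_os)
        _check_quantiles(
            f"arm {self.arm_id} PFS", self.q1_pfs, self.median_pfs, self.q3_pfs
        )
        for label, hr in (("hr_os", self.hr_os), ("hr_pfs", self.hr_pfs)):
            if hr is not None and hr <= 0:
                raise ValidationError(f"arm {self.arm_id}: {label} must be > 0")
        for label, rate in (
            ("orr_pct", self.orr_pct),
            ("os_rate_end_fu_pct", self.os_rate_end_fu_pct),
        ):
            if rate is not None and not (0.0 <= rate <= 100.0):
                raise ValidationError(
                    f"arm {self.arm_id}: {label} must lie in [0, 100], got {rate}"
                )


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized survival coordinates plus the published numbers-at-risk table."""

    arm_id: str
    endpoint: Endpoint
    times: np.ndarray          # strictly increasing, times[0] == 0
    survival: np.ndarray       # non-increasing in [0, 1], survival[0] == 1
    risk_times: np.ndarray     # non-decreasing, risk_times[0] == 0
    n_risk: np.ndarray         # non-increasing integers
    total_events: Optional[int] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        rt = np.asarray(self.risk_times, dtype=float)
        nr = np.asarray(self.n_risk, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        object.__setattr__(self, "risk_times", rt)
        object.__setattr__(self, "n_risk", nr)
        if len(t) < 2:
            raise ValidationError("digitized curve needs at least 2 points")
        if t[0] != 0 or abs(s[0] - 1.0) > 1e-9:
            raise ValidationError("first digitized point must be (0, 1)")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("point times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValidationError("survival must be non-increasing")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValidationError("survival values must lie in [0, 1]")
        if len(rt) == 0 or rt[0] != 0:
            raise ValidationError("risk table must contain a time-0 entry")
        if np.any(np.diff(rt) < 0):
            raise ValidationError("risk-table times must be non-decreasing")
        if np.any(np.diff(nr) > 0):
            raise ValidationError("numbers at risk must be non-increasing")
        if np.any(nr < 0):
            raise ValidationError("numbers at risk must be non-negative")
        if self.total_events is not None and self.total_events < 0:
            raise ValidationError("total_events must be non-negative")

    @property
    def n(self) -> int:
        """Arm size: the published number at risk at time 0."""
        return int(self.n_risk[0])


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed (or simulated) per-patient time-to-event records."""

    arm_id: str
    endpoint: Endpoint
    times: np.ndarray
    events: np.ndarray  # boolean; True = event, False = censored

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=bool)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        if len(t) == 0:
            raise ValidationError("pseudo-IPD must contain at least one record")
        if len(t) != len(e):
            raise ValidationError("times and events must have equal length")
        if np.any(t <= 0):
            raise ValidationError("record times must be > 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with Greenwood variance at the event times.

    ``gw_sum`` is the cumulative Greenwood sum ``sum d/(n(n-d))`` up to each
    event time; ``greenwood_var`` is ``S^2 * gw_sum``.  ``at_risk`` and
    ``events`` carry the risk-set size and event count per distinct event
    time, which pooling and digitization rely on.
    """

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    gw_sum: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n: int
    max_followup: float

    def survival_at(self, t) -> np.ndarray:
        """Right-continuous step-function evaluation of S-hat."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.where(idx >= 0, np.concatenate(([1.0], self.survival))[idx + 1], 1.0)
        return out

    def gw_sum_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return np.where(idx >= 0, np.concatenate(([0.0], self.gw_sum))[idx + 1], 0.0)


@dataclass(frozen=True)
class QuantileEstimate:
    """Survival-time quantile (event fraction q); None encodes not-reached."""

    level: float
    time: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]

    @property
    def reached(self) -> bool:
        return self.time is not None


@dataclass(frozen=True)
class RMSTEstimate:
    tau: float
    value: float
    se: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 < self.value <= self.tau + 1e-9):
            raise ValidationError(
                f"RMST value {self.value} must lie in (0, tau={self.tau}]"
            )


@dataclass(frozen=True)
class PooledCurve:
    """Random-effects summary survival curve on a common time grid."""

    grid: np.ndarray
    pooled_survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    tau2: np.ndarray          # per grid interval, cloglog scale
    i2_per_interval: np.ndarray
    i2_pct: float             # summary I2 (interval containing the pooled median)
    n_studies: int

    def survival_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.grid, self.pooled_survival)


class TimeFunction(str, Enum):
    """Candidate time transforms for the time-dependent Cox interaction."""

    NONE = "none"
    LINEAR = "linear"
    LOG = "log"
    STEP6MO = "step6mo"


@dataclass(frozen=True)
class PHDiagnostics:
    log_hr: float
    schoenfeld_p: float
    ph_holds: bool
    chosen_time_fn: TimeFunction = TimeFunction.NONE
    aic_by_model: dict = field(default_factory=dict)
    hr_t: Optional[np.ndarray] = None  # shape (m, 2): time_mo, hr


@dataclass(frozen=True)
class SurrogacyFit:
    """Sample-size-weighted linear fit of a true-endpoint statistic on a surrogate."""

    x_label: str
    y_label: str
    slope: float
    intercept: float
    r2: float
    r2_ci_low: float
    r2_ci_high: float
    n_arms: int
    weights: np.ndarray
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class SubgroupInteraction:
    subgroup_var: str
    interaction_coef: float
    interaction_p: float
    groups: Sequence[str]

    def __post_init__(self) -> None:
        if not (0.0 <= self.interaction_p <= 1.0) or math.isnan(self.interaction_p):
            raise ValidationError("interaction p-value must lie in [0, 1]")
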