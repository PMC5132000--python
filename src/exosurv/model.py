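"""Core domain model: stimulation protocol, piecewise-constant hazards and the
discrete-frailty survival mixture.

The experimental design is a train of brief depolarizing K+ pulses applied to a
cell while single secretory granules are followed until they undergo exocytosis
(the event) or the recording ends (administrative censoring).  Time is measured
in seconds from the onset of the first pulse.  The hazard of exocytosis is
modelled as piecewise constant on the pulse / rest partition of the observation
window, with a cell-level binary covariate (healthy vs diabetic donor) acting
multiplicatively on the rates, and an optional two-point frailty Z in {1, eta}
marking membership of the immediately releasable pool (IRP).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationWarning(UserWarning):
    """Raised (as a warning) for suspicious but tolerable event-table rows."""


class SegmentClass(IntEnum):
    """Exhaustive partition of the observation window.

    ``FIRST_PULSE`` (k=0) is the first stimulation pulse, ``LATER_PULSE``
    (k=1) any subsequent pulse, ``BETWEEN`` (k=2) the rest intervals.
    """

    FIRST_PULSE = 0
    LATER_PULSE = 1
    BETWEEN = 2


@dataclass(frozen=True)
class StimulusProtocol:
    """Pulse timing and observation window defining the piecewise time axis.

    Parameters
    ----------
    pulse_starts
        Strictly increasing pulse onset times, in seconds.
    pulse_duration
        Duration of each pulse, in seconds.  Pulse intervals are half-open,
        ``[s, s + duration)``.
    observation_end
        Administrative censoring time (end of the recording), in seconds.
    """

    pulse_starts: tuple[float, ...]
    pulse_duration: float
    observation_end: float

    def __post_init__(self) -> None:
        starts = tuple(float(s) for s in self.pulse_starts)
        object.__setattr__(self, "pulse_starts", starts)
        if len(starts) == 0:
            raise ValueError("protocol needs at least one pulse")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if any(b - a < self.pulse_duration for a, b in zip(starts, starts[1:])):
            raise ValueError("pulse intervals must be disjoint and increasing")
        if starts[0] < 0 or starts[-1] + self.pulse_duration > self.observation_end:
            raise ValueError("pulse intervals must lie within [0, observation_end]")

    @classmethod
    def default(cls) -> "StimulusProtocol":
        """Ten 1-s pulses at 10-s spacing, observation ending at 100 s."""
        return cls(tuple(float(10 * i) for i in range(10)), 1.0, 100.0)

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_starts)

    @property
    def total_pulse_time(self) -> float:
        return self.n_pulses * self.pulse_duration

    def segment_of(self, t: float) -> SegmentClass:
        """Classify a time point into first-pulse / later-pulse / between."""
        if not 0 <= t < self.observation_end:
            raise ValueError(
                f"t={t} outside the observation window [0, {self.observation_end})"
            )
        for idx, s in enumerate(self.pulse_starts):
            if s <= t < s + self.pulse_duration:
                return SegmentClass.FIRST_PULSE if idx == 0 else SegmentClass.LATER_PULSE
        return SegmentClass.BETWEEN

    def class_exposures(self, t):
        """Time spent in each segment class during ``[0, t)``.

        Vectorized over ``t``.  Returns an array of shape ``t.shape + (3,)``
        ordered as (first pulse, later pulses, between).
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.observation_end):
            raise ValueError("t outside [0, observation_end]")
        starts = np.asarray(self.pulse_starts)
        # overlap of [0, t) with each pulse interval [s, s+d)
        overlap = np.clip(t[..., None] - starts, 0.0, self.pulse_duration)
        first = overlap[..., 0]
        later = overlap[..., 1:].sum(axis=-1)
        out = np.stack([first, later, t - first - later], axis=-1)
        return out


def segment_of(t: float, protocol: StimulusProtocol) -> SegmentClass:
    """Functional alias for :meth:`StimulusProtocol.segment_of`."""
    return protocol.segment_of(t)


@dataclass(frozen=True)
class PoissonParams:
    """Parameters of the three-branch piecewise-constant hazard.

    ``alpha[k] = log rho_k`` are log rates (log s^-1) for the first pulse
    (k=0), later pulses (k=1) and between pulses (k=2); ``beta[k]`` are the
    corresponding log hazard ratios of the diabetic covariate.
    """

    alpha: tuple[float, float, float]
    beta: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def rho(self) -> tuple[float, float, float]:
        return tuple(math.exp(a) for a in self.alpha)

    def log_rate(self, k: int, X: int) -> float:
        return self.alpha[k] + self.beta[k] * X

    def rates(self, X: int) -> np.ndarray:
        """(rate_first, rate_later, rate_between) for covariate value X."""
        return np.exp(np.asarray(self.alpha) + np.asarray(self.beta) * X)


@dataclass(frozen=True)
class FrailtyParams:
    """Parameters of the discrete-frailty (IRP) model.

    The baseline hazard is ``exp(alpha1)`` during every pulse (first and
    later pulses share the rate; diabetes does not act during pulses) and
    ``exp(alpha2 + beta2 * X)`` between pulses.  A granule carries frailty
    ``Z = eta`` with probability ``pi_X`` (it belongs to the IRP) and
    ``Z = 1`` otherwise; the conditional hazard is ``Z`` times baseline.
    """

    alpha1: float
    alpha2: float
    beta2: float
    eta: float
    pi0: float
    pi1: float

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not (0 <= self.pi0 <= 1 and 0 <= self.pi1 <= 1):
            raise ValueError("pi0, pi1 must be probabilities")

    @property
    def rho1(self) -> float:
        return math.exp(self.alpha1)

    @property
    def rho2(self) -> float:
        return math.exp(self.alpha2)

    def pi(self, X: int) -> float:
        return self.pi1 if X else self.pi0

    def rates(self, X: int) -> np.ndarray:
        """(pulse rate, pulse rate, between rate) for covariate value X."""
        pulse = math.exp(self.alpha1)
        between = math.exp(self.alpha2 + self.beta2 * X)
        return np.array([pulse, pulse, between])


def hazard_at(t, params, X: int = 0, z: float = 1.0,
              protocol: StimulusProtocol | None = None) -> float:
    """Conditional hazard ``z * exp(alpha_k + beta_k X)`` at time ``t``.

    ``z`` is the frailty value (1 for the plain Poisson model, ``eta`` for an
    IRP granule).
    """
    if t < 0:
        raise ValueError("negative time")
    protocol = protocol or StimulusProtocol.default()
    k = protocol.segment_of(t)
    rate = params.rates(X)[int(k)]
    return z * rate


def cumulative_baseline_hazard(t, params, X: int = 0,
                               protocol: StimulusProtocol | None = None):
    """Cumulative baseline hazard ``M0(t|X)`` (dimensionless), vectorized in t.

    Exact closed form: the hazard is constant on each segment, so M0 is the
    sum of rate x overlap over the segments intersecting [0, t); it is
    continuous, nondecreasing and piecewise linear.
    """
    protocol = protocol or StimulusProtocol.default()
    expo = protocol.class_exposures(t)
    return expo @ params.rates(X)


def marginal_survival(t, X: int, params: FrailtyParams,
                      protocol: StimulusProtocol | None = None):
    """Marginal survival ``S(t|X) = pi_X e^{-eta M0} + (1-pi_X) e^{-M0}``.

    The frailty has been averaged out: the population survival is a mixture
    of the IRP (high-hazard) and non-IRP survival curves.
    """
    m0 = cumulative_baseline_hazard(t, params, X, protocol)
    pi = params.pi(X)
    return pi * np.exp(-params.eta * m0) + (1.0 - pi) * np.exp(-m0)


@dataclass(frozen=True)
class SurvivalCurve:
    """A survival or cumulative-incidence curve on a time grid."""

    times: np.ndarray
    values: np.ndarray
    kind: str  # "survival" or "incidence"
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.kind not in ("survival", "incidence"):
            raise ValueError("kind must be 'survival' or 'incidence'")
        if t.shape != v.shape:
            raise ValueError("times and values must have equal shape")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("curve values must lie in [0, 1]")


def incidence_components(grid, X: int, params: FrailtyParams,
                         protocol: StimulusProtocol | None = None
                         ) -> dict[str, SurvivalCurve]:
    """Marginal cumulative incidence and its IRP / non-IRP decomposition.

    Returns curves ``marginal`` = 1 - S(t|X), ``irp`` = pi_X (1 - e^{-eta M0})
    and ``non_irp`` = (1 - pi_X)(1 - e^{-M0}); the two components sum to the
    marginal at every grid point.
    """
    grid = np.asarray(grid, dtype=float)
    m0 = cumulative_baseline_hazard(grid, params, X, protocol)
    pi = params.pi(X)
    irp = pi * (1.0 - np.exp(-params.eta * m0))
    non_irp = (1.0 - pi) * (1.0 - np.exp(-m0))
    return {
        "marginal": SurvivalCurve(grid, irp + non_irp, "incidence", "marginal"),
        "irp": SurvivalCurve(grid, irp, "incidence", "irp"),
        "non_irp": SurvivalCurve(grid, non_irp, "incidence", "non_irp"),
    }


@dataclass(frozen=True)
class GranuleRecord:
    """One granule: cluster label, unit label, observed time, event indicator
    and the cell-level diabetic covariate."""

    cell_id: str
    granule_id: str
    time: float
    event: int
    diabetic: int


_EVENT_COLUMNS = ["cell_id", "granule_id", "time", "event", "diabetic"]


@dataclass
class EventDataset:
    """Clustered right-censored time-to-event observations plus protocol.

    ``table`` has one row per granule with columns cell_id, granule_id, time,
    event (1 = exocytosis observed, 0 = censored) and diabetic (0/1,
    constant within a cell).
    """

    table: pd.DataFrame
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol.default)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).reset_index(drop=True)
        missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        df = df[_EVENT_COLUMNS].copy()
        df["time"] = df["time"].astype(float)
        df["event"] = df["event"].astype(int)
        df["diabetic"] = df["diabetic"].astype(int)
        if len(df) == 0:
            raise ValueError("event table is empty")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 or 1")
        if not df["diabetic"].isin([0, 1]).all():
            raise ValueError("diabetic must be 0 or 1")
        end = self.protocol.observation_end
        if (df["time"] <= 0).any() or (df["time"] > end).any():
            raise ValueError("times must lie in (0, observation_end]")
        per_cell = df.groupby("cell_id")["diabetic"].nunique()
        if (per_cell > 1).any():
            bad = per_cell[per_cell > 1].index.tolist()
            raise ValueError(f"diabetic covariate varies within cell(s) {bad}")
        censored_early = (df["event"] == 0) & (df["time"] < end)
        if censored_early.any():
            warnings.warn(
                f"{int(censored_early.sum())} censored rows have time < "
                f"observation_end={end}; administrative censoring expects "
                "time == observation_end",
                ValidationWarning,
                stacklevel=2,
            )
        self.table = df

    @classmethod
    def from_records(cls, records: Sequence[GranuleRecord],
                     protocol: StimulusProtocol | None = None) -> "EventDataset":
        df = pd.DataFrame([r.__dict__ for r in records])
        return cls(df, protocol or StimulusProtocol.default())

    @property
    def n_clusters(self) -> int:
        return self.table["cell_id"].nunique()

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.table.groupby("cell_id").size()

    @property
    def n_events(self) -> int:
        return int(self.table["event"].sum())

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, diabetic: int) -> "EventDataset":
        sub = self.table[self.table["diabetic"] == diabetic]
        if len(sub) == 0:
            raise ValueError(f"no granules with diabetic={diabetic}")
        return EventDataset(sub, self.protocol)
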