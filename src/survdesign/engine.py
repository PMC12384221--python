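"""Patient-level trial simulation.

A trial is generated in three steps: accrual (uniform entry times over
the accrual window), latent event and drop-out times per patient from
the arm-specific piecewise-exponential models, and a follow-up regime
that turns the latent times into the observed analysis dataset.

Two regimes are supported, matching how survival trials are sized:

* **event-driven** -- the analysis happens at the calendar time of the
  D-th event; every patient still on study is administratively censored
  then.  If fewer than D events can ever occur (events lost to
  drop-out), the analysis happens when the last patient resolves and
  proceeds with the attained events.
* **fixed-horizon** -- every patient is followed until the event or a
  fixed time-on-study horizon, whichever comes first; the analysis
  calendar time is accrual duration plus the horizon.

Calendar time starts at the first possible enrollment (time 0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .models import (
    EffectPattern,
    PiecewiseExpModel,
    apply_effect,
    dropout_rate_from_cumulative,
)
from .seeding import as_seed_sequence

__all__ = [
    "AccrualModel",
    "EventDriven",
    "FixedHorizon",
    "TrialDesign",
    "TrialLatents",
    "TrialDataset",
    "sample_latents",
    "event_driven_analysis",
    "fixed_horizon_analysis",
    "simulate_trial",
    "trial_duration",
    "observed_dropout_rate",
]


@dataclass(frozen=True)
class EventDriven:
    """Analyze at the calendar time of the ``target_events``-th event."""

    target_events: int

    def __post_init__(self) -> None:
        if self.target_events < 1:
            raise ValueError("target_events must be at least 1")


@dataclass(frozen=True)
class FixedHorizon:
    """Follow each patient to min(event, ``horizon`` years on study)."""

    horizon: float

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")


Regime = Union[EventDriven, FixedHorizon]


@dataclass(frozen=True)
class AccrualModel:
    """Uniform accrual of ``total_n`` patients over ``accrual_duration`` years.

    ``ratio`` is the treatment:control allocation ratio (1.0 means 1:1).
    """

    total_n: int
    accrual_duration: float
    ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.total_n < 2:
            raise ValueError("need at least one patient per arm")
        if self.accrual_duration <= 0:
            raise ValueError("accrual_duration must be positive")
        if self.ratio <= 0:
            raise ValueError("allocation ratio must be positive")
        if self.ratio == 1.0 and self.total_n % 2:
            raise ValueError("total_n must be even under 1:1 allocation")

    @property
    def n_treatment(self) -> int:
        return round(self.total_n * self.ratio / (1.0 + self.ratio))

    @property
    def n_control(self) -> int:
        return self.total_n - self.n_treatment


@dataclass(frozen=True)
class TrialDesign:
    """Complete specification of a simulated two-arm trial."""

    control: PiecewiseExpModel
    effect: EffectPattern
    accrual: AccrualModel
    regime: Regime
    dropout_5yr: float = 0.0
    alpha: float = 0.025

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if not 0.0 <= self.dropout_5yr < 1.0:
            raise ValueError("dropout_5yr must be in [0, 1)")
        if (isinstance(self.regime, EventDriven)
                and self.regime.target_events > self.accrual.total_n):
            raise ValueError("event target exceeds the number of patients")

    @property
    def treatment(self) -> PiecewiseExpModel:
        return apply_effect(self.control, self.effect)

    @property
    def dropout_rate(self) -> float:
        return dropout_rate_from_cumulative(self.dropout_5yr)


@dataclass
class TrialLatents:
    """Latent per-patient times for a batch of simulated trials.

    ``entry``, ``event_time`` and ``dropout_time`` are ``(reps, n)``
    matrices (rows are independent trial replicates); ``arm`` is shared
    across replicates (0 = control, 1 = treatment).  Drop-out times are
    ``inf`` when the design has no drop-out.
    """

    arm: np.ndarray
    entry: np.ndarray
    event_time: np.ndarray
    dropout_time: np.ndarray
    accrual_duration: float

    @property
    def reps(self) -> int:
        return self.entry.shape[0]


# process tags for substream derivation, fixed so that scenarios sharing
# a master seed couple their latent times process by process
_STREAM_ENTRY, _STREAM_EVENT_C, _STREAM_EVENT_T, _STREAM_DROPOUT = range(4)


def sample_latents(design: TrialDesign, reps: int, seed) -> TrialLatents:
    """Draw latent entry, event and drop-out times for ``reps`` trials.

    Four independent substreams (entry, control events, treatment
    events, drop-out) are derived from ``seed``; latent times are
    inverse-transform maps of the substream uniforms, so two designs
    differing only in, say, the drop-out rate see identical event times
    and monotone-coupled drop-out times under the same seed.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    ss = as_seed_sequence(seed)
    streams = [np.random.default_rng(child) for child in ss.spawn(4)]
    n0, n1 = design.accrual.n_control, design.accrual.n_treatment
    n = n0 + n1
    arm = np.repeat(np.array([0, 1], dtype=np.int8), [n0, n1])

    a = design.accrual.accrual_duration
    entry = streams[_STREAM_ENTRY].uniform(0.0, a, size=(reps, n))

    # -log(1-U) maps U in [0,1) to a standard-exponential deviate
    e_c = -np.log1p(-streams[_STREAM_EVENT_C].uniform(size=(reps, n0)))
    e_t = -np.log1p(-streams[_STREAM_EVENT_T].uniform(size=(reps, n1)))
    event_time = np.empty((reps, n))
    event_time[:, :n0] = design.control.inverse_cumulative_hazard(e_c)
    event_time[:, n0:] = design.treatment.inverse_cumulative_hazard(e_t)

    e_d = -np.log1p(-streams[_STREAM_DROPOUT].uniform(size=(reps, n)))
    lam_d = design.dropout_rate
    if lam_d > 0:
        dropout_time = e_d / lam_d
    else:
        dropout_time = np.full((reps, n), np.inf)
    return TrialLatents(arm, entry, event_time, dropout_time, a)


def event_driven_analysis(latents: TrialLatents, target_events: int):
    """Observed data at the calendar time of the ``target_events``-th event.

    Returns ``(time, event, include, analysis_time, n_events)`` where
    ``time``/``event``/``include`` are ``(reps, n)`` matrices (``include``
    marks patients enrolled by the analysis time) and the last two are
    per-replicate vectors.  When fewer than ``target_events`` events are
    attainable the analysis time falls back to the last resolution
    (event or drop-out) and the attained events are analyzed.
    """
    X, C = latents.event_time, latents.dropout_time
    cal_event = np.where(X < C, latents.entry + X, np.inf)
    kth = np.partition(cal_event, target_events - 1, axis=1)[:, target_events - 1]
    short = ~np.isfinite(kth)
    if short.any():
        last_resolution = (latents.entry + np.minimum(X, C)).max(axis=1)
        analysis_time = np.where(short, last_resolution, kth)
    else:
        analysis_time = kth
    follow = analysis_time[:, None] - latents.entry
    include = follow >= 0.0
    # event membership decided on the calendar scale: the analysis time is
    # itself one of the event calendar times, so `cal_event <= A` is exact
    # where `X <= A - entry` could lose the defining event to rounding
    event = (cal_event <= analysis_time[:, None]) & include
    time = np.where(event, X,
                    np.minimum(C, np.maximum(follow, 0.0)))
    n_events = event.sum(axis=1)
    return time, event, include, analysis_time, n_events


def fixed_horizon_analysis(latents: TrialLatents, horizon: float):
    """Observed data when each patient is followed to min(event, horizon)."""
    X, C = latents.event_time, latents.dropout_time
    time = np.minimum(np.minimum(X, C), horizon)
    event = (X <= C) & (X <= horizon)
    include = np.ones_like(event, dtype=bool)
    analysis_time = np.full(latents.reps, latents.accrual_duration + horizon)
    return time, event, include, analysis_time, event.sum(axis=1)


@dataclass
class TrialDataset:
    """Analysis snapshot of one simulated trial.

    Observed columns: ``arm`` (0 control, 1 treatment), ``entry``
    (calendar enrollment time), ``time`` (observed years on study) and
    ``event`` (1 = event, 0 = censored).  The latent event and drop-out
    times are retained alongside (they exist only in simulation; CSV
    output carries the observed columns unless asked otherwise).
    """

    arm: np.ndarray
    entry: np.ndarray
    time: np.ndarray
    event: np.ndarray
    analysis_time: float
    event_time: Optional[np.ndarray] = field(default=None, repr=False)
    dropout_time: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.arm = np.asarray(self.arm, dtype=np.int8)
        self.entry = np.asarray(self.entry, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=np.int8)
        if np.any(self.time < 0):
            raise ValueError("observed times must be non-negative")

    def __len__(self) -> int:
        return self.arm.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self, include_latent: bool = False) -> pd.DataFrame:
        cols = {"arm": self.arm, "entry": self.entry,
                "time": self.time, "event": self.event}
        if include_latent:
            if self.event_time is None or self.dropout_time is None:
                raise ValueError("latent times are not available")
            cols["event_time"] = self.event_time
            cols["dropout_time"] = self.dropout_time
        return pd.DataFrame(cols)

    def to_csv(self, path_or_buf, include_latent: bool = False) -> None:
        """Write the dataset (header row; event coded 1, censored 0)."""
        self.to_frame(include_latent).to_csv(
            path_or_buf, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path_or_buf) -> "TrialDataset":
        df = pd.read_csv(path_or_buf, float_precision="round_trip")
        required = {"arm", "entry", "time", "event"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        return cls(
            arm=df["arm"].to_numpy(),
            entry=df["entry"].to_numpy(float),
            time=df["time"].to_numpy(float),
            event=df["event"].to_numpy(),
            analysis_time=float((df["entry"] + df["time"]).max()),
            event_time=df["event_time"].to_numpy(float)
            if "event_time" in df else None,
            dropout_time=df["dropout_time"].to_numpy(float)
            if "dropout_time" in df else None,
        )


def simulate_trial(design: TrialDesign, seed) -> TrialDataset:
    """Simulate a single trial under ``design`` and return its dataset."""
    latents = sample_latents(design, 1, seed)
    if isinstance(design.regime, EventDriven):
        time, event, include, analysis_time, _ = event_driven_analysis(
            latents, design.regime.target_events)
    else:
        time, event, include, analysis_time, _ = fixed_horizon_analysis(
            latents, design.regime.horizon)
    keep = include[0]
    return TrialDataset(
        arm=latents.arm[keep],
        entry=latents.entry[0, keep],
        time=time[0, keep],
        event=event[0, keep],
        analysis_time=float(analysis_time[0]),
        event_time=latents.event_time[0, keep],
        dropout_time=latents.dropout_time[0, keep],
    )


def trial_duration(dataset: TrialDataset) -> float:
    """Calendar time from first possible enrollment to the analysis."""
    return float(dataset.analysis_time)


def observed_dropout_rate(dataset: TrialDataset, horizon: float) -> float:
    """Fraction of patients dropping out before both their event and ``horizon``.

    Uses the latent times, so the answer does not depend on the regime
    the dataset was observed under (a drop-out hidden behind earlier
    administrative censoring still counts).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if dataset.event_time is None or dataset.dropout_time is None:
        raise ValueError("latent times are required to attribute drop-out")
    dropped = ((dataset.dropout_time < dataset.event_time)
               & (dataset.dropout_time < horizon))
    return float(dropped.mean())
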