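"""Analytic design calculators for event-driven survival trials.

The number of events comes from the Schoenfeld formula for the log-rank
test; the enrollment size is then the smallest whole-month cohort whose
expected event count, under uniform accrual and exponential event (and
optionally drop-out) processes, reaches the event target by the planned
analysis time.  Horizons for the fixed-duration designs (survival
probability at ``t``, restricted mean up to ``tau``) are calibrated
empirically by simulation because no convenient closed form exists for
their power under censoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log

import numpy as np
from scipy.stats import norm

__all__ = [
    "DesignSpec",
    "schoenfeld_events",
    "expected_events",
    "required_sample_size",
    "calibrate_horizon",
]


@dataclass(frozen=True)
class DesignSpec:
    """Design inputs for the event-count and sample-size calculators.

    ``accrual_rate`` is in patients per year; ``horizon`` is the planned
    calendar time of the analysis (years from first enrollment).
    """

    alpha: float = 0.025
    power: float = 0.90
    hr: float = 0.6
    p0: float = 0.5
    p1: float = 0.5
    control_rate: float = log(2.0) / 3.0
    accrual_rate: float = 120.0
    horizon: float = 5.0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must be in (0, 1)")
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")
        if abs(self.p0 + self.p1 - 1.0) > 1e-12 or self.p0 <= 0 or self.p1 <= 0:
            raise ValueError("allocation fractions must be positive and sum to 1")
        if self.control_rate <= 0 or self.accrual_rate <= 0 or self.horizon <= 0:
            raise ValueError("rates and horizon must be positive")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be non-negative")


def schoenfeld_events(spec: DesignSpec) -> int:
    """Required event count for the one-sided log-rank design.

    ``D = ceil[(z_{1-alpha} + z_{1-beta})^2 / (p0 p1 (ln HR)^2)]``.
    Symmetric in HR vs 1/HR; undefined at HR = 1.
    """
    if spec.hr == 1.0:
        raise ValueError("hazard ratio of 1 gives no events to detect")
    za = norm.ppf(1.0 - spec.alpha)
    zb = norm.ppf(spec.power)
    return ceil((za + zb) ** 2 / (spec.p0 * spec.p1 * log(spec.hr) ** 2))


def _arm_event_fraction(rate: float, dropout_rate: float,
                        accrual_duration: float, t_cal: float) -> float:
    """P(event observed by calendar ``t_cal``) for a uniformly accrued patient.

    The event (rate ``lam_e``) competes with exponential drop-out (rate
    ``lam_d``); entry is uniform on [0, accrual_duration].  Averaging the
    per-entry probability ``(lam_e/theta)(1 - e^{-theta (T-e)})`` with
    ``theta = lam_e + lam_d`` over entries gives the closed form below.
    """
    theta = rate + dropout_rate
    a = accrual_duration
    bracket = 1.0 - np.exp(-theta * t_cal) * np.expm1(theta * a) / (theta * a)
    return rate / theta * bracket


def expected_events(n: int, accrual_duration: float, control_rate: float,
                    hr: float, t_cal: float, dropout_rate: float = 0.0,
                    p1: float = 0.5) -> float:
    """Expected observed events by calendar time ``t_cal``, both arms.

    Exponential event processes (control rate, treatment rate = HR x
    control rate), uniform accrual over ``accrual_duration`` years, and
    an optional exponential drop-out competing with the event.  Requires
    ``t_cal >= accrual_duration`` (every patient must be enrolled by the
    analysis).
    """
    if t_cal < accrual_duration:
        raise ValueError("analysis time must not precede the end of accrual")
    if n < 1:
        raise ValueError("n must be positive")
    n1 = n * p1
    n0 = n - n1
    return (n0 * _arm_event_fraction(control_rate, dropout_rate,
                                     accrual_duration, t_cal)
            + n1 * _arm_event_fraction(hr * control_rate, dropout_rate,
                                       accrual_duration, t_cal))


def required_sample_size(spec: DesignSpec, events: int,
                         monthly_accrual: int = 10,
                         t_cal: float | None = None) -> int:
    """Smallest enrollment (whole accrual months) reaching the event target.

    Scans ``n`` in multiples of ``monthly_accrual`` — accrual runs in
    whole monthly cohorts — until the closed-form expected event count at
    calendar time ``t_cal`` reaches ``events``.  Accrual cannot extend
    past ``t_cal``, which bounds the search; if even the largest feasible
    cohort falls short the target is declared infeasible.
    """
    if events < 1:
        raise ValueError("events must be at least 1")
    if monthly_accrual < 1:
        raise ValueError("monthly_accrual must be at least 1")
    t_cal = spec.horizon if t_cal is None else float(t_cal)
    max_months = int(t_cal * 12.0 + 1e-9)
    for months in range(1, max_months + 1):
        n = months * monthly_accrual
        exp_ev = expected_events(n, months / 12.0, spec.control_rate,
                                 spec.hr, t_cal, spec.dropout_rate, spec.p1)
        if exp_ev >= events:
            return n
    raise ValueError(
        f"target of {events} events is infeasible: accrual is capped at "
        f"{max_months} months ({max_months * monthly_accrual} patients) "
        f"by the analysis time {t_cal:g}y")


def calibrate_horizon(test: str, grid, design, reps: int, seed,
                      target_power: float = 0.90,
                      alpha: float = 0.025) -> tuple[float, float]:
    """Pick the follow-up horizon whose empirical power is nearest the target.

    ``test`` is ``"survprob"`` or ``"rmst"``; each candidate horizon in
    ``grid`` is used both as the per-patient follow-up limit and as the
    test's time point, power is estimated by simulation with ``reps``
    trials per candidate, and the horizon minimizing ``|power - target|``
    is returned with its power (ties go to the shorter horizon).
    """
    from .engine import FixedHorizon, TrialDesign
    from .scenarios import estimate_power

    grid = [float(h) for h in grid]
    if not grid:
        raise ValueError("candidate grid must be non-empty")
    best: tuple[float, float, float] | None = None
    for i, h in enumerate(sorted(grid)):
        d = TrialDesign(control=design.control, effect=design.effect,
                        accrual=design.accrual, regime=FixedHorizon(h),
                        dropout_5yr=design.dropout_5yr, alpha=alpha)
        power, _ = estimate_power(d, test, reps, seed, horizon=h)
        gap = abs(power - target_power)
        if best is None or gap < best[0]:
            best = (gap, h, power)
    return best[1], best[2]
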