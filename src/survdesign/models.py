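"""Piecewise-exponential survival distributions.

Every event and drop-out process in the simulator is driven by a
piecewise-exponential distribution: the hazard is constant on a finite
set of segments and the last segment extends to infinity.  The family is
closed under multiplicative, piecewise-constant hazard ratios (so a
time-varying treatment effect applied to a piecewise-exponential control
arm stays in the family), and it admits closed forms for the survival
function, the cumulative hazard, the restricted mean, and the inverse
CDF, which keeps the Monte-Carlo engine free of quadrature error.

Time is measured in years throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from math import log

import numpy as np

LN2 = log(2.0)

EFFECT_KINDS = ("proportional", "early_benefit", "late_benefit", "crossing")

__all__ = [
    "PiecewiseExpModel",
    "EffectPattern",
    "survival_at",
    "rmst_closed_form",
    "sample_times",
    "apply_effect",
    "dropout_rate_from_cumulative",
    "LN2",
]


@dataclass(frozen=True)
class PiecewiseExpModel:
    """Survival distribution with a piecewise-constant hazard.

    Parameters
    ----------
    breaks
        Strictly increasing segment start times (years).  The first entry
        must be ``0``; the final segment extends to infinity.
    rates
        Per-year hazard on each segment; one rate per entry of ``breaks``.

    Notes
    -----
    The cumulative hazard ``H`` is piecewise linear and continuous, so
    ``S(x) = exp(-H(x))`` is continuous and strictly decreasing, with
    ``S(0) = 1``.  The hazard is right-continuous: a changepoint ``k``
    belongs to the *later* segment.
    """

    breaks: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        breaks = tuple(float(b) for b in self.breaks)
        rates = tuple(float(r) for r in self.rates)
        object.__setattr__(self, "breaks", breaks)
        object.__setattr__(self, "rates", rates)
        if not breaks or breaks[0] != 0.0:
            raise ValueError("breaks must be non-empty and start at 0")
        if len(rates) != len(breaks):
            raise ValueError("need exactly one hazard rate per segment")
        if any(b1 <= b0 for b0, b1 in zip(breaks, breaks[1:])):
            raise ValueError("breaks must be strictly increasing")
        if any((not np.isfinite(r)) or r <= 0.0 for r in rates):
            raise ValueError("all hazard rates must be positive and finite")

    # -- constructors -------------------------------------------------

    @classmethod
    def exponential(cls, rate: float) -> "PiecewiseExpModel":
        """Single-segment (plain exponential) model with hazard ``rate``."""
        return cls((0.0,), (float(rate),))

    @classmethod
    def from_median(cls, median: float) -> "PiecewiseExpModel":
        """Exponential model with the given median survival time (years)."""
        if median <= 0:
            raise ValueError("median must be positive")
        return cls.exponential(LN2 / median)

    # -- cached arrays -------------------------------------------------

    @cached_property
    def _breaks(self) -> np.ndarray:
        return np.asarray(self.breaks, dtype=float)

    @cached_property
    def _rates(self) -> np.ndarray:
        return np.asarray(self.rates, dtype=float)

    @cached_property
    def _cumhaz_at_breaks(self) -> np.ndarray:
        widths = np.diff(self._breaks)
        return np.concatenate(([0.0], np.cumsum(self._rates[:-1] * widths)))

    # -- closed forms --------------------------------------------------

    def hazard(self, x) -> np.ndarray:
        """Hazard h(x); right-continuous at changepoints."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("time must be non-negative")
        idx = np.searchsorted(self._breaks, x, side="right") - 1
        return self._rates[idx]

    def cumulative_hazard(self, x) -> np.ndarray:
        """H(x) = integral of the hazard on [0, x]; piecewise linear."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("time must be non-negative")
        idx = np.searchsorted(self._breaks, x, side="right") - 1
        return self._cumhaz_at_breaks[idx] + self._rates[idx] * (x - self._breaks[idx])

    def survival(self, x) -> np.ndarray:
        """S(x) = Pr(X > x) = exp(-H(x))."""
        return np.exp(-self.cumulative_hazard(x))

    def inverse_cumulative_hazard(self, e) -> np.ndarray:
        """Solve H(x) = e segment by segment (e >= 0, vectorized)."""
        e = np.asarray(e, dtype=float)
        if np.any(e < 0):
            raise ValueError("cumulative hazard must be non-negative")
        idx = np.searchsorted(self._cumhaz_at_breaks, e, side="right") - 1
        return self._breaks[idx] + (e - self._cumhaz_at_breaks[idx]) / self._rates[idx]

    def ppf(self, q) -> np.ndarray:
        """Quantile function of the event time (inverse CDF)."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q >= 1)):
            raise ValueError("quantile levels must lie in [0, 1)")
        return self.inverse_cumulative_hazard(-np.log1p(-q))

    def median(self) -> float:
        return float(self.inverse_cumulative_hazard(LN2))

    def rmst(self, tau: float) -> float:
        """Restricted mean survival time: integral of S on [0, tau], exact."""
        tau = float(tau)
        if tau <= 0:
            raise ValueError("restriction time tau must be positive")
        upper = np.append(self._breaks[1:], np.inf)
        widths = np.clip(np.minimum(upper, tau) - self._breaks, 0.0, None)
        # integral of exp(-(H_j + r*(u-b_j))) over a segment of width w
        seg = np.exp(-self._cumhaz_at_breaks) * -np.expm1(-self._rates * widths) / self._rates
        return float(seg.sum())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. event times by inverse-transform sampling."""
        if n < 1:
            raise ValueError("n must be at least 1")
        return self.inverse_cumulative_hazard(rng.standard_exponential(int(n)))


@dataclass(frozen=True)
class EffectPattern:
    """Multiplicative, piecewise-constant treatment effect.

    ``segments`` lists ``(start, hazard_ratio)`` pairs with strictly
    increasing starts beginning at 0; each hazard ratio multiplies the
    control-arm hazard from that start until the next one.  ``kind``
    labels the field's standard patterns (proportional hazards, early
    benefit, late benefit, crossing hazards).
    """

    kind: str
    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"kind must be one of {EFFECT_KINDS}")
        segments = tuple((float(s), float(h)) for s, h in self.segments)
        object.__setattr__(self, "segments", segments)
        if not segments or segments[0][0] != 0.0:
            raise ValueError("effect segments must start at 0")
        starts = [s for s, _ in segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment starts must be strictly increasing")
        if any(h <= 0 for _, h in segments):
            raise ValueError("hazard ratios must be positive")
        if self.kind == "proportional" and len(segments) != 1:
            raise ValueError("a proportional effect has a single hazard ratio")

    @classmethod
    def proportional(cls, hr: float) -> "EffectPattern":
        return cls("proportional", ((0.0, float(hr)),))

    @classmethod
    def null(cls) -> "EffectPattern":
        return cls.proportional(1.0)

    @classmethod
    def early_benefit(cls, k: float, hr_early: float = 0.4,
                      hr_late: float = 0.8) -> "EffectPattern":
        """Strong effect before ``k`` years post enrollment, weaker after."""
        return cls("early_benefit", ((0.0, hr_early), (float(k), hr_late)))

    @classmethod
    def late_benefit(cls, k: float, hr_early: float = 0.8,
                     hr_late: float = 0.4) -> "EffectPattern":
        """Weak effect before ``k`` years post enrollment, stronger after."""
        return cls("late_benefit", ((0.0, hr_early), (float(k), hr_late)))

    @classmethod
    def crossing(cls, k: float, hr_early: float = 1.2,
                 hr_late: float = 0.6) -> "EffectPattern":
        """Harmful before ``k`` years, beneficial after (crossing hazards)."""
        return cls("crossing", ((0.0, hr_early), (float(k), hr_late)))

    @cached_property
    def _starts(self) -> np.ndarray:
        return np.asarray([s for s, _ in self.segments], dtype=float)

    @cached_property
    def _hrs(self) -> np.ndarray:
        return np.asarray([h for _, h in self.segments], dtype=float)

    def hazard_ratio_at(self, x) -> np.ndarray:
        """HR(x); right-continuous at segment starts (patient time)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("time must be non-negative")
        idx = np.searchsorted(self._starts, x, side="right") - 1
        return self._hrs[idx]

    @property
    def is_null(self) -> bool:
        return all(h == 1.0 for _, h in self.segments)


# ---------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------

def survival_at(model: PiecewiseExpModel, x) -> np.ndarray:
    """Survival probability S(x) = Pr(X > x) of ``model`` at time(s) ``x``."""
    return model.survival(x)


def rmst_closed_form(model: PiecewiseExpModel, tau: float) -> float:
    """Exact restricted mean survival time of ``model`` up to ``tau`` years."""
    return model.rmst(tau)


def sample_times(model: PiecewiseExpModel, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """``n`` i.i.d. event times drawn from ``model`` (inverse transform)."""
    return model.sample(n, rng)


def apply_effect(control: PiecewiseExpModel,
                 effect: EffectPattern) -> PiecewiseExpModel:
    """Treatment-arm model: control hazard times the pattern's HR(x).

    The result's changepoints are the union of the control changepoints
    and the effect-segment starts; on each resulting segment both the
    control hazard and the hazard ratio are constant.
    """
    breaks = np.union1d(control._breaks, effect._starts)
    rates = control.hazard(breaks) * effect.hazard_ratio_at(breaks)
    return PiecewiseExpModel(tuple(breaks), tuple(rates))


def dropout_rate_from_cumulative(p: float, horizon: float = 5.0) -> float:
    """Exponential drop-out rate with cumulative probability ``p`` by ``horizon``.

    Drop-out is an exponential process specified by its CDF at a fixed
    horizon (by convention 5 years); the unique consistent rate is
    ``-ln(1 - p) / horizon``.  ``p = 0`` means no drop-out (rate 0).
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("cumulative drop-out proportion must be in [0, 1)")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return -log(1.0 - p) / horizon if p > 0 else 0.0
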