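"""The deviation study: scenario grid, Monte-Carlo driver, aggregation.

The reference design is a two-arm 1:1 trial: exponential control arm
with median survival 3 years, proportional hazard ratio 0.6, one-sided
alpha 0.025 sized for 90% power (162 events, 350 patients accrued
uniformly at 10/month), no drop-out.  Event-driven tests (log-rank and
the two MaxCombo variants) analyze at the 162nd event; the fixed-
duration tests follow each patient to t = 3.5 years (survival
probability) or tau = 4.5 years (restricted mean).

`build_grid` enumerates the deviation families — control-arm median,
effect magnitude, the three non-proportional-hazards patterns, accrual
duration and drop-out — plus null (HR = 1) twins for the families where
Type I error is meaningful.  `run_scenario` estimates rejection rates,
trial-duration distributions and observed drop-out for every test under
its own follow-up regime, coupling the latent patient times across
regimes within an iteration to cut between-test Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import (
    AccrualModel,
    EventDriven,
    FixedHorizon,
    TrialDesign,
    TrialLatents,
    event_driven_analysis,
    fixed_horizon_analysis,
    sample_latents,
)
from .models import EffectPattern, PiecewiseExpModel
from .seeding import substream
from .survtests import (
    MAXCOMBO_2,
    MAXCOMBO_3,
    FHWeight,
    maxcombo,
    risk_sets_from_arrays,
    rmst_test_arrays,
    surv_prob_test_arrays,
    weighted_logrank,
)

__all__ = [
    "REFERENCE",
    "ReferenceDesign",
    "Scenario",
    "ScenarioResult",
    "build_grid",
    "run_scenario",
    "estimate_power",
    "summarize",
    "TEST_NAMES",
]

TEST_NAMES = ("logrank", "maxcombo2", "maxcombo3", "survprob", "rmst")

# stable family codes for seed-substream derivation: running any subset
# of the grid reproduces the numbers of the full grid
FAMILY_CODES = {
    "baseline": 1,
    "effect_magnitude": 2,
    "nph_early": 3,
    "nph_late": 4,
    "nph_crossing": 5,
    "accrual": 6,
    "dropout": 7,
    "null_baseline": 8,
    "null_accrual": 9,
    "null_dropout": 10,
    "custom": 99,
}


@dataclass(frozen=True)
class ReferenceDesign:
    """The undisturbed design every deviation is measured against.

    The planning arithmetic (10 patients/month, so 350 patients in 35
    months) lives in :mod:`survdesign.design`; the simulated reference
    trial enrolls uniformly over 3 years, the accrual duration the
    deviation families perturb.
    """

    control_median: float = 3.0
    hr: float = 0.6
    n: int = 350
    accrual_years: float = 3.0
    target_events: int = 162
    t_fixed: float = 3.5
    tau: float = 4.5
    alpha: float = 0.025
    maxcombo2_weights: tuple[FHWeight, ...] = MAXCOMBO_2
    maxcombo3_weights: tuple[FHWeight, ...] = MAXCOMBO_3


REFERENCE = ReferenceDesign()


@dataclass(frozen=True)
class Scenario:
    """One point of the deviation grid.

    Only the deviating parameter differs from the reference; ``is_null``
    marks Type-I-error twins (hazard ratio forced to 1).
    """

    label: str
    family: str
    effect: EffectPattern
    control_median: float = REFERENCE.control_median
    accrual_years: float = REFERENCE.accrual_years
    dropout_5yr: float = 0.0
    seed_index: int = 0

    @property
    def is_null(self) -> bool:
        return self.effect.is_null

    def control_model(self) -> PiecewiseExpModel:
        return PiecewiseExpModel.from_median(self.control_median)

    def accrual(self, ref: ReferenceDesign = REFERENCE) -> AccrualModel:
        return AccrualModel(ref.n, self.accrual_years)

    def design(self, regime, ref: ReferenceDesign = REFERENCE) -> TrialDesign:
        return TrialDesign(control=self.control_model(), effect=self.effect,
                           accrual=self.accrual(ref), regime=regime,
                           dropout_5yr=self.dropout_5yr, alpha=ref.alpha)

    def seed_key(self) -> tuple[int, int]:
        return (FAMILY_CODES.get(self.family, FAMILY_CODES["custom"]),
                self.seed_index)


def _grid_values(ref: ReferenceDesign):
    return {
        "baseline": [2.0, 2.5, 3.0, 4.0, 5.0],
        "effect_magnitude": [0.4, 0.5, 0.6, 0.7, 0.8],
        "nph_early": [1.0, 2.0, 3.0, 4.0, 5.0],
        "nph_late": [1.0, 2.0, 3.0, 4.0, 5.0],
        "nph_crossing": [0.25, 0.5, 1.0, 1.5, 2.0],
        "accrual": sorted({2.0, 2.5, ref.accrual_years, 3.5, 4.0}),
        "dropout": [0.0, 0.15, 0.30, 0.45, 0.60],
    }


def build_grid(families: Optional[Sequence[str]] = None,
               include_null: bool = True,
               ref: ReferenceDesign = REFERENCE) -> list[Scenario]:
    """Enumerate the deviation scenarios (35 alternatives + 13 nulls).

    Alternatives: control-arm medians {2, 2.5, 3, 4, 5}; proportional HR
    {0.4 ... 0.8}; early benefit (0.4 then 0.8) and late benefit (0.8
    then 0.4) with changepoint k in {1 ... 5}; crossing hazards (1.2
    then 0.6) with k in {0.25, 0.5, 1, 1.5, 2}; accrual durations {2,
    2.5, 35/12, 3.5, 4}; 5-year drop-out {0, 0.15, 0.30, 0.45, 0.60}.
    Null twins (HR = 1) cover the baseline medians and the deviating
    accrual and drop-out values.  ``families`` filters by family name.
    """
    vals = _grid_values(ref)
    hr = EffectPattern.proportional(ref.hr)
    grid: list[Scenario] = []

    def add(label, family, i, **kw):
        grid.append(Scenario(label=label, family=family, seed_index=i, **kw))

    for i, m in enumerate(vals["baseline"]):
        add(f"baseline_median_{m:g}", "baseline", i,
            effect=hr, control_median=m)
    for i, h in enumerate(vals["effect_magnitude"]):
        add(f"hr_{h:g}", "effect_magnitude", i,
            effect=EffectPattern.proportional(h))
    for i, k in enumerate(vals["nph_early"]):
        add(f"early_benefit_k{k:g}", "nph_early", i,
            effect=EffectPattern.early_benefit(k))
    for i, k in enumerate(vals["nph_late"]):
        add(f"late_benefit_k{k:g}", "nph_late", i,
            effect=EffectPattern.late_benefit(k))
    for i, k in enumerate(vals["nph_crossing"]):
        add(f"crossing_k{k:g}", "nph_crossing", i,
            effect=EffectPattern.crossing(k))
    for i, a in enumerate(vals["accrual"]):
        add(f"accrual_{a:g}y", "accrual", i, effect=hr, accrual_years=a)
    for i, p in enumerate(vals["dropout"]):
        add(f"dropout_{100 * p:g}pct", "dropout", i,
            effect=hr, dropout_5yr=p)

    if include_null:
        null = EffectPattern.null()
        for i, m in enumerate(vals["baseline"]):
            add(f"null_baseline_median_{m:g}", "null_baseline", i,
                effect=null, control_median=m)
        acc_dev = [a for a in vals["accrual"] if a != ref.accrual_years]
        for i, a in enumerate(acc_dev):
            add(f"null_accrual_{a:g}y", "null_accrual", i,
                effect=null, accrual_years=a)
        drop_dev = [p for p in vals["dropout"] if p > 0]
        for i, p in enumerate(drop_dev):
            add(f"null_dropout_{100 * p:g}pct", "null_dropout", i,
                effect=null, dropout_5yr=p)

    if families is not None:
        families = set(families)
        unknown = families - set(FAMILY_CODES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")
        grid = [s for s in grid if s.family in families]
    return grid


def _duration_summary(durations: np.ndarray) -> dict[str, float]:
    q = np.percentile(durations, [2.5, 50.0, 97.5])
    return {"median": float(q[1]), "min": float(durations.min()),
            "max": float(durations.max()), "q2.5": float(q[0]),
            "q97.5": float(q[2])}


@dataclass
class ScenarioResult:
    """Monte-Carlo operating characteristics of one scenario."""

    scenario: Scenario
    reps: int
    rejection_rate: dict[str, float]
    rejection_se: dict[str, float]
    n_failed: dict[str, int]
    duration_event_driven: dict[str, float]
    duration_fixed_t: dict[str, float]
    duration_fixed_tau: dict[str, float]
    dropout_median_t: float
    dropout_median_tau: float
    frac_events_short: float
    events_at_analysis: np.ndarray = field(repr=False)

    def events_summary(self) -> dict[str, float]:
        e = self.events_at_analysis
        return {"mean": float(e.mean()), "min": float(e.min()),
                "max": float(e.max())}


def _coupled_latents(scenario: Scenario, reps: int, master_seed,
                     ref: ReferenceDesign) -> TrialLatents:
    key = scenario.seed_key()
    design = scenario.design(EventDriven(ref.target_events), ref)
    return sample_latents(design, reps, substream(master_seed, *key))


def run_scenario(scenario: Scenario, reps: int = 10_000, master_seed: int = 0,
                 ref: ReferenceDesign = REFERENCE,
                 couple_regimes: bool = True) -> ScenarioResult:
    """Estimate all five tests' operating characteristics for one scenario.

    Each iteration draws one set of latent patient times and analyzes it
    under every regime (event-driven for log-rank/MaxCombo, fixed t and
    tau for the survival-probability and RMST tests), so the same
    patients underlie every test.  Set ``couple_regimes=False`` to draw
    independent latent times per regime instead.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    lat = _coupled_latents(scenario, reps, master_seed, ref)
    if couple_regimes:
        lat_t = lat_tau = lat
    else:
        key = scenario.seed_key()
        design = scenario.design(EventDriven(ref.target_events), ref)
        lat_t = sample_latents(design, reps,
                               substream(master_seed, *key, 1))
        lat_tau = sample_latents(design, reps,
                                 substream(master_seed, *key, 2))

    ev_time, ev_event, ev_inc, ev_A, ev_n = event_driven_analysis(
        lat, ref.target_events)
    t_time, t_event, _, t_A, _ = fixed_horizon_analysis(lat_t, ref.t_fixed)
    u_time, u_event, _, u_A, _ = fixed_horizon_analysis(lat_tau, ref.tau)

    alpha = ref.alpha
    rejects = {name: np.zeros(reps, dtype=bool) for name in TEST_NAMES}
    failed = {name: 0 for name in TEST_NAMES}
    for r in range(reps):
        keep = ev_inc[r]
        table = risk_sets_from_arrays(ev_time[r, keep], ev_event[r, keep],
                                      lat.arm[keep])
        results = {
            "logrank": weighted_logrank(table, FHWeight(0, 0), alpha),
            "maxcombo2": maxcombo(table, ref.maxcombo2_weights, alpha),
            "maxcombo3": maxcombo(table, ref.maxcombo3_weights, alpha),
            "survprob": surv_prob_test_arrays(
                t_time[r], t_event[r], lat_t.arm, ref.t_fixed, alpha),
            "rmst": rmst_test_arrays(
                u_time[r], u_event[r], lat_tau.arm, ref.tau, alpha),
        }
        for name, res in results.items():
            rejects[name][r] = res.reject
            if res.note:
                failed[name] += 1

    rate = {k: float(v.mean()) for k, v in rejects.items()}
    se = {k: float(np.sqrt(p * (1.0 - p) / reps)) for k, p in rate.items()}

    dropped_t = ((lat.dropout_time < lat.event_time)
                 & (lat.dropout_time < ref.t_fixed)).mean(axis=1)
    dropped_tau = ((lat.dropout_time < lat.event_time)
                   & (lat.dropout_time < ref.tau)).mean(axis=1)

    return ScenarioResult(
        scenario=scenario,
        reps=reps,
        rejection_rate=rate,
        rejection_se=se,
        n_failed=failed,
        duration_event_driven=_duration_summary(ev_A),
        duration_fixed_t=_duration_summary(t_A),
        duration_fixed_tau=_duration_summary(u_A),
        dropout_median_t=float(np.median(dropped_t)),
        dropout_median_tau=float(np.median(dropped_tau)),
        frac_events_short=float((ev_n < ref.target_events).mean()),
        events_at_analysis=np.asarray(ev_n),
    )


def estimate_power(design: TrialDesign, test: str, reps: int, seed,
                   horizon: float | None = None,
                   weights: Sequence[FHWeight] | None = None
                   ) -> tuple[float, float]:
    """Monte-Carlo rejection rate of one test under one design.

    ``test`` is one of ``logrank``, ``maxcombo``, ``survprob``, ``rmst``.
    For the fixed-duration tests ``horizon`` (default: the regime's
    follow-up horizon) is both the follow-up limit and the test's time
    point.  Returns ``(rate, binomial standard error)``.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    lat = sample_latents(design, reps, seed)
    alpha = design.alpha
    if test in ("logrank", "maxcombo"):
        if not isinstance(design.regime, EventDriven):
            raise ValueError(f"{test} requires an event-driven design")
        time, event, inc, _, _ = event_driven_analysis(
            lat, design.regime.target_events)
    else:
        if horizon is None:
            if not isinstance(design.regime, FixedHorizon):
                raise ValueError("horizon is required for fixed-duration tests")
            horizon = design.regime.horizon
        time, event, inc, _, _ = fixed_horizon_analysis(lat, horizon)

    rej = np.zeros(reps, dtype=bool)
    for r in range(reps):
        keep = inc[r]
        if test == "logrank":
            table = risk_sets_from_arrays(time[r, keep], event[r, keep],
                                          lat.arm[keep])
            res = weighted_logrank(table, FHWeight(0, 0), alpha)
        elif test == "maxcombo":
            table = risk_sets_from_arrays(time[r, keep], event[r, keep],
                                          lat.arm[keep])
            res = maxcombo(table, weights or MAXCOMBO_2, alpha)
        elif test == "survprob":
            res = surv_prob_test_arrays(time[r], event[r], lat.arm,
                                        horizon, alpha)
        elif test == "rmst":
            res = rmst_test_arrays(time[r], event[r], lat.arm,
                                   horizon, alpha)
        else:
            raise ValueError(f"unknown test {test!r}")
        rej[r] = res.reject
    p = float(rej.mean())
    return p, float(np.sqrt(p * (1.0 - p) / reps))


def summarize(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Tidy table: one row per (scenario, test), stable column order."""
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    for res in results:
        s = res.scenario
        evs = res.events_summary()
        durations = {
            "logrank": res.duration_event_driven,
            "maxcombo2": res.duration_event_driven,
            "maxcombo3": res.duration_event_driven,
            "survprob": res.duration_fixed_t,
            "rmst": res.duration_fixed_tau,
        }
        for test in TEST_NAMES:
            dur = durations[test]
            rows.append({
                "scenario": s.label,
                "family": s.family,
                "is_null": s.is_null,
                "test": test,
                "rejection_rate": res.rejection_rate[test],
                "mc_se": res.rejection_se[test],
                "reps": res.reps,
                "n_failed": res.n_failed[test],
                "duration_median": dur["median"],
                "duration_min": dur["min"],
                "duration_max": dur["max"],
                "duration_q2.5": dur["q2.5"],
                "duration_q97.5": dur["q97.5"],
                "dropout_median_3.5y": res.dropout_median_t,
                "dropout_median_4.5y": res.dropout_median_tau,
                "frac_events_short": res.frac_events_short,
                "events_mean": evs["mean"],
                "events_min": evs["min"],
                "events_max": evs["max"],
            })
    return pd.DataFrame(rows)
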