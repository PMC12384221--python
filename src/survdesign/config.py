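"""Run configuration: YAML schema, validation, defaults.

An empty config reproduces the reference design (162 events, 350
patients, t = 3.5, tau = 4.5, one-sided alpha 0.025, 10,000 iterations).
Unknown keys are rejected with their key path so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import yaml

from .scenarios import FAMILY_CODES
from .survtests import MAXCOMBO_2, MAXCOMBO_3, FHWeight

__all__ = ["RunConfig", "parse_config"]

_RUNNABLE_FAMILIES = tuple(f for f in FAMILY_CODES if f != "custom")


@dataclass
class RunConfig:
    """Validated configuration for a scenario-grid run."""

    seed: int = 0
    reps: int = 10_000
    alpha: float = 0.025
    families: Optional[tuple[str, ...]] = None  # None = full grid
    out_dir: str = "results"
    control_median: float = 3.0
    hr: float = 0.6
    n: int = 350
    accrual_years: float = 3.0
    target_events: int = 162
    t_fixed: float = 3.5
    tau: float = 4.5
    maxcombo2_weights: tuple[FHWeight, ...] = MAXCOMBO_2
    maxcombo3_weights: tuple[FHWeight, ...] = MAXCOMBO_3

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps: must be at least 1")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha: must be in (0, 0.5)")
        if self.seed < 0:
            raise ValueError("seed: must be non-negative")
        if self.n < 2 or self.n % 2:
            raise ValueError("n: must be an even count of patients")
        if self.target_events < 1 or self.target_events > self.n:
            raise ValueError("target_events: must be in [1, n]")
        for key in ("control_median", "accrual_years", "t_fixed", "tau"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key}: must be positive")
        if self.hr <= 0:
            raise ValueError("hr: must be positive")
        if self.families is not None:
            unknown = set(self.families) - set(_RUNNABLE_FAMILIES)
            if unknown:
                raise ValueError(
                    f"families: unknown {sorted(unknown)}; "
                    f"choose from {_RUNNABLE_FAMILIES}")
            self.families = tuple(self.families)

    def reference(self):
        from .scenarios import ReferenceDesign
        return ReferenceDesign(
            control_median=self.control_median, hr=self.hr, n=self.n,
            accrual_years=self.accrual_years,
            target_events=self.target_events, t_fixed=self.t_fixed,
            tau=self.tau, alpha=self.alpha,
            maxcombo2_weights=self.maxcombo2_weights,
            maxcombo3_weights=self.maxcombo3_weights)


def _parse_weights(key: str, raw) -> tuple[FHWeight, ...]:
    try:
        pairs = [FHWeight(float(r), float(g)) for r, g in raw]
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"{key}: expected a list of [rho, gamma] pairs") from exc
    if not pairs:
        raise ValueError(f"{key}: needs at least one [rho, gamma] pair")
    return tuple(pairs)


def parse_config(path) -> RunConfig:
    """Load and validate a YAML config; missing keys take the defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of option: value")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("maxcombo2_weights", "maxcombo3_weights"):
        if key in raw:
            raw[key] = _parse_weights(key, raw[key])
    if "families" in raw and raw["families"] is not None:
        if isinstance(raw["families"], str):
            raw["families"] = (raw["families"],)
        else:
            raw["families"] = tuple(raw["families"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ValueError(f"invalid config: {exc}") from exc
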