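import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import survdesign as sd

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def control_median3() -> sd.PiecewiseExpModel:
    """Exponential control arm with median survival 3 years."""
    return sd.PiecewiseExpModel.from_median(3.0)


@pytest.fixture(scope="session")
def reference_event_design(control_median3) -> sd.TrialDesign:
    """Reference event-driven design: 162 events, 350 patients, HR 0.6."""
    return sd.TrialDesign(
        control=control_median3,
        effect=sd.EffectPattern.proportional(0.6),
        accrual=sd.AccrualModel(350, 3.0),
        regime=sd.EventDriven(162),
    )


def fixed_design(horizon: float, hr: float = 0.6, median: float = 3.0,
                 dropout: float = 0.0) -> sd.TrialDesign:
    return sd.TrialDesign(
        control=sd.PiecewiseExpModel.from_median(median),
        effect=sd.EffectPattern.proportional(hr),
        accrual=sd.AccrualModel(350, 3.0),
        regime=sd.FixedHorizon(horizon),
        dropout_5yr=dropout,
    )


@pytest.fixture(scope="session")
def scenario_models():
    """Control and treatment models of every scenario in the deviation grid."""
    models = {}
    for s in sd.build_grid():
        c = s.control_model()
        models[("control", s.label)] = c
        models[("treatment", s.label)] = sd.apply_effect(c, s.effect)
    return models


def dataset_from_arrays(time, event, arm) -> sd.TrialDataset:
    time = np.asarray(time, dtype=float)
    return sd.TrialDataset(
        arm=np.asarray(arm), entry=np.zeros_like(time), time=time,
        event=np.asarray(event), analysis_time=float(time.max()))
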