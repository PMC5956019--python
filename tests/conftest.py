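import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mstkit as mk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def noiseless():
    """Trace model with all stochastic/systematic perturbations off."""
    return mk.TraceNoiseModel(noise_cv=0.0, bleach_rate=0.0)


@pytest.fixture
def serum_saturation_design():
    """Post-immune-serum conventional design: 16-point 1:1 series,
    0.25 nM tracer, 50 nM top final binding sites."""
    return mk.TitrationDesign.from_top_final(50.0, tracer_final=0.25)


@pytest.fixture
def standard_competition_design():
    """Standard competition condition: 0.25 nM tracer, 10 nM sites,
    4000 nM top final competitor (16,000 nM working)."""
    return mk.TitrationDesign(
        top_working_conc=16000.0, tracer_final=0.25, antibody_sites_final=10.0
    )


def flat_trace(conc=1.0, level=1000.0, cid="c0"):
    t = np.arange(0.0, 40.0, 0.25)
    return mk.MstTrace(cid, conc, t, np.full_like(t, level))


@pytest.fixture
def make_flat_trace():
    return flat_trace
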