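import numpy as np
import pytest

from lakeprod.light import ParSeries
from lakeprod.pe_curves import PICurve
from lakeprod.synthetic import SimulationSpec, gen_diel_par, gen_par_profile


@pytest.fixture
def spec() -> SimulationSpec:
    return SimulationSpec(seed=1)


@pytest.fixture
def psoe_curve() -> PICurve:
    """The study-mean PSOE Platt parameters."""
    return PICurve(p_s=271.0, alpha=3.31, beta=0.109)


@pytest.fixture
def diel_par(spec) -> ParSeries:
    return gen_diel_par(spec)


@pytest.fixture
def clean_profile(spec):
    return gen_par_profile(spec)


@pytest.fixture
def half_sine_field(spec, diel_par):
    from lakeprod.light import LightField
    return LightField(kd=spec.kd, series=diel_par)


def approx_rel(a, b, rel):
    return abs(a - b) <= rel * abs(b)
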