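import numpy as np
import pytest

from biomethane import gas_preprocess as gp
from biomethane.kinetics import KineticModelSpec, model_curve
from biomethane.synthetic_data import BMPSimConfig, generate_bmp_dataset


@pytest.fixture(scope="session")
def clean_sim():
    """Zero-noise simulated BMP dataset (shared; generators are pure)."""
    return generate_bmp_dataset(BMPSimConfig(noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-noise simulated BMP dataset."""
    return generate_bmp_dataset(BMPSimConfig())


def preprocess_sim(sim):
    """Blank-correct every substrate channel of a simulated dataset."""
    channels = {cid: df for cid, df in sim.gas_logs.groupby("channel_id")}
    blanks = [m for m in sim.channel_meta if m.is_blank]
    blank_curve = gp.blank_curve_per_g_inoculum(
        [channels[m.channel_id] for m in blanks], blanks
    )
    curves, metas = [], []
    for m in sim.channel_meta:
        if m.is_blank:
            continue
        curves.append(gp.specific_methane_curve(channels[m.channel_id], m, blank_curve))
        metas.append(m)
    return curves, metas


@pytest.fixture(scope="session")
def daily_grid():
    return np.arange(0.0, 26.0)


@pytest.fixture(scope="session")
def gompertz_curve(daily_grid):
    spec = KineticModelSpec("modified_gompertz", {"B0": 300.0, "Rmax": 150.0, "lambda_": 0.2})
    return gp.YieldCurve(daily_grid, model_curve(spec, daily_grid)), spec
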