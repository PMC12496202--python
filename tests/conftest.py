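import numpy as np
import pytest

from audiomech import synthetic
from audiomech.constants import BOLTZMANN, DEFAULT_TEMPERATURE

# female passive receiver: f0 = 337.52 Hz, Q = 0.69, apparent mass 77.45 ng
FEMALE_PASSIVE = dict(f0=337.52, q=0.69, mass=7.745e-11)


@pytest.fixture
def female_passive_params() -> synthetic.OscillatorParams:
    return synthetic.OscillatorParams.from_resonance(
        FEMALE_PASSIVE["f0"], FEMALE_PASSIVE["q"], FEMALE_PASSIVE["mass"]
    )


@pytest.fixture
def equipartition_x2(female_passive_params) -> float:
    return (
        BOLTZMANN * DEFAULT_TEMPERATURE / female_passive_params.stiffness_n_per_m
    )


def model_spectrum(f0, q, amplitude, band=(1.0, 10_000.0), df=1.0):
    """Exact model curve on a uniform grid (no noise)."""
    from audiomech.spectra import AmplitudeSpectrum, oscillator_velocity_model

    f = np.arange(band[0], band[1] + df / 2, df)
    return AmplitudeSpectrum(f, oscillator_velocity_model(f, f0, q, amplitude))
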