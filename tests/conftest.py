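"""Shared fixtures: canonical stimuli, noise-free playback, parameter sets.

Session-scoped where generation is not free, so the suite reuses one copy.
"""

import numpy as np
import pytest

from neckdec import (
    Anthropometrics,
    GROUP_PARAMS,
    PlaybackParams,
    generate_playback,
    generate_prts,
    gravity_torque_coefficient,
)

SAMPLE_RATE = 100.0
PERIOD = 60.5


@pytest.fixture(scope="session")
def stim_1deg():
    """Two periods of the canonical 1 degree peak-to-peak stimulus."""
    return generate_prts(1.0, duration=2 * PERIOD, sample_rate=SAMPLE_RATE, seed=0)


@pytest.fixture(scope="session")
def stim_half_deg():
    return generate_prts(0.5, duration=2 * PERIOD, sample_rate=SAMPLE_RATE, seed=0)


@pytest.fixture(scope="session")
def quiet_playback(stim_1deg):
    """Deterministic noise-free leg/trunk sway for the 1 degree stimulus."""
    return generate_playback(stim_1deg, PlaybackParams(noise_rms=0.0), seed=1)


@pytest.fixture(scope="session")
def quiet_playback_half(stim_half_deg):
    return generate_playback(stim_half_deg, PlaybackParams(noise_rms=0.0), seed=1)


@pytest.fixture(scope="session")
def anthro():
    return Anthropometrics()


@pytest.fixture(scope="session")
def co_ec_params():
    return GROUP_PARAMS[("CO", "EC")]


@pytest.fixture(scope="session")
def psp_eo_params():
    return GROUP_PARAMS[("PSP", "EO")]


def linear_oracle(freqs, params, anthro, playback_params=None):
    """Closed-form head-in-space transfer of the linearised loop.

    Valid when theta_fs = 0 (dead-band inactive).  The playback is the exact
    second-order low-pass used by the frequency-domain playback generator.
    """
    pp = playback_params or PlaybackParams(noise_rms=0.0)
    w = 2 * np.pi * np.asarray(freqs, dtype=float)
    jw = 1j * w
    w0 = 2 * np.pi * pp.cutoff
    lp = w0**2 / (jw + w0) ** 2
    p_l = pp.gain_leg * lp
    p_t = pp.gain_trunk * lp
    mgh = gravity_torque_coefficient(anthro)
    num = (params.k_pp + params.k_pd * jw) * p_t + anthro.m_h * anthro.h_h * jw**2 * (
        anthro.l_l * p_l + anthro.l_t * p_t
    )
    den = (
        anthro.j_h * jw**2
        - mgh
        + (params.k_pp + params.k_pd * jw)
        + (1 + params.k_g) * (params.k_p + params.k_d * jw) * np.exp(-jw * params.delta_t)
    )
    return num / den
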