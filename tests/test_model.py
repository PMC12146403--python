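import numpy as np
import pytest

from neckdec import (
    ControllerParams,
    KinematicPlayback,
    SimulationConfig,
    band_average,
    control_torques,
    dead_band,
    estimate_frf,
    estimate_platform_tilt,
    gravity_torque_coefficient,
    simulate_head,
)
from neckdec.errors import InvalidArgumentError, SimulationDivergenceError

from conftest import linear_oracle


def _params(**overrides):
    base = dict(k_p=5.0, k_d=1.0, k_pp=37.591, k_pd=8.4535, k_g=0.1, theta_fs=0.0, delta_t=0.0)
    base.update(overrides)
    return ControllerParams(**base)


# ---------------------------------------------------------------- dead band

def test_dead_band_worked_examples():
    assert dead_band(0.25, 0.1) == pytest.approx(0.15)
    assert dead_band(-0.25, 0.1) == pytest.approx(-0.15)
    assert dead_band(0.05, 0.1) == 0.0
    assert dead_band(0.1, 0.1) == 0.0


def test_dead_band_array_and_oddness():
    x = np.linspace(-1, 1, 101)
    out = dead_band(x, 0.3)
    assert np.allclose(out, -dead_band(-x, 0.3))
    assert np.all(np.abs(out) <= np.abs(x))


def test_dead_band_zero_threshold_is_identity():
    x = np.array([-2.0, -0.1, 0.0, 0.4])
    assert np.array_equal(dead_band(x, 0.0), x)


def test_dead_band_negative_threshold_raises():
    with pytest.raises(InvalidArgumentError):
        dead_band(1.0, -0.1)


# ------------------------------------------------------------ tilt estimator

def test_tilt_estimator_identity_limit():
    fs = 100.0
    t = np.arange(0, 10, 1 / fs)
    alpha = 0.02 * np.sin(2 * np.pi * 0.4 * t)
    est = estimate_platform_tilt(alpha, theta_fs=0.0, sample_rate=fs)
    assert np.allclose(est, alpha - alpha[0], atol=1e-4)


def test_tilt_estimator_ramp_worked_example():
    # constant 0.5 rad/s ramp for 10 s with a 0.2 rad/s threshold registers
    # (0.5 - 0.2) * 10 = 3 rad
    fs = 100.0
    t = np.arange(0, 10 + 1 / fs, 1 / fs)
    alpha = 0.5 * t
    est = estimate_platform_tilt(alpha, theta_fs=0.2, sample_rate=fs)
    assert est[-1] == pytest.approx(3.0, rel=1e-3)


def test_tilt_estimator_below_threshold_registers_nothing():
    fs = 100.0
    t = np.arange(0, 10, 1 / fs)
    est = estimate_platform_tilt(0.1 * t, theta_fs=0.2, sample_rate=fs)
    assert np.allclose(est, 0.0, atol=1e-9)


# ------------------------------------------------------------------ torques

def test_gravity_torque_coefficient(anthro):
    # 4.5 kg * 9.81 m/s^2 * 0.2053 m = 9.063 N m/rad
    assert gravity_torque_coefficient(anthro) == pytest.approx(9.063, abs=1e-3)


def test_passive_torque_worked_example(co_ec_params):
    _, tau_pass = control_torques(0.0, 0.0, 0.1, 0.0, co_ec_params)
    assert tau_pass == pytest.approx(-3.7591)


def test_active_torque_worked_example():
    p = _params(k_p=1.0, k_d=0.0, k_g=0.1)
    tau_act, _ = control_torques(0.1, 0.0, 0.0, 0.0, p)
    # u = 0.1 + 0.1 * 0.1 = 0.11 -> tau = -0.11
    assert tau_act == pytest.approx(-0.11)


def test_torques_restore_toward_zero(co_ec_params):
    tau_act, tau_pass = control_torques(0.05, 0.0, 0.05, 0.0, co_ec_params)
    assert tau_act < 0 and tau_pass < 0


# --------------------------------------------------------------- simulation

def _still_stimulus(duration=20.0, fs=100.0):
    from neckdec.prts import PRTSStimulus

    n = int(duration * fs)
    zeros = np.zeros(n)
    return PRTSStimulus(
        velocity_trace=zeros,
        position_trace=zeros.copy(),
        sample_rate=fs,
        state_duration=0.25,
        speed_level=0.0,
        period=60.5,
        amplitude_pp=0.0,
        excited_freqs=[],
        seed=0,
    )


def _still_playback(duration=20.0, fs=100.0):
    n = int(duration * fs)
    return KinematicPlayback(np.zeros(n), np.zeros(n), fs)


def test_equilibrium_stays_at_rest():
    head = simulate_head(_still_stimulus(), _still_playback(), _params())
    assert np.allclose(head, 0.0, atol=1e-12)


def test_perturbed_head_returns_to_equilibrium():
    head = simulate_head(
        _still_stimulus(40.0), _still_playback(40.0), _params(), initial_state=(0.05, 0.0)
    )
    assert abs(head[-1]) < 1e-4
    assert np.all(np.abs(head) < 0.1)


def test_understiff_passive_only_head_falls():
    # passive stiffness below mgh = 9.063 N m/rad and no active control:
    # gravity wins and the head diverges from any nonzero angle
    p = ControllerParams(k_p=0.0, k_d=0.0, k_pp=2.0, k_pd=1.0, k_g=0.0, theta_fs=0.0, delta_t=0.0)
    with pytest.raises(SimulationDivergenceError):
        simulate_head(
            _still_stimulus(60.0),
            _still_playback(60.0),
            p,
            initial_state=(0.01, 0.0),
            config=SimulationConfig(divergence_limit=10.0),
        )


def test_overstiff_passive_only_head_stands():
    p = ControllerParams(k_p=0.0, k_d=0.0, k_pp=30.0, k_pd=5.0, k_g=0.0, theta_fs=0.0, delta_t=0.0)
    head = simulate_head(
        _still_stimulus(40.0), _still_playback(40.0), p, initial_state=(0.01, 0.0)
    )
    assert abs(head[-1]) < 1e-3


def test_linear_limit_matches_oracle(stim_1deg, quiet_playback, anthro):
    # acceptance criterion: theta_fs = 0, delta_t = 0 simulation matches the
    # hand-derived closed-loop transfer within 1% at all 11 bands
    p = _params()
    head = simulate_head(
        stim_1deg,
        quiet_playback,
        p,
        anthro,
        config=SimulationConfig(playback_smooth_cutoff=None),
    )
    vec = estimate_frf(stim_1deg, np.rad2deg(head))
    oracle_raw = linear_oracle(stim_1deg.excited_freqs, p, anthro)
    oracle = band_average(oracle_raw, stim_1deg.excited_freqs, band_map=vec.band_map)
    rel = np.abs(vec.values - oracle.values) / np.abs(oracle.values)
    assert rel.max() < 0.01


def test_delay_handling_matches_oracle(stim_1deg, quiet_playback, anthro):
    # sub-sample-capable delay path: also within 1% of the closed form
    p = _params(delta_t=0.11315)
    head = simulate_head(
        stim_1deg,
        quiet_playback,
        p,
        anthro,
        config=SimulationConfig(playback_smooth_cutoff=None),
    )
    vec = estimate_frf(stim_1deg, np.rad2deg(head))
    oracle_raw = linear_oracle(stim_1deg.excited_freqs, p, anthro)
    oracle = band_average(oracle_raw, stim_1deg.excited_freqs, band_map=vec.band_map)
    rel = np.abs(vec.values - oracle.values) / np.abs(oracle.values)
    assert rel.max() < 0.01


def test_delay_changes_the_response_as_the_closed_form_predicts(stim_1deg, quiet_playback, anthro):
    # the simulated FRF with a 0.08 s loop delay must match the closed form
    # with that delay and clearly deviate from the delay-free closed form,
    # confirming the delay is actually applied inside the loop
    cfg = SimulationConfig(playback_smooth_cutoff=None)
    p = _params(delta_t=0.08)
    head = simulate_head(stim_1deg, quiet_playback, p, config=cfg)
    vec = estimate_frf(stim_1deg, np.rad2deg(head))
    with_delay = band_average(
        linear_oracle(stim_1deg.excited_freqs, p, anthro),
        stim_1deg.excited_freqs,
        band_map=vec.band_map,
    )
    no_delay = band_average(
        linear_oracle(stim_1deg.excited_freqs, _params(delta_t=0.0), anthro),
        stim_1deg.excited_freqs,
        band_map=vec.band_map,
    )
    err_with = np.abs(vec.values - with_delay.values) / np.abs(with_delay.values)
    err_without = np.abs(vec.values - no_delay.values) / np.abs(no_delay.values)
    assert err_with.max() < 0.01
    assert err_without.max() > 0.05


def test_all_group_rows_are_stable(stim_1deg, quiet_playback):
    from neckdec import GROUP_PARAMS

    for params in GROUP_PARAMS.values():
        head = simulate_head(stim_1deg, quiet_playback, params)
        assert np.all(np.isfinite(head))
        assert np.max(np.abs(head)) < 0.5  # rad; sane sway for a 1 deg stimulus


def test_head_to_trunk_control_tracks_trunk(stim_1deg, quiet_playback):
    p = _params(k_p=50.0, k_d=10.0)
    head = simulate_head(stim_1deg, quiet_playback, p, controlled_variable="head_to_trunk")
    n = stim_1deg.samples_per_period
    err_ht = head[n:] - quiet_playback.alpha_ts[n:]
    err_hs = head[n:]
    assert np.abs(err_ht).mean() < np.abs(err_hs).mean()


def test_length_mismatch_raises(stim_1deg):
    bad = KinematicPlayback(np.zeros(10), np.zeros(10), stim_1deg.sample_rate)
    with pytest.raises(InvalidArgumentError):
        simulate_head(stim_1deg, bad, _params())


def test_unknown_controlled_variable_raises(stim_1deg, quiet_playback):
    with pytest.raises(InvalidArgumentError):
        simulate_head(stim_1deg, quiet_playback, _params(), controlled_variable="head_on_feet")
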