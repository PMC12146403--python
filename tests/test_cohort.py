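import numpy as np
import pytest

from neckdec import (
    CohortConfig,
    GROUP_PARAMS,
    PlaybackParams,
    SimulationConfig,
    generate_cohort,
    generate_playback,
    generate_prts,
    generate_subject,
    markers_to_inclination,
    sample_frf_group,
    simulate_head,
)
from neckdec.frf import FRFVector
from neckdec.errors import InvalidArgumentError

PERIOD = 60.5


def test_playback_null_gains(stim_1deg):
    pb = generate_playback(stim_1deg, PlaybackParams(gain_leg=0.0, gain_trunk=0.0, noise_rms=0.0))
    assert np.allclose(pb.alpha_ls, 0.0)
    assert np.allclose(pb.alpha_ts, 0.0)


def test_playback_attenuates_and_scales(stim_1deg):
    pb = generate_playback(stim_1deg, PlaybackParams(noise_rms=0.0))
    tilt = np.deg2rad(stim_1deg.position_trace)
    # low-pass with gain < 1: sway range below the scaled tilt range
    assert pb.alpha_ls.std() < 0.8 * tilt.std() * 1.001
    assert pb.alpha_ts.std() < 0.6 * tilt.std() * 1.001
    # leg/trunk share the filtered base: exactly proportional without noise
    assert np.allclose(pb.alpha_ls * 0.6, pb.alpha_ts * 0.8, atol=1e-15)


def test_playback_deterministic(stim_1deg):
    p1 = generate_playback(stim_1deg, PlaybackParams(), seed=3)
    p2 = generate_playback(stim_1deg, PlaybackParams(), seed=3)
    p3 = generate_playback(stim_1deg, PlaybackParams(), seed=4)
    assert np.array_equal(p1.alpha_ls, p2.alpha_ls)
    assert not np.array_equal(p1.alpha_ls, p3.alpha_ls)


def test_playback_periodic_for_whole_period_traces(stim_1deg):
    pb = generate_playback(stim_1deg, PlaybackParams(noise_rms=0.0))
    n = stim_1deg.samples_per_period
    assert np.allclose(pb.alpha_ts[:n], pb.alpha_ts[n : 2 * n], atol=1e-12)


def _cfg(**kw):
    base = dict(
        group="CO",
        vision="EC",
        n_subjects=2,
        param_cv=0.0,
        playback=PlaybackParams(noise_rms=0.0),
        sensor_noise_rms=0.0,
        seed=7,
    )
    base.update(kw)
    return CohortConfig(**base)


def test_subject_record_shape():
    cfg = _cfg()
    rec = generate_subject(cfg.group_params, 0.0, cfg, amplitude_pp=1.0, seed=5, subject_id="CO000")
    n = int(round(PERIOD * cfg.sample_rate))
    assert rec.stimulus.n_samples == n
    assert rec.playback.n_samples == n
    assert len(rec.head_trace) == n
    assert rec.condition == {
        "group": "CO",
        "vision": "EC",
        "amplitude_pp": 1.0,
        "subject_id": "CO000",
    }


def test_noise_free_subject_matches_direct_simulation():
    cfg = _cfg()
    rec = generate_subject(cfg.group_params, 0.0, cfg, amplitude_pp=1.0, seed=5)
    # rebuild the full two-period run and compare the recorded period
    stim = generate_prts(1.0, duration=2 * PERIOD, sample_rate=cfg.sample_rate, seed=cfg.seed)
    rng = np.random.default_rng(5)
    playback = generate_playback(stim, cfg.playback, seed=int(rng.integers(0, 2**31 - 1)))
    head = simulate_head(stim, playback, cfg.group_params)
    n = stim.samples_per_period
    assert np.allclose(rec.head_trace, np.rad2deg(head[n : 2 * n]), atol=1e-12)


def test_subject_determinism_and_scatter():
    cfg = _cfg(param_cv=0.2)
    r1 = generate_subject(cfg.group_params, cfg.param_cv, cfg, amplitude_pp=1.0, seed=5)
    r2 = generate_subject(cfg.group_params, cfg.param_cv, cfg, amplitude_pp=1.0, seed=5)
    r3 = generate_subject(cfg.group_params, cfg.param_cv, cfg, amplitude_pp=1.0, seed=6)
    assert np.array_equal(r1.head_trace, r2.head_trace)
    assert not np.array_equal(r1.head_trace, r3.head_trace)


def test_cohort_size_and_reproducibility():
    cfg = _cfg(n_subjects=2)
    records = generate_cohort(cfg)
    assert len(records) == 2 * 2  # subjects x amplitudes
    amps = sorted({r.amplitude_pp for r in records})
    assert amps == [0.5, 1.0]
    again = generate_cohort(cfg)
    for a, b in zip(records, again):
        assert np.array_equal(a.head_trace, b.head_trace)


def test_trial_frf_is_well_formed():
    cfg = _cfg()
    rec = generate_subject(cfg.group_params, 0.0, cfg, amplitude_pp=1.0, seed=5)
    vec = rec.frf()
    assert vec.values.shape == (11,)
    assert np.all(np.isfinite(vec.values))
    assert vec.condition["amplitude_pp"] == 1.0


def test_markers_to_inclination_examples():
    assert markers_to_inclination((0, 0, 1.0), (0, 0, 0)) == pytest.approx(0.0)
    assert markers_to_inclination((0, 1.0, 1.0), (0, 0, 0)) == pytest.approx(45.0)
    # small anterior lean: atan(0.002 / 1) = 0.1146 deg
    assert markers_to_inclination((0, 0.002, 1.0), (0, 0, 0)) == pytest.approx(0.11459, abs=1e-4)
    # posterior lean is negative
    assert markers_to_inclination((0, -1.0, 1.0), (0, 0, 0)) == pytest.approx(-45.0)
    with pytest.raises(InvalidArgumentError):
        markers_to_inclination((1.0, 0, 0), (0, 0, 0))


def test_sample_frf_group_statistics():
    base = FRFVector(values=np.ones(11, dtype=complex))
    g = sample_frf_group(base, n=400, rel_noise=0.2, seed=3)
    mat = g.as_matrix()
    assert mat.shape == (400, 11)
    assert np.allclose(mat.mean(axis=0), 1.0, atol=0.05)
    spread = np.abs(mat - 1.0).std()
    g_low = sample_frf_group(base, n=400, rel_noise=0.05, seed=3)
    spread_low = np.abs(g_low.as_matrix() - 1.0).std()
    assert spread_low < spread


def test_invalid_cohort_config():
    with pytest.raises(InvalidArgumentError):
        CohortConfig(group="XX")
    with pytest.raises(InvalidArgumentError):
        CohortConfig(vision="blindfolded")
    with pytest.raises(InvalidArgumentError):
        CohortConfig(n_subjects=0)
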