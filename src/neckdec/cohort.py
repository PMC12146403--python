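"""Synthetic cohort generation.

Builds complete trial records with the structure of the platform-tilt study:
a PRTS stimulus, trunk/leg "playback" kinematics correlated with the tilt,
head sway produced by the closed-loop neck model, inter-subject parameter
scatter, and band-limited sensor noise.  The playback emulates what motion
capture would record from the body riding the platform — a low-pass-filtered,
attenuated copy of the tilt — and is an explicit modelling convention, not a
prediction: whole-body sway is an input to the neck model.

Each simulated trial prepends one unrecorded warm-up stimulus period so the
recorded epoch (one period, 60.5 s at 100 Hz by default) is free of the
startup transient, as a recording from a platform already in motion would be.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import InvalidArgumentError
from .frf import FRFGroup, FRFVector, estimate_frf
from .model import KinematicPlayback, SimulationConfig, simulate_head
from .params import GROUP_PARAMS, Anthropometrics, ControllerParams
from .prts import PRTSStimulus, SequenceConfig, generate_prts

__all__ = [
    "PlaybackParams",
    "CohortConfig",
    "TrialRecord",
    "generate_playback",
    "generate_subject",
    "generate_cohort",
    "markers_to_inclination",
    "sample_frf_group",
]


@dataclass(frozen=True)
class PlaybackParams:
    """Tilt-to-sway playback model.

    Leg and trunk sway are second-order critically damped low-passes of the
    platform tilt scaled by the respective gains, plus band-limited Gaussian
    noise.  Defaults produce sub-degree sway of the order seen in
    platform-tilt recordings.
    """

    gain_leg: float = 0.8
    gain_trunk: float = 0.6
    cutoff: float = 0.5
    noise_rms: float = 0.05
    noise_cutoff: float = 5.0

    def __post_init__(self) -> None:
        if self.gain_leg < 0 or self.gain_trunk < 0:
            raise InvalidArgumentError("playback gains must be >= 0")
        if self.cutoff <= 0 or self.noise_cutoff <= 0:
            raise InvalidArgumentError("cutoff frequencies must be > 0")
        if self.noise_rms < 0:
            raise InvalidArgumentError("noise_rms must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """One synthetic cohort: group label, vision condition, size, scatter.

    ``param_cv`` is the coefficient of variation of the lognormal
    inter-subject scatter on the controller gains (delay and threshold are
    perturbed additively and clipped at zero).  ``sensor_noise_rms`` (deg) is
    band-limited measurement noise added to every recorded trace.
    Defaults mirror the study cohort sizes (17 controls, 11 IPD, 17 PSP).
    """

    group: str = "CO"
    vision: str = "EC"
    n_subjects: int = 17
    param_cv: float = 0.2
    playback: PlaybackParams = field(default_factory=PlaybackParams)
    sensor_noise_rms: float = 0.05
    sensor_noise_cutoff: float = 5.0
    amplitudes: tuple = (0.5, 1.0)
    sample_rate: float = 100.0
    sequence: SequenceConfig = field(default_factory=SequenceConfig)
    warmup_periods: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidArgumentError("n_subjects must be >= 1")
        if self.param_cv < 0:
            raise InvalidArgumentError("param_cv must be >= 0")
        if self.group not in ("CO", "IPD", "PSP"):
            raise InvalidArgumentError("group must be CO, IPD or PSP")
        if self.vision not in ("EO", "EC"):
            raise InvalidArgumentError("vision must be EO or EC")

    @property
    def group_params(self) -> ControllerParams:
        return GROUP_PARAMS[(self.group, self.vision)]


@dataclass
class TrialRecord:
    """One recorded subject-condition: stimulus, playback and head sway.

    Traces are degrees at this boundary (the CSV schema); the playback inside
    is radians, matching the simulation interface.
    """

    stimulus: PRTSStimulus
    playback: KinematicPlayback
    head_trace: np.ndarray
    subject_id: str = ""
    group: str = ""
    vision: str = ""
    amplitude_pp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.head_trace = np.asarray(self.head_trace, dtype=float)
        if len(self.head_trace) != self.stimulus.n_samples:
            raise InvalidArgumentError("head trace must match the stimulus length")

    @property
    def condition(self) -> dict:
        return {
            "group": self.group,
            "vision": self.vision,
            "amplitude_pp": self.amplitude_pp,
            "subject_id": self.subject_id,
        }

    def frf(self, band_map: dict | None = None) -> FRFVector:
        return estimate_frf(self.stimulus, self.head_trace, condition=self.condition, band_map=band_map)


def _bandlimited_noise(n: int, rms: float, cutoff: float, sample_rate: float, rng) -> np.ndarray:
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    b, a = butter(4, min(cutoff / (sample_rate / 2), 0.99), btype="low")
    shaped = filtfilt(b, a, white)
    return shaped * (rms / shaped.std())


def generate_playback(stim: PRTSStimulus, pp: PlaybackParams, seed: int = 0) -> KinematicPlayback:
    """Leg/trunk sway (rad) correlated with the platform tilt.

    For whole-period traces the low-pass is applied in the frequency domain
    (exact, transient-free for the periodic stimulus); otherwise a bilinear
    time-domain filter is used.
    """
    fs = stim.sample_rate
    tilt = np.deg2rad(stim.position_trace)
    n = len(tilt)
    n_per = stim.samples_per_period
    w0 = 2 * np.pi * pp.cutoff
    if n_per > 0 and n % n_per == 0:
        spec = np.fft.rfft(tilt)
        w = 2 * np.pi * np.fft.rfftfreq(n, 1.0 / fs)
        h = w0**2 / (1j * w + w0) ** 2
        base = np.fft.irfft(spec * h, n=n)
    else:
        from scipy.signal import bilinear, lfilter

        b, a = bilinear([w0**2], [1.0, 2 * w0, w0**2], fs)
        base = lfilter(b, a, tilt)
    rng = np.random.default_rng(seed)
    noise_rms_rad = np.deg2rad(pp.noise_rms)
    leg = pp.gain_leg * base + _bandlimited_noise(n, noise_rms_rad, pp.noise_cutoff, fs, rng)
    trunk = pp.gain_trunk * base + _bandlimited_noise(n, noise_rms_rad, pp.noise_cutoff, fs, rng)
    return KinematicPlayback(alpha_ls=leg, alpha_ts=trunk, sample_rate=fs)


def _perturb_params(base: ControllerParams, cv: float, rng) -> ControllerParams:
    """Lognormal multiplicative scatter on gains (unit mean, given CV);
    additive Gaussian scatter on delay and threshold, clipped at zero."""
    if cv == 0:
        return base
    sigma = np.sqrt(np.log1p(cv**2))
    mu = -(sigma**2) / 2

    def logn() -> float:
        return float(np.exp(mu + sigma * rng.standard_normal()))

    return ControllerParams(
        k_p=base.k_p * logn(),
        k_d=base.k_d * logn(),
        k_pp=base.k_pp * logn(),
        k_pd=base.k_pd * logn(),
        k_g=float(np.clip(base.k_g * logn(), 0.0, 2.0)),
        theta_fs=float(max(0.0, base.theta_fs + cv * base.theta_fs * rng.standard_normal())),
        delta_t=float(max(0.0, base.delta_t + cv * base.delta_t * rng.standard_normal())),
    )


def generate_subject(
    group_params: ControllerParams,
    cv: float,
    cfg: CohortConfig,
    amplitude_pp: float,
    seed: int,
    anthro: Anthropometrics | None = None,
    subject_id: str = "",
) -> TrialRecord:
    """Simulate one subject-condition trial.

    The stimulus and playback span ``1 + warmup_periods`` periods; the
    closed loop is integrated over the whole span and only the final period
    is recorded.  Sensor noise is added to the recorded traces only (it is
    measurement noise, not part of the dynamics).
    """
    anthro = anthro or Anthropometrics()
    rng = np.random.default_rng(seed)
    subj_params = _perturb_params(group_params, cv, rng)

    n_periods = 1 + cfg.warmup_periods
    stim = generate_prts(
        amplitude_pp,
        duration=n_periods * cfg.sequence.period,
        sample_rate=cfg.sample_rate,
        config=cfg.sequence,
        seed=cfg.seed,
    )
    playback = generate_playback(stim, cfg.playback, seed=int(rng.integers(0, 2**31 - 1)))
    head = simulate_head(stim, playback, subj_params, anthro)

    n_per = stim.samples_per_period
    lo = cfg.warmup_periods * n_per
    rec_stim = stim.slice_period(cfg.warmup_periods)
    rec_playback = KinematicPlayback(
        alpha_ls=playback.alpha_ls[lo : lo + n_per].copy(),
        alpha_ts=playback.alpha_ts[lo : lo + n_per].copy(),
        sample_rate=cfg.sample_rate,
    )
    head_deg = np.rad2deg(head[lo : lo + n_per].copy())

    noise_rad = np.deg2rad(cfg.sensor_noise_rms)
    if cfg.sensor_noise_rms > 0:
        for trace in (rec_playback.alpha_ls, rec_playback.alpha_ts):
            trace += _bandlimited_noise(
                n_per, noise_rad, cfg.sensor_noise_cutoff, cfg.sample_rate, rng
            )
        head_deg = head_deg + _bandlimited_noise(
            n_per, cfg.sensor_noise_rms, cfg.sensor_noise_cutoff, cfg.sample_rate, rng
        )

    return TrialRecord(
        stimulus=rec_stim,
        playback=rec_playback,
        head_trace=head_deg,
        subject_id=subject_id,
        group=cfg.group,
        vision=cfg.vision,
        amplitude_pp=amplitude_pp,
        seed=seed,
    )


def generate_cohort(cfg: CohortConfig, anthro: Anthropometrics | None = None) -> list:
    """All trial records of a cohort: ``n_subjects`` x both amplitudes.

    Child seeds are spawned deterministically from the cohort seed by subject
    index and amplitude, so any record can be regenerated in isolation.
    """
    records = []
    for i in range(cfg.n_subjects):
        for j, amp in enumerate(cfg.amplitudes):
            child = np.random.default_rng([cfg.seed, i, j]).integers(0, 2**31 - 1)
            records.append(
                generate_subject(
                    cfg.group_params,
                    cfg.param_cv,
                    cfg,
                    amplitude_pp=amp,
                    seed=int(child),
                    anthro=anthro,
                    subject_id=f"{cfg.group}{i:03d}",
                )
            )
    return records


def markers_to_inclination(upper_point, lower_point) -> float:
    """Sagittal inclination (deg) of the segment between two 3D markers.

    Coordinates are (x, y, z) with x lateral, y anterior-posterior, z
    vertical; the angle is measured between the segment and the vertical
    axis after projection on the sagittal (y, z) plane.  For the head's
    three-marker triangle, pass the centroid of the top marker pair as the
    upper point.
    """
    upper = np.asarray(upper_point, dtype=float)
    lower = np.asarray(lower_point, dtype=float)
    dy = upper[1] - lower[1]
    dz = upper[2] - lower[2]
    if dy == 0 and dz == 0:
        raise InvalidArgumentError("marker points coincide in the sagittal plane")
    return float(np.degrees(np.arctan2(dy, dz)))


def sample_frf_group(
    base: FRFVector,
    n: int,
    rel_noise: float = 0.2,
    seed: int = 0,
    condition: dict | None = None,
) -> FRFGroup:
    """Draw an FRF group from a synthetic population centred on ``base``.

    Per member and band, complex Gaussian noise with standard deviation
    ``rel_noise * |H_k|`` is added — a compact stand-in for the combined
    effect of parameter scatter and measurement noise on band-averaged FRFs,
    used for statistical calibration experiments.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    rng = np.random.default_rng(seed)
    scale = rel_noise * np.abs(base.values)
    members = []
    for i in range(n):
        z = (rng.standard_normal(11) + 1j * rng.standard_normal(11)) / np.sqrt(2)
        members.append(
            FRFVector(values=base.values + scale * z, condition=dict(condition or base.condition))
        )
    return FRFGroup(members=members, condition=dict(condition or base.condition))
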