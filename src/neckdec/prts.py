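"""Pseudo-random ternary sequence (PRTS) support-surface tilt stimulus.

The platform tilt velocity alternates between three levels {-s, 0, +s}
following a maximum-length sequence generated by an n-stage feedback shift
register over GF(3).  The resulting tilt-position profile is periodic with
period ``(3**n - 1) * state_duration`` and has a line spectrum whose power is
concentrated on a subset of the harmonics of ``1/T`` (for the canonical
5-stage register, the odd harmonics), leaving exact spectral nulls in
between.  Angles are expressed in degrees at this module's boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from math import ceil
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import InsufficientDataError, InvalidArgumentError

__all__ = [
    "SequenceConfig",
    "PRTSStimulus",
    "generate_prts",
    "excited_frequencies",
    "write_stimulus",
    "read_stimulus",
]


@dataclass(frozen=True)
class SequenceConfig:
    """Shift-register recipe for the ternary sequence.

    ``n_stages`` sets the sequence period (``3**n_stages - 1`` states) and
    ``state_duration`` the dwell time per state in seconds.  The canonical
    configuration (5 stages, 0.25 s) gives a 242-state sequence and a 60.5 s
    stimulus period, approximating the 60 s stimulation epochs used in
    platform-tilt experiments.
    """

    n_stages: int = 5
    state_duration: float = 0.25

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise InvalidArgumentError("n_stages must be >= 2")
        if self.state_duration <= 0:
            raise InvalidArgumentError("state_duration must be > 0")

    @property
    def n_states(self) -> int:
        return 3**self.n_stages - 1

    @property
    def period(self) -> float:
        return self.n_states * self.state_duration


@lru_cache(maxsize=None)
def _maximal_taps(n_stages: int) -> tuple[int, ...]:
    """First feedback tap set (lexicographic) whose register over GF(3) is
    maximal length, i.e. cycles through all 3**n - 1 nonzero states.

    The recurrence is ``a[t+n] = sum_i taps[i] * a[t+i] (mod 3)``.  For the
    canonical 5-stage register this search yields taps (2, 0, 0, 0, 1).
    """
    full = 3**n_stages - 1
    for taps in product(range(3), repeat=n_stages):
        state = (1,) + (0,) * (n_stages - 1)
        start = state
        period = 0
        while True:
            new = sum(c * s for c, s in zip(taps, state)) % 3
            state = state[1:] + (new,)
            period += 1
            if state == start or period > full:
                break
        if period == full:
            return taps
    raise InvalidArgumentError(f"no maximal-length register found for n_stages={n_stages}")


def _symbol_sequence(config: SequenceConfig, seed: int) -> np.ndarray:
    """One period of register output symbols in {0, 1, 2}.

    The seed picks the initial register state, i.e. a cyclic rotation of the
    sequence; spectra and the full-period position range are rotation
    invariant.
    """
    taps = _maximal_taps(config.n_stages)
    rng = np.random.default_rng(seed)
    state = tuple(int(v) for v in rng.integers(0, 3, size=config.n_stages))
    if all(v == 0 for v in state):
        state = (1,) + (0,) * (config.n_stages - 1)
    out = np.empty(config.n_states, dtype=np.int64)
    for i in range(config.n_states):
        out[i] = state[0]
        new = sum(c * s for c, s in zip(taps, state)) % 3
        state = state[1:] + (new,)
    return out


@dataclass
class PRTSStimulus:
    """A realized PRTS platform-tilt stimulus.

    Attributes
    ----------
    velocity_trace : ndarray
        Platform angular velocity (deg/s), ternary in {-s, 0, +s}.
    position_trace : ndarray
        Platform tilt (deg), the mean-removed integral of the velocity.
    sample_rate : float
        Hz.
    state_duration : float
        Dwell time per sequence state (s).
    speed_level : float
        The magnitude s of the nonzero velocity levels (deg/s).
    period : float
        Sequence period T (s).
    amplitude_pp : float
        Peak-to-peak range of the position trace (deg).
    excited_freqs : list of float
        Harmonics of 1/T carrying stimulus power (Hz), ascending, DC excluded.
    seed : int
        Seed that selected the sequence rotation.
    """

    velocity_trace: np.ndarray
    position_trace: np.ndarray
    sample_rate: float
    state_duration: float
    speed_level: float
    period: float
    amplitude_pp: float
    excited_freqs: list = field(default_factory=list)
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.position_trace)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def samples_per_period(self) -> int:
        return int(round(self.period * self.sample_rate))

    def slice_period(self, index: int) -> "PRTSStimulus":
        """Return a new stimulus containing the ``index``-th full period."""
        n = self.samples_per_period
        lo, hi = index * n, (index + 1) * n
        if hi > self.n_samples:
            raise InsufficientDataError(
                f"trace has {self.n_samples} samples; period {index} needs {hi}"
            )
        return PRTSStimulus(
            velocity_trace=self.velocity_trace[lo:hi].copy(),
            position_trace=self.position_trace[lo:hi].copy(),
            sample_rate=self.sample_rate,
            state_duration=self.state_duration,
            speed_level=self.speed_level,
            period=self.period,
            amplitude_pp=self.amplitude_pp,
            excited_freqs=list(self.excited_freqs),
            seed=self.seed,
        )


def _velocity_samples(config: SequenceConfig, seed: int, n_samples: int, sample_rate: float) -> np.ndarray:
    """Unit-speed ternary velocity (levels {-1, 0, +1}) at sample resolution."""
    symbols = _symbol_sequence(config, seed)
    levels = np.array([0.0, 1.0, -1.0])
    t = np.arange(n_samples) / sample_rate
    state_idx = np.floor(t / config.state_duration).astype(np.int64) % config.n_states
    return levels[symbols[state_idx]]


def _integrate_position(velocity: np.ndarray, sample_rate: float) -> np.ndarray:
    pos = cumulative_trapezoid(velocity, dx=1.0 / sample_rate, initial=0.0)
    return pos - pos.mean()


def generate_prts(
    amplitude_pp: float,
    duration: float,
    sample_rate: float,
    config: SequenceConfig | None = None,
    seed: int = 0,
    power_floor: float = 1e-4,
    f_max: float = 2.5,
) -> PRTSStimulus:
    """Generate a PRTS tilt stimulus with an exact peak-to-peak position range.

    The integrated position is linear in the speed level s, so s is obtained
    by direct scaling: the unit-speed profile is integrated once and s is the
    ratio between the requested and the unit peak-to-peak range.  The result
    is deterministic for a fixed ``seed`` and ``config``.

    ``excited_freqs`` is always computed from one full sequence period (the
    register output is known exactly) regardless of ``duration``, keeping the
    bookkeeping valid for traces shorter than one period.
    """
    if amplitude_pp <= 0:
        raise InvalidArgumentError("amplitude_pp must be > 0")
    if duration <= 0:
        raise InvalidArgumentError("duration must be > 0")
    if sample_rate <= 0:
        raise InvalidArgumentError("sample_rate must be > 0")
    config = config or SequenceConfig()

    n_samples = ceil(duration * sample_rate)
    unit_v = _velocity_samples(config, seed, n_samples, sample_rate)
    unit_p = _integrate_position(unit_v, sample_rate)
    pp_unit = unit_p.max() - unit_p.min()
    if pp_unit <= 0:
        raise InvalidArgumentError(
            "degenerate stimulus: trace too short to contain any platform motion"
        )
    s = amplitude_pp / pp_unit

    # Excited-frequency bookkeeping from one exact period of the register.
    n_per = int(round(config.period * sample_rate))
    period_v = _velocity_samples(config, seed, n_per, sample_rate)
    excited = _excited_from_period(period_v, sample_rate, config.period, power_floor, f_max)

    return PRTSStimulus(
        velocity_trace=unit_v * s,
        position_trace=unit_p * s,
        sample_rate=sample_rate,
        state_duration=config.state_duration,
        speed_level=s,
        period=config.period,
        amplitude_pp=amplitude_pp,
        excited_freqs=excited,
        seed=seed,
    )


def _excited_from_period(
    velocity_period: np.ndarray,
    sample_rate: float,
    period: float,
    power_floor: float,
    f_max: float | None,
) -> list:
    spectrum = np.fft.rfft(velocity_period)
    power = np.abs(spectrum) ** 2
    freqs = np.arange(len(power)) / period
    peak = power[1:].max()
    keep = power > power_floor * peak
    keep[0] = False  # DC never excited (zero-mean velocity)
    if f_max is not None:
        keep &= freqs <= f_max
    return [float(f) for f in freqs[keep]]


def excited_frequencies(stim: PRTSStimulus, power_floor: float = 1e-4, f_max: float | None = None) -> list:
    """Harmonics of 1/T whose velocity-spectrum power exceeds ``power_floor``
    times the peak power, computed from the first full period of the trace.

    Raises :class:`InsufficientDataError` if the trace is shorter than one
    period.
    """
    n_per = stim.samples_per_period
    if stim.n_samples < n_per:
        raise InsufficientDataError(
            f"trace spans {stim.duration:.2f} s, shorter than one period ({stim.period:.2f} s)"
        )
    return _excited_from_period(
        stim.velocity_trace[:n_per], stim.sample_rate, stim.period, power_floor, f_max
    )


def write_stimulus(stim: PRTSStimulus, csv_path: str | Path) -> None:
    """Write the tilt trace as a two-column CSV plus a JSON sidecar with the
    sequence metadata (speed level, period, state duration, seed, excited
    frequencies)."""
    csv_path = Path(csv_path)
    import pandas as pd

    pd.DataFrame({"time_s": stim.time, "tilt_deg": stim.position_trace}).to_csv(
        csv_path, index=False
    )
    sidecar = {
        "speed_level_deg_s": stim.speed_level,
        "period_s": stim.period,
        "state_duration_s": stim.state_duration,
        "sample_rate_hz": stim.sample_rate,
        "amplitude_pp_deg": stim.amplitude_pp,
        "seed": stim.seed,
        "excited_freqs_hz": stim.excited_freqs,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stimulus(csv_path: str | Path) -> PRTSStimulus:
    """Read a stimulus written by :func:`write_stimulus`.

    The velocity trace is rebuilt by numerical differentiation of the tilt
    column and snapped to the ternary levels recorded in the sidecar.
    """
    csv_path = Path(csv_path)
    import pandas as pd

    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    pos = df["tilt_deg"].to_numpy()
    fs = float(meta["sample_rate_hz"])
    vel = np.gradient(pos, 1.0 / fs)
    s = float(meta["speed_level_deg_s"])
    levels = np.array([-s, 0.0, s])
    vel = levels[np.argmin(np.abs(vel[:, None] - levels[None, :]), axis=1)]
    return PRTSStimulus(
        velocity_trace=vel,
        position_trace=pos,
        sample_rate=fs,
        state_duration=float(meta["state_duration_s"]),
        speed_level=s,
        period=float(meta["period_s"]),
        amplitude_pp=float(meta["amplitude_pp_deg"]),
        excited_freqs=list(meta["excited_freqs_hz"]),
        seed=int(meta["seed"]),
    )
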