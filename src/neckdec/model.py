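"""Closed-loop simulation of head-in-space sway.

The head is a single inverted pendulum rotating about the neck joint, riding
on recorded (or synthetic) trunk and leg kinematics.  It is stabilised by a
DEC controller: an active PD acting on the sensed controlled variable plus
gravity compensation, all behind one lumped delay, and an undelayed passive
visco-elastic neck (stiffness/damping on the head-to-trunk angle).  The
support-surface tilt estimator applies a velocity dead-band, which is the
only nonlinearity in the loop and the source of amplitude-dependent gains.

Small-angle dynamics (sin a ~ a) throughout; internal units are radians and
SI.  Torques restore toward zero angle (negative feedback); the printed
positive gains then yield a stable loop.

The internal head-in-space estimate fuses proprioception with the tilt
estimate as ``a_HS_hat = a_HS - (a_FS - a_FS_hat)``: an unregistered portion
of the platform tilt shifts the controller's reference so that the head
follows the platform, reproducing the larger response gains observed with
smaller stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt

from .errors import InvalidArgumentError, SimulationDivergenceError
from .params import Anthropometrics, ControllerParams
from .prts import PRTSStimulus

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


__all__ = [
    "KinematicPlayback",
    "SimulationConfig",
    "dead_band",
    "estimate_platform_tilt",
    "gravity_torque_coefficient",
    "control_torques",
    "simulate_head",
]

CONTROLLED_VARIABLES = ("head_in_space", "head_to_trunk")


@dataclass
class KinematicPlayback:
    """Leg- and trunk-in-space sway traces (rad) driving the head model.

    These are inputs, not predictions: in experiments they come from motion
    capture, in synthetic cohorts from the playback generator.
    """

    alpha_ls: np.ndarray
    alpha_ts: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.alpha_ls = np.asarray(self.alpha_ls, dtype=float)
        self.alpha_ts = np.asarray(self.alpha_ts, dtype=float)
        if self.alpha_ls.shape != self.alpha_ts.shape:
            raise InvalidArgumentError("leg and trunk traces must have the same length")
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.alpha_ls)


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical knobs of the integrator.

    playback_smooth_cutoff : float or None
        Zero-phase low-pass corner (Hz) applied to the playback traces before
        they are differentiated for the passive-damping velocity and the
        translational-acceleration torque.  ``None`` disables smoothing
        (useful for noise-free inputs and for oracle comparisons).
    substeps : int
        Integration sub-steps per input sample (escape hatch for stiff
        parameter sets; 1 is adequate for the printed parameter ranges at
        100 Hz).
    divergence_limit : float
        |head angle| (rad) beyond which the run is declared divergent.
    """

    playback_smooth_cutoff: float | None = 5.0
    substeps: int = 1
    divergence_limit: float = 1e3

    def __post_init__(self) -> None:
        if self.substeps < 1:
            raise InvalidArgumentError("substeps must be >= 1")
        if self.playback_smooth_cutoff is not None and self.playback_smooth_cutoff <= 0:
            raise InvalidArgumentError("playback_smooth_cutoff must be > 0 or None")


def dead_band(x, theta: float):
    """Odd-symmetric, continuous dead-band: 0 inside [-theta, theta], the
    excess ``x -/+ theta`` outside.  Accepts scalars or arrays."""
    if theta < 0:
        raise InvalidArgumentError("dead-band threshold must be >= 0")
    x = np.asarray(x, dtype=float)
    out = np.where(x > theta, x - theta, np.where(x < -theta, x + theta, 0.0))
    return out if out.ndim else float(out)


def estimate_platform_tilt(alpha_fs: np.ndarray, theta_fs: float, sample_rate: float) -> np.ndarray:
    """Internal support-surface tilt estimate (rad).

    The tilt velocity is passed through the dead-band and re-integrated from
    a zero initial condition, so any velocity below threshold is never
    registered.
    """
    alpha_fs = np.asarray(alpha_fs, dtype=float)
    if alpha_fs.size == 0:
        raise InvalidArgumentError("tilt trace must be non-empty")
    if sample_rate <= 0:
        raise InvalidArgumentError("sample_rate must be > 0")
    velocity = np.gradient(alpha_fs, 1.0 / sample_rate)
    registered = dead_band(velocity, theta_fs)
    return cumulative_trapezoid(registered, dx=1.0 / sample_rate, initial=0.0)


def gravity_torque_coefficient(anthro: Anthropometrics) -> float:
    """m_H * g * h_H, the destabilising gravity stiffness (N m/rad)."""
    return anthro.m_h * anthro.g * anthro.h_h


def control_torques(
    sensed_angle,
    sensed_rate,
    alpha_ht,
    alpha_ht_rate,
    params: ControllerParams,
    gravity_angle=None,
    gravity_rate=None,
):
    """Active and passive controller torques (N m) for given signals.

    ``sensed_angle``/``sensed_rate`` are the delayed controlled-variable
    estimate and its derivative; ``gravity_angle`` is the delayed
    head-in-space signal feeding the gravity compensation (defaults to the
    sensed signal, appropriate when the controlled variable is head-in-space
    with perfect tilt registration).  The passive torque acts on the current,
    undelayed head-to-trunk angle.
    """
    if gravity_angle is None:
        gravity_angle = sensed_angle
    if gravity_rate is None:
        gravity_rate = sensed_rate
    u = np.asarray(sensed_angle, dtype=float) + params.k_g * np.asarray(gravity_angle, dtype=float)
    du = np.asarray(sensed_rate, dtype=float) + params.k_g * np.asarray(gravity_rate, dtype=float)
    tau_act = -(params.k_p * u + params.k_d * du)
    tau_pass = -(
        params.k_pp * np.asarray(alpha_ht, dtype=float)
        + params.k_pd * np.asarray(alpha_ht_rate, dtype=float)
    )
    if tau_act.ndim == 0:
        return float(tau_act), float(tau_pass)
    return tau_act, tau_pass


def _central_diff(x: np.ndarray, dt: float) -> np.ndarray:
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) / (2 * dt)
    d[0] = d[1]
    d[-1] = d[-2]
    return d


def _central_diff2(x: np.ndarray, dt: float) -> np.ndarray:
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - 2 * x[1:-1] + x[:-2]) / dt**2
    d[0] = d[1]
    d[-1] = d[-2]
    return d


def _smooth(x: np.ndarray, cutoff: float | None, sample_rate: float) -> np.ndarray:
    if cutoff is None:
        return x
    b, a = butter(2, cutoff / (sample_rate / 2), btype="low")
    return filtfilt(b, a, x)


@njit(cache=False)
def _rk4_kernel(
    alpha_ts,
    dalpha_ts,
    comp,
    dcomp,
    t_acc,
    dt,
    substeps,
    j_h,
    mgh,
    k_p,
    k_d,
    k_pp,
    k_pd,
    k_g,
    delay,
    controlled,
    a0,
    da0,
    limit,
):  # pragma: no cover - numba-compiled; covered via simulate_head
    n = alpha_ts.shape[0]
    m = substeps
    h = dt / m
    nf = (n - 1) * m + 1
    ah = np.empty(nf)
    dah = np.empty(nf)
    ah[0] = a0
    dah[0] = da0

    for jf in range(nf - 1):
        tj = jf * h
        a = ah[jf]
        da = dah[jf]

        # One RK4 step; delayed head state is read from the fine-grid history
        # (linear interpolation), or extrapolated from the stage state when
        # the delay is shorter than the look-back available mid-step.
        k1a = 0.0
        k1d = 0.0
        k2a = 0.0
        k2d = 0.0
        k3a = 0.0
        k3d = 0.0
        k4a = 0.0
        k4d = 0.0
        for stage in range(4):
            if stage == 0:
                ts = tj
                a_s = a
                da_s = da
            elif stage == 1:
                ts = tj + 0.5 * h
                a_s = a + 0.5 * h * k1a
                da_s = da + 0.5 * h * k1d
            elif stage == 2:
                ts = tj + 0.5 * h
                a_s = a + 0.5 * h * k2a
                da_s = da + 0.5 * h * k2d
            else:
                ts = tj + h
                a_s = a + h * k3a
                da_s = da + h * k3d

            # delayed head state
            tq = ts - delay
            xq = tq / h
            if xq <= jf:
                if xq <= 0.0:
                    a_d = ah[0]
                    da_d = dah[0]
                else:
                    k = int(xq)
                    fr = xq - k
                    if k >= jf:
                        k = jf - 1
                        fr = 1.0
                    a_d = ah[k] * (1.0 - fr) + ah[k + 1] * fr
                    da_d = dah[k] * (1.0 - fr) + dah[k + 1] * fr
            else:
                a_d = a_s - delay * da_s
                da_d = da_s

            # inputs at stage time (linear interpolation on the sample grid)
            x = ts / dt
            i0 = int(x)
            if i0 >= n - 1:
                i0 = n - 2
            fr = x - i0
            ats = alpha_ts[i0] * (1.0 - fr) + alpha_ts[i0 + 1] * fr
            dats = dalpha_ts[i0] * (1.0 - fr) + dalpha_ts[i0 + 1] * fr
            ta = t_acc[i0] * (1.0 - fr) + t_acc[i0 + 1] * fr

            # delayed exogenous sensory signals
            xc = (ts - delay) / dt
            if xc <= 0.0:
                ic = 0
                frc = 0.0
            else:
                ic = int(xc)
                if ic >= n - 1:
                    ic = n - 2
                frc = xc - ic

            if controlled == 0:
                cv = comp[ic] * (1.0 - frc) + comp[ic + 1] * frc
                dcv = dcomp[ic] * (1.0 - frc) + dcomp[ic + 1] * frc
                u = (1.0 + k_g) * a_d + cv
                du = (1.0 + k_g) * da_d + dcv
            else:
                ats_d = alpha_ts[ic] * (1.0 - frc) + alpha_ts[ic + 1] * frc
                dats_d = dalpha_ts[ic] * (1.0 - frc) + dalpha_ts[ic + 1] * frc
                u = (1.0 + k_g) * a_d - ats_d
                du = (1.0 + k_g) * da_d - dats_d

            tau_act = -(k_p * u + k_d * du)
            tau_pass = -(k_pp * (a_s - ats) + k_pd * (da_s - dats))
            grav = mgh * a_s
            dda = (tau_act + tau_pass + grav + ta) / j_h

            if stage == 0:
                k1a = da_s
                k1d = dda
            elif stage == 1:
                k2a = da_s
                k2d = dda
            elif stage == 2:
                k3a = da_s
                k3d = dda
            else:
                k4a = da_s
                k4d = dda

        ah[jf + 1] = a + h / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        dah[jf + 1] = da + h / 6.0 * (k1d + 2.0 * k2d + 2.0 * k3d + k4d)
        if not np.isfinite(ah[jf + 1]) or abs(ah[jf + 1]) > limit:
            return ah[::m], dah[::m], jf + 1

    return ah[::m], dah[::m], -1


def simulate_head(
    stim: PRTSStimulus,
    playback: KinematicPlayback,
    params: ControllerParams,
    anthro: Anthropometrics | None = None,
    controlled_variable: str = "head_in_space",
    initial_state: tuple[float, float] = (0.0, 0.0),
    config: SimulationConfig | None = None,
) -> np.ndarray:
    """Integrate the closed neck-control loop and return head sway (rad).

    The stimulus (degrees at its boundary) and the playback (radians) must
    share sample rate and length.  The output has the same length.  Fixed-step
    4th-order Runge-Kutta at the sample rate (optionally sub-stepped); the
    delayed sensory path reads the integrator's own state history, so no
    numerical differentiation of the fed-back head angle is needed.  The
    tilt-estimator input is the exact ternary stimulus velocity.
    """
    anthro = anthro or Anthropometrics()
    config = config or SimulationConfig()
    if controlled_variable not in CONTROLLED_VARIABLES:
        raise InvalidArgumentError(
            f"controlled_variable must be one of {CONTROLLED_VARIABLES}"
        )
    if playback.n_samples != stim.n_samples:
        raise InvalidArgumentError(
            f"stimulus ({stim.n_samples}) and playback ({playback.n_samples}) lengths differ"
        )
    if abs(playback.sample_rate - stim.sample_rate) > 1e-9:
        raise InvalidArgumentError("stimulus and playback sample rates differ")

    fs = stim.sample_rate
    dt = 1.0 / fs

    # Tilt-compensation input: comp = -(a_FS - a_FS_hat) and its derivative,
    # computed exactly from the ternary velocity trace.
    v_rad = np.deg2rad(stim.velocity_trace)
    registered = dead_band(v_rad, params.theta_fs)
    dcomp = -(v_rad - registered)
    comp = cumulative_trapezoid(dcomp, dx=dt, initial=0.0)

    alpha_ts = _smooth(playback.alpha_ts, config.playback_smooth_cutoff, fs)
    alpha_ls = _smooth(playback.alpha_ls, config.playback_smooth_cutoff, fs)
    dalpha_ts = _central_diff(alpha_ts, dt)
    acc_ls = _central_diff2(alpha_ls, dt)
    acc_ts = _central_diff2(alpha_ts, dt)
    t_acc = (acc_ls * anthro.l_l + acc_ts * anthro.l_t) * anthro.h_h * anthro.m_h

    mgh = gravity_torque_coefficient(anthro)
    controlled = 0 if controlled_variable == "head_in_space" else 1

    ah, dah, bad = _rk4_kernel(
        alpha_ts,
        dalpha_ts,
        comp,
        dcomp,
        t_acc,
        dt,
        config.substeps,
        anthro.j_h,
        mgh,
        params.k_p,
        params.k_d,
        params.k_pp,
        params.k_pd,
        params.k_g,
        params.delta_t,
        controlled,
        float(initial_state[0]),
        float(initial_state[1]),
        config.divergence_limit,
    )
    if bad != -1:
        raise SimulationDivergenceError(time=bad * dt / config.substeps)
    return ah
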