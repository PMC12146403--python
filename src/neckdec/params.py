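"""Anthropometrics and neck-controller parameter sets.

The controller implements the disturbance-estimation-and-compensation (DEC)
scheme: a PD servo on the sensed controlled variable, augmented by
feed-forward compensation of gravity (gain ``k_g``) and of support-surface
tilt (a velocity dead-band with threshold ``theta_fs`` feeding an internal
tilt estimator), with one lumped delay ``delta_t`` on the active sensory
path.  Gains are torques per radian; the threshold is in rad/s.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .errors import InvalidArgumentError

__all__ = ["Anthropometrics", "ControllerParams", "GROUP_PARAMS", "PARAM_NAMES"]


@dataclass(frozen=True)
class Anthropometrics:
    """Standard rigid-body parameters of the single-inverted-pendulum head.

    Defaults are a standard adult parameter set used unchanged for every
    simulated subject: head inertia about the neck joint ``j_h`` (kg m^2),
    head mass ``m_h`` (kg), head centre-of-mass height above the neck joint
    ``h_h`` (m), leg (ankle-to-hip) and trunk (hip-to-neck) segment lengths
    ``l_l`` and ``l_t`` (m), and the gravity constant ``g`` (m/s^2).
    """

    j_h: float = 0.4797
    m_h: float = 4.5
    h_h: float = 0.2053
    l_l: float = 0.8543
    l_t: float = 0.5011
    g: float = 9.81

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise InvalidArgumentError(f"anthropometric field {name} must be > 0, got {value}")


@dataclass(frozen=True)
class ControllerParams:
    """The seven identified neck-control parameters.

    ``k_p``/``k_d``: active PD gains (N m/rad, N m s/rad); ``k_pp``/``k_pd``:
    passive neck stiffness and damping; ``k_g``: unitless gravity
    compensation gain in [0, 2]; ``theta_fs``: dead-band threshold on the
    support-surface tilt velocity (rad/s); ``delta_t``: lumped loop delay (s).
    """

    k_p: float
    k_d: float
    k_pp: float
    k_pd: float
    k_g: float
    theta_fs: float
    delta_t: float

    def __post_init__(self) -> None:
        for name in ("k_p", "k_d", "k_pp", "k_pd", "theta_fs", "delta_t"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if not 0.0 <= self.k_g <= 2.0:
            raise InvalidArgumentError("k_g must lie in [0, 2]")

    def as_dict(self) -> dict:
        return asdict(self)

    def as_array(self):
        import numpy as np

        return np.array(
            [self.k_p, self.k_d, self.k_pp, self.k_pd, self.k_g, self.theta_fs, self.delta_t]
        )

    @classmethod
    def from_array(cls, a) -> "ControllerParams":
        return cls(
            k_p=float(a[0]),
            k_d=float(a[1]),
            k_pp=float(a[2]),
            k_pd=float(a[3]),
            k_g=float(a[4]),
            theta_fs=float(a[5]),
            delta_t=float(a[6]),
        )


PARAM_NAMES = ("k_p", "k_d", "k_pp", "k_pd", "k_g", "theta_fs", "delta_t")

# Group-level parameter sets identified from the control (CO), idiopathic
# Parkinson's disease (IPD) and progressive supranuclear palsy (PSP) cohorts
# under eyes-closed (EC) / eyes-open (EO) conditions.  Used as simulation
# ground truths for synthetic cohorts and recovery experiments.
GROUP_PARAMS: dict[tuple[str, str], ControllerParams] = {
    ("CO", "EC"): ControllerParams(
        k_p=0.004094, k_d=2.8939, k_pp=37.591, k_pd=8.4535,
        k_g=0.10619, theta_fs=0.02226, delta_t=0.039358,
    ),
    ("CO", "EO"): ControllerParams(
        k_p=0.53982, k_d=0.96498, k_pp=43.029, k_pd=7.5394,
        k_g=0.095583, theta_fs=0.12776, delta_t=0.02217,
    ),
    ("IPD", "EC"): ControllerParams(
        k_p=5.7809, k_d=11.365, k_pp=38.852, k_pd=4.1253,
        k_g=0.018112, theta_fs=0.007753, delta_t=0.000673,
    ),
    ("IPD", "EO"): ControllerParams(
        k_p=6.5599, k_d=5.3434, k_pp=15.499, k_pd=1.9855,
        k_g=0.020482, theta_fs=0.004569, delta_t=0.001211,
    ),
    ("PSP", "EC"): ControllerParams(
        k_p=4.0473, k_d=10.459, k_pp=224.94, k_pd=1.511,
        k_g=0.03196, theta_fs=0.000332, delta_t=0.00288,
    ),
    ("PSP", "EO"): ControllerParams(
        k_p=9.0265, k_d=0.41382, k_pp=32.136, k_pd=4.6341,
        k_g=0.01004, theta_fs=0.00016, delta_t=0.11315,
    ),
}
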