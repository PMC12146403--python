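"""Identification of the seven controller parameters from FRF pairs.

The objective is the mean complex-modulus distance between simulated and
target band-averaged FRFs, averaged over the two stimulus amplitudes (both
amplitude conditions are simulated with the same candidate parameters per
evaluation, since one parameter set must reproduce both).  Minimisation is a
derivative-free simplex search in a transformed space: gains are searched in
log10 (positivity, wide printed ranges), while the bounded parameters (k_g,
delay, threshold) use a logit map onto their intervals.  Multiple restarts
from multiplicatively perturbed initial points guard against local minima;
the best score wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .errors import FitFailureError, InvalidArgumentError
from .frf import FRFVector, estimate_frf
from .model import KinematicPlayback, SimulationConfig, simulate_head
from .params import PARAM_NAMES, Anthropometrics, ControllerParams
from .prts import PRTSStimulus

__all__ = ["FitConfig", "FitResult", "frf_distance", "fit_parameters"]

# Parameter vector order matches ControllerParams.as_array():
# (k_p, k_d, k_pp, k_pd, k_g, theta_fs, delta_t)
_LOG_IDX = (0, 1, 2, 3)
_DEFAULT_BOUNDS = {
    0: (1e-4, 1e3),
    1: (1e-4, 1e3),
    2: (1e-2, 1e3),
    3: (1e-4, 1e3),
    4: (0.0, 2.0),    # k_g
    5: (0.0, 0.5),    # theta_fs (rad/s)
    6: (0.0, 0.3),    # delta_t (s)
}
_BOUNDED_IDX = (4, 5, 6)


@dataclass(frozen=True)
class FitConfig:
    """Search settings for :func:`fit_parameters`."""

    initial_params: ControllerParams
    max_evals: int = 2000
    xtol: float = 1e-4
    ftol: float = 1e-6
    n_restarts: int = 5
    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_evals <= 0:
            raise InvalidArgumentError("max_evals must be > 0")
        if self.n_restarts < 1:
            raise InvalidArgumentError("n_restarts must be >= 1")
        p = self.initial_params.as_array()
        for i, (lo, hi) in self.bounds.items():
            if not lo <= p[i] <= hi:
                raise InvalidArgumentError(
                    f"initial value of {PARAM_NAMES[i]} ({p[i]}) outside bounds [{lo}, {hi}]"
                )


@dataclass
class FitResult:
    """Best parameter set found, its score, and search diagnostics."""

    params: ControllerParams
    score: float
    n_evals: int
    converged: bool
    trace: np.ndarray

    def to_json(self, condition: dict | None = None, path: str | Path | None = None) -> dict:
        doc = dict(self.params.as_dict())
        doc.update(
            score=self.score,
            n_evals=self.n_evals,
            converged=self.converged,
        )
        if condition:
            doc["condition"] = condition
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=2))
        return doc


def frf_distance(sim_pair, target_pair) -> float:
    """Mean over the two amplitude conditions of the mean over the 11 bands
    of the complex modulus |H_sim - H_target|; symmetric, zero iff equal."""
    if len(sim_pair) != len(target_pair):
        raise InvalidArgumentError("FRF pairs must have matching lengths")
    total = 0.0
    for sim, target in zip(sim_pair, target_pair):
        if tuple(sim.center_freqs) != tuple(target.center_freqs):
            raise InvalidArgumentError("FRF vectors are defined on different band centres")
        amp_s = sim.condition.get("amplitude_pp")
        amp_t = target.condition.get("amplitude_pp")
        if amp_s is not None and amp_t is not None and amp_s != amp_t:
            raise InvalidArgumentError(
                f"amplitude conditions differ: {amp_s} vs {amp_t}"
            )
        total += float(np.abs(sim.values - target.values).mean())
    return total / len(sim_pair)


def _to_internal(p: np.ndarray, bounds: dict) -> np.ndarray:
    x = np.empty(7)
    for i in _LOG_IDX:
        lo, _ = bounds[i]
        x[i] = np.log10(max(p[i], lo))
    for i in _BOUNDED_IDX:
        lo, hi = bounds[i]
        u = np.clip((p[i] - lo) / (hi - lo), 1e-9, 1 - 1e-9)
        x[i] = np.log(u / (1 - u))
    return x


def _from_internal(x: np.ndarray, bounds: dict) -> np.ndarray:
    p = np.empty(7)
    for i in _LOG_IDX:
        lo, hi = bounds[i]
        p[i] = np.clip(10.0 ** x[i], lo, hi)
    for i in _BOUNDED_IDX:
        lo, hi = bounds[i]
        p[i] = lo + (hi - lo) / (1.0 + np.exp(-x[i]))
    return p


def simulate_frf_pair(
    params: ControllerParams,
    stimuli: tuple,
    playbacks: tuple,
    anthro: Anthropometrics | None = None,
    band_map: dict | None = None,
    sim_config: SimulationConfig | None = None,
) -> tuple:
    """Simulate both amplitude conditions and band-average the head FRFs."""
    out = []
    for stim, playback in zip(stimuli, playbacks):
        head = simulate_head(stim, playback, params, anthro, config=sim_config)
        out.append(
            estimate_frf(
                stim,
                np.rad2deg(head),
                condition={"amplitude_pp": stim.amplitude_pp},
                band_map=band_map,
            )
        )
    return tuple(out)


def fit_parameters(
    target: tuple,
    stimuli: tuple,
    playbacks: tuple,
    anthro: Anthropometrics | None = None,
    config: FitConfig | None = None,
    sim_config: SimulationConfig | None = None,
) -> FitResult:
    """Simplex re-identification of the controller parameters.

    ``target`` is the pair of FRF vectors for the two amplitudes (in the same
    order as ``stimuli``/``playbacks``).  Deterministic for a fixed config
    seed; raises :class:`FitFailureError` if every restart produced only
    non-finite scores.
    """
    if config is None:
        raise InvalidArgumentError("a FitConfig with an initial point is required")
    if not (len(target) == len(stimuli) == len(playbacks)):
        raise InvalidArgumentError("target, stimuli and playbacks must pair up")
    anthro = anthro or Anthropometrics()
    bounds = config.bounds
    band_map = target[0].band_map or None

    rng = np.random.default_rng(config.seed)
    p_init = config.initial_params.as_array()

    best_x = None
    best_score = np.inf
    best_converged = False
    n_evals = 0
    trace: list[float] = []
    any_finite = False

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals, any_finite
        n_evals += 1
        p = _from_internal(x, bounds)
        try:
            sim_pair = simulate_frf_pair(
                ControllerParams.from_array(p),
                stimuli,
                playbacks,
                anthro,
                band_map=band_map,
                sim_config=sim_config,
            )
            score = frf_distance(sim_pair, target)
        except Exception:
            score = np.inf
        if np.isfinite(score):
            any_finite = True
        else:
            score = 1e6
        trace.append(min(score, trace[-1]) if trace else score)
        return score

    for restart in range(config.n_restarts):
        if restart == 0:
            p0 = p_init.copy()
        else:
            p0 = p_init * rng.uniform(0.5, 2.0, size=7)
        for i, (lo, hi) in bounds.items():
            p0[i] = float(np.clip(p0[i], lo, hi))
        res = minimize(
            objective,
            _to_internal(p0, bounds),
            method="Nelder-Mead",
            options=dict(
                maxfev=config.max_evals,
                xatol=config.xtol,
                fatol=config.ftol,
                adaptive=True,
            ),
        )
        if res.fun < best_score:
            best_score = float(res.fun)
            best_x = res.x
            best_converged = bool(res.success)

    if not any_finite or best_x is None:
        raise FitFailureError(
            f"all {config.n_restarts} restarts diverged (no finite score in {n_evals} evaluations)"
        )

    return FitResult(
        params=ControllerParams.from_array(_from_internal(best_x, bounds)),
        score=best_score,
        n_evals=n_evals,
        converged=best_converged,
        trace=np.asarray(trace),
    )
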