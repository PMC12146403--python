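"""Frequency response function (FRF) estimation and band averaging.

The empirical transfer function between platform tilt and segment sway is
computed at the stimulus' excited frequencies as the cross-power spectrum
divided by the stimulus power spectrum (no window: the stimulus is periodic
and traces are handled in whole periods).  The raw values are then averaged
in the complex domain over 11 frequency bands centred at fixed points spaced
for logarithmic display, giving comparable confidence across bands; band
membership is resolved on a log-frequency axis with a small tie zone so that
harmonics near a boundary contribute to both neighbouring bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InsufficientDataError, InvalidArgumentError
from .prts import PRTSStimulus

__all__ = [
    "CENTER_FREQS",
    "FRFVector",
    "FRFGroup",
    "raw_transfer_function",
    "default_band_map",
    "band_average",
    "group_mean_frf",
    "estimate_frf",
    "frf_to_json",
    "frf_from_json",
]

#: The 11 band-centre frequencies (Hz) on which every FRF vector is defined.
CENTER_FREQS = (0.05, 0.15, 0.3, 0.4, 0.55, 0.7, 0.9, 1.1, 1.35, 1.75, 2.2)

#: Log-distance tie zone: a harmonic whose two nearest centres are within a
#: factor 1.05 of being equidistant (on the log axis) joins both bands.
TIE_ZONE = np.log(1.05)


@dataclass
class FRFVector:
    """11 band-averaged complex FRF values (unitless, deg/deg).

    ``condition`` carries free-form metadata (group label, vision, stimulus
    amplitude); ``band_map`` records which excited frequencies entered each
    band, making the averaging auditable.
    """

    values: np.ndarray
    center_freqs: tuple = CENTER_FREQS
    condition: dict = field(default_factory=dict)
    band_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != (11,):
            raise InvalidArgumentError(f"FRF vector must have 11 values, got {self.values.shape}")
        if tuple(self.center_freqs) != CENTER_FREQS:
            raise InvalidArgumentError(f"center_freqs must equal {CENTER_FREQS}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("FRF values must be finite")

    @property
    def gain(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


@dataclass
class FRFGroup:
    """A group of per-subject FRF vectors sharing one condition."""

    members: list
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise InvalidArgumentError("FRF group must be non-empty")

    def __len__(self) -> int:
        return len(self.members)

    def as_matrix(self) -> np.ndarray:
        return np.vstack([m.values for m in self.members])


def raw_transfer_function(
    stimulus_trace: np.ndarray,
    response_trace: np.ndarray,
    sample_rate: float,
    period: float,
    excited: list,
) -> np.ndarray:
    """Complex H at each excited frequency, S_sr(f) / S_ss(f).

    Complete periods are averaged coherently (the stimulus repeats exactly),
    each period has its mean removed, and the spectra are evaluated at the
    harmonic bins ``f * period``.  Raises :class:`InsufficientDataError` for
    traces shorter than one period.
    """
    stimulus_trace = np.asarray(stimulus_trace, dtype=float)
    response_trace = np.asarray(response_trace, dtype=float)
    if stimulus_trace.shape != response_trace.shape:
        raise InvalidArgumentError("stimulus and response traces must have equal length")
    n_per = int(round(period * sample_rate))
    n_full = len(stimulus_trace) // n_per
    if n_full < 1:
        raise InsufficientDataError(
            f"trace covers {len(stimulus_trace) / sample_rate:.2f} s, "
            f"less than one stimulus period ({period:.2f} s)"
        )
    s = stimulus_trace[: n_full * n_per].reshape(n_full, n_per)
    r = response_trace[: n_full * n_per].reshape(n_full, n_per)
    # Per-period mean removal only: a linear detrend would break the
    # periodicity of whole-period segments and leak a 1/f sawtooth spectrum
    # into every harmonic, swamping the small high-band gains.
    s = s - s.mean(axis=1, keepdims=True)
    r = r - r.mean(axis=1, keepdims=True)
    spec_s = np.fft.rfft(s, axis=1)
    spec_r = np.fft.rfft(r, axis=1)
    cross = (np.conj(spec_s) * spec_r).mean(axis=0)
    power = (np.abs(spec_s) ** 2).mean(axis=0)
    bins = np.array([int(round(f * period)) for f in excited])
    if np.any(bins >= len(cross)):
        raise InvalidArgumentError("excited frequency beyond the Nyquist limit")
    with np.errstate(invalid="ignore", divide="ignore"):
        h = cross[bins] / power[bins]
    if not np.all(np.isfinite(h)):
        raise InvalidArgumentError("stimulus has no power at a requested excited frequency")
    return h


def default_band_map(excited: list, centers: tuple = CENTER_FREQS, tie_zone: float = TIE_ZONE) -> dict:
    """Assign each excited frequency to the band with the nearest centre on a
    log-frequency axis; frequencies inside the tie zone join both neighbours.

    Returns ``{band_index: [frequencies]}`` for all 11 bands.
    """
    log_c = np.log(np.asarray(centers))
    bands: dict[int, list] = {i: [] for i in range(len(centers))}
    for f in excited:
        d = np.abs(np.log(f) - log_c)
        order = np.argsort(d)
        bands[int(order[0])].append(float(f))
        if d[order[1]] - d[order[0]] < tie_zone:
            bands[int(order[1])].append(float(f))
    return bands


def band_average(
    raw: np.ndarray,
    excited: list,
    band_map: dict | None = None,
    condition: dict | None = None,
) -> FRFVector:
    """Complex-domain mean of the raw transfer values within each band."""
    raw = np.asarray(raw, dtype=complex)
    if len(raw) != len(excited):
        raise InvalidArgumentError("raw values and excited frequencies must align")
    band_map = band_map if band_map is not None else default_band_map(excited)
    lookup = {round(float(f), 12): i for i, f in enumerate(excited)}
    values = np.empty(11, dtype=complex)
    for b in range(11):
        freqs = band_map.get(b, [])
        if not freqs:
            raise ConfigurationError(
                f"band {b} (centre {CENTER_FREQS[b]} Hz) has no member frequencies"
            )
        idx = [lookup[round(float(f), 12)] for f in freqs]
        values[b] = raw[idx].mean()
    return FRFVector(values=values, condition=condition or {}, band_map=band_map)


def group_mean_frf(group: FRFGroup) -> FRFVector:
    """Element-wise complex mean across the group members."""
    mat = group.as_matrix()
    return FRFVector(values=mat.mean(axis=0), condition=dict(group.condition))


def estimate_frf(
    stim: PRTSStimulus,
    response_trace: np.ndarray,
    condition: dict | None = None,
    band_map: dict | None = None,
    discard_first_period: bool = True,
) -> FRFVector:
    """Full pipeline from traces to a band-averaged FRF vector.

    When the traces span more than one stimulus period the first period is
    dropped as a startup transient; a single-period trace is used as is.
    """
    response_trace = np.asarray(response_trace, dtype=float)
    n_per = stim.samples_per_period
    stim_trace = stim.position_trace
    if len(response_trace) != len(stim_trace):
        raise InvalidArgumentError("response length must match the stimulus trace")
    if discard_first_period and len(stim_trace) >= 2 * n_per:
        stim_trace = stim_trace[n_per:]
        response_trace = response_trace[n_per:]
    raw = raw_transfer_function(
        stim_trace, response_trace, stim.sample_rate, stim.period, stim.excited_freqs
    )
    return band_average(raw, stim.excited_freqs, band_map=band_map, condition=condition)


def frf_to_json(frf: FRFVector, path: str | Path | None = None) -> dict:
    doc = {
        "center_freqs": list(frf.center_freqs),
        "re": [float(v) for v in frf.values.real],
        "im": [float(v) for v in frf.values.imag],
        "condition": frf.condition,
        "band_map": {str(k): v for k, v in frf.band_map.items()},
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def frf_from_json(source: str | Path | dict) -> FRFVector:
    if isinstance(source, dict):
        doc = source
    else:
        doc = json.loads(Path(source).read_text())
    values = np.asarray(doc["re"], dtype=float) + 1j * np.asarray(doc["im"], dtype=float)
    band_map = {int(k): v for k, v in doc.get("band_map", {}).items()}
    return FRFVector(values=values, condition=doc.get("condition", {}), band_map=band_map)
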