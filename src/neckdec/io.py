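"""Trial CSV schema, parameter JSON documents, and run manifests.

Trial records are stored as plain five-column CSV (time_s, platform_deg,
leg_deg, trunk_deg, head_deg) with a JSON sidecar carrying the stimulus and
condition metadata — small enough as text and diffable.  Every artifact the
pipeline writes is accompanied by the seed and a hash of the configuration
that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .model import KinematicPlayback
from .params import Anthropometrics, ControllerParams
from .prts import PRTSStimulus
from .cohort import TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "write_trial_csv",
    "read_trial_csv",
    "params_to_json",
    "params_from_json",
    "anthro_to_json",
    "anthro_from_json",
    "config_hash",
    "write_manifest",
]

TRIAL_COLUMNS = ("time_s", "platform_deg", "leg_deg", "trunk_deg", "head_deg")


def write_trial_csv(record: TrialRecord, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": record.stimulus.time,
            "platform_deg": record.stimulus.position_trace,
            "leg_deg": np.rad2deg(record.playback.alpha_ls),
            "trunk_deg": np.rad2deg(record.playback.alpha_ts),
            "head_deg": record.head_trace,
        }
    )
    df.to_csv(path, index=False)
    sidecar = {
        "subject_id": record.subject_id,
        "group": record.group,
        "vision": record.vision,
        "amplitude_pp": record.amplitude_pp,
        "seed": record.seed,
        "sample_rate_hz": record.stimulus.sample_rate,
        "period_s": record.stimulus.period,
        "state_duration_s": record.stimulus.state_duration,
        "speed_level_deg_s": record.stimulus.speed_level,
        "excited_freqs_hz": record.stimulus.excited_freqs,
        "stimulus_seed": record.stimulus.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_trial_csv(path: str | Path) -> TrialRecord:
    """Parse a trial CSV (header-keyed: column order is free) and its sidecar.

    Raises :class:`FormatError` for missing or extra columns and for a
    non-monotone time column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = set(df.columns)
    expected = set(TRIAL_COLUMNS)
    if cols != expected:
        missing = sorted(expected - cols)
        extra = sorted(cols - expected)
        parts = []
        if missing:
            parts.append(f"missing columns: {missing}")
        if extra:
            parts.append(f"unexpected columns: {extra}")
        raise FormatError(f"{path.name}: " + "; ".join(parts))
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path.name}: time_s is not strictly increasing")

    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"{path.name}: sidecar {sidecar_path.name} not found")
    meta = json.loads(sidecar_path.read_text())

    fs = float(meta["sample_rate_hz"])
    pos = df["platform_deg"].to_numpy()
    s = float(meta["speed_level_deg_s"])
    vel = np.gradient(pos, 1.0 / fs)
    levels = np.array([-s, 0.0, s])
    vel = levels[np.argmin(np.abs(vel[:, None] - levels[None, :]), axis=1)]
    stim = PRTSStimulus(
        velocity_trace=vel,
        position_trace=pos,
        sample_rate=fs,
        state_duration=float(meta["state_duration_s"]),
        speed_level=s,
        period=float(meta["period_s"]),
        amplitude_pp=float(meta["amplitude_pp"]),
        excited_freqs=list(meta["excited_freqs_hz"]),
        seed=int(meta.get("stimulus_seed", 0)),
    )
    playback = KinematicPlayback(
        alpha_ls=np.deg2rad(df["leg_deg"].to_numpy()),
        alpha_ts=np.deg2rad(df["trunk_deg"].to_numpy()),
        sample_rate=fs,
    )
    return TrialRecord(
        stimulus=stim,
        playback=playback,
        head_trace=df["head_deg"].to_numpy(),
        subject_id=str(meta.get("subject_id", "")),
        group=str(meta.get("group", "")),
        vision=str(meta.get("vision", "")),
        amplitude_pp=float(meta["amplitude_pp"]),
        seed=int(meta.get("seed", 0)),
    )


def params_to_json(params: ControllerParams, path: str | Path | None = None) -> dict:
    doc = params.as_dict()
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def params_from_json(source: str | Path | dict) -> ControllerParams:
    doc = source if isinstance(source, dict) else json.loads(Path(source).read_text())
    return ControllerParams(**{k: doc[k] for k in ControllerParams.__dataclass_fields__})


def anthro_to_json(anthro: Anthropometrics, path: str | Path | None = None) -> dict:
    doc = {
        "j_h": anthro.j_h,
        "m_h": anthro.m_h,
        "h_h": anthro.h_h,
        "l_l": anthro.l_l,
        "l_t": anthro.l_t,
        "g": anthro.g,
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def anthro_from_json(source: str | Path | dict) -> Anthropometrics:
    doc = source if isinstance(source, dict) else json.loads(Path(source).read_text())
    return Anthropometrics(**doc)


def config_hash(config: dict) -> str:
    """Stable hash of a configuration document (sorted-key JSON, sha256)."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: dict, seed: int, outputs: list) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "outputs": [str(p) for p in outputs],
    }
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(doc, indent=2))
    return manifest
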