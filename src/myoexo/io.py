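"""Trial file formats and the run manifest.

A trial is one CSV (``<subject>_<condition>.csv``) with a ``time_s`` column
followed by channel columns, plus a JSON sidecar
(``<subject>_<condition>.json``) holding sampling rates, units, condition
metadata and the generating ground truth.  EMG and mechanics channels live
on different clocks; the CSV rows follow the faster clock and slower
channels are populated only at their own sample times.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import SampledSignal, StrideEvents
from .synthetic import CONDITIONS, MUSCLES, TrialRecording

KNOWN_CHANNELS = tuple(
    [f"emg_{m}" for m in MUSCLES]
    + [f"{j}_{q}" for j in ("ankle", "knee", "hip") for q in ("angle", "moment")]
    + ["exo_angle", "grf_v"]
)


def sidecar_path(csv_path: Path | str) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_trial_csv(trial: TrialRecording, path: Path | str) -> Path:
    """Write one trial as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    rates = {name: sig.rate for name, sig in trial.channels.items()}
    fast = max(rates.values())
    names = sorted(trial.channels)
    n_rows = max(
        int(round(sig.n * fast / sig.rate)) for sig in trial.channels.values()
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s"] + names)
        cols = {}
        for name in names:
            sig = trial.channels[name]
            step = int(round(fast / sig.rate))
            cols[name] = (sig, step)
        for i in range(n_rows):
            row = [repr(i / fast)]
            for name in names:
                sig, step = cols[name]
                if i % step == 0 and i // step < sig.n:
                    row.append(repr(float(sig.values[i // step])))
                else:
                    row.append("")
            w.writerow(row)
    meta = {
        "subject_id": trial.subject_id,
        "condition": trial.condition,
        "rates": rates,
        "units": {name: sig.units for name, sig in trial.channels.items()},
        "events": {
            "heel_strikes": trial.events.heel_strikes.tolist(),
            "toe_offs": trial.events.toe_offs.tolist(),
            "rate": trial.events.rate,
        },
        "ground_truth": trial.ground_truth,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_trial_csv(path: Path | str, strict: bool = True) -> TrialRecording:
    """Read a trial CSV (+ sidecar) back into a :class:`TrialRecording`.

    Errors name the offending column: a missing/non-monotone time column,
    duplicate timestamps, or (under ``strict``) an unknown channel all
    raise; with ``strict=False`` unknown channels are skipped with a
    warning.  Channel rates come from the sidecar when present, otherwise
    from the spacing of each column's populated rows.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError("missing required column 'time_s'")
    t = df["time_s"].to_numpy(float)
    if np.any(~np.isfinite(t)):
        raise ValueError("column 'time_s' contains non-finite values")
    dt = np.diff(t)
    if np.any(dt == 0):
        raise ValueError("column 'time_s' contains duplicate timestamps")
    if np.any(dt < 0):
        raise ValueError("column 'time_s' is not strictly increasing")

    meta = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())

    channels: dict[str, SampledSignal] = {}
    for name in df.columns:
        if name == "time_s":
            continue
        if name not in KNOWN_CHANNELS:
            if strict:
                raise ValueError(f"unknown channel column {name!r}")
            warnings.warn(f"skipping unknown channel column {name!r}")
            continue
        col = df[name].to_numpy(float)
        mask = np.isfinite(col)
        if not mask.any():
            raise ValueError(f"channel column {name!r} is empty")
        vals = col[mask]
        if name in meta.get("rates", {}):
            rate = float(meta["rates"][name])
        else:
            steps = np.diff(t[mask])
            if steps.size and not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError(f"channel column {name!r} is not uniformly sampled")
            rate = 1.0 / steps[0] if steps.size else 1.0
        units = meta.get("units", {}).get(name, "")
        channels[name] = SampledSignal(rate, vals, units)

    ev = meta.get("events")
    if ev:
        events = StrideEvents(
            np.asarray(ev["heel_strikes"], int),
            np.asarray(ev["toe_offs"], int),
            float(ev["rate"]),
        )
    else:
        events = StrideEvents(np.array([], int), np.array([], int),
                              max(s.rate for s in channels.values()))
    return TrialRecording(
        subject_id=meta.get("subject_id", path.stem.split("_")[0]),
        condition=meta.get("condition", path.stem.split("_")[-1]),
        channels=channels,
        events=events,
        ground_truth=meta.get("ground_truth", {}),
    )


def config_hash(config_json: dict) -> str:
    """Stable sha256 of a canonical JSON rendering of a config."""
    blob = json.dumps(config_json, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written next to every report."""

    config_hash: str
    seed: int
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    versions: dict = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @staticmethod
    def collect_versions() -> dict:
        import numpy, pandas, scipy

        from . import __version__

        return {
            "myoexo": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        }
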