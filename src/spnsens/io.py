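"""File formats: trace/centroid/photometry CSV, trains and labels tables.

All on-disk formats are plain text.  Trace CSVs hold long-format
(neuron_id, time_s, fluorescence) rows as written by the synthetic generator
or exported from an upstream source-extraction tool; trains and label sets
are JSON/CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import SessionDesign
from .photometry import PhotometrySignal
from .responsiveness import ResponseLabel
from .transients import RawTrace, TransientEvent, TransientTrain

__all__ = [
    "read_traces_csv",
    "read_centroid_csv",
    "read_photometry_csv",
    "write_trains_json",
    "read_trains_json",
    "events_to_frame",
    "labels_to_frame",
    "read_identity_map",
]


def read_traces_csv(path: str | Path, design: SessionDesign) -> list[RawTrace]:
    """Load every neuron's trace from a long-format session CSV."""
    df = pd.read_csv(path)
    out = []
    for nid, g in df.groupby("neuron_id", sort=True):
        g = g.sort_values("time_s")
        out.append(
            RawTrace(
                neuron_id=str(nid),
                session_id=design.session_id,
                sample_rate_hz=design.sample_rate_hz,
                samples=g["fluorescence"].to_numpy(),
                design=design,
            )
        )
    return out


def read_centroid_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"time_s", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"centroid file lacks columns: {sorted(missing)}")
    return df


def read_photometry_csv(path: str | Path, sample_rate_hz: float = 20.0) -> PhotometrySignal:
    df = pd.read_csv(path)
    return PhotometrySignal(
        times_s=df["time_s"].to_numpy(),
        ch470=df["ch470"].to_numpy(),
        ch405=df["ch405"].to_numpy(),
        sample_rate_hz=sample_rate_hz,
    )


def write_trains_json(trains: list[TransientTrain], path: str | Path) -> None:
    payload = [
        {
            "neuron_id": tr.neuron_id,
            "session_id": tr.session_id,
            "onsets_s": tr.onsets_s.tolist(),
        }
        for tr in trains
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_trains_json(path: str | Path) -> list[TransientTrain]:
    payload = json.loads(Path(path).read_text())
    return [
        TransientTrain(
            neuron_id=d["neuron_id"],
            session_id=d["session_id"],
            onsets_s=np.asarray(d["onsets_s"], dtype=float),
        )
        for d in payload
    ]


def events_to_frame(
    events: dict[str, list[TransientEvent]], session_id: str
) -> pd.DataFrame:
    """Events table as written to the per-session events CSV."""
    rows = []
    for nid, evs in events.items():
        for e in evs:
            rows.append(
                {
                    "neuron_id": nid,
                    "session_id": session_id,
                    "onset_s": e.onset_s,
                    "t0_s": e.params.t0,
                    "alpha_p": e.params.alpha_p,
                    "tau_g": e.params.tau_g,
                    "tau_d": e.params.tau_d,
                    "peak_amp": e.peak_amp,
                    "area": e.area,
                    "rmse": e.rmse,
                    "accepted": e.accepted,
                    "reason": e.reason,
                }
            )
    return pd.DataFrame(rows)


def labels_to_frame(labels: list[ResponseLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "neuron_id": l.neuron_id,
                "label": l.label,
                "delta_hz": l.delta_hz,
                "null_p01": l.null_p01,
                "null_p99": l.null_p99,
                "n_pre": l.n_pre,
                "n_post": l.n_post,
                "reason": l.reason,
            }
            for l in labels
        ]
    )


def read_identity_map(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
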