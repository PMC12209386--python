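"""Reading and writing the on-disk formats.

Quaternion streams travel as columnar CSV with the header
``time_s,q0,q1,q2,q3,site`` (site in {hand, forearm, upperarm}); joint
angles and displacements as CSV with a ``time_s`` column; rating reports
as JSON records; feature sequences as an ``.npz`` array container with a
JSON sidecar recording shape, column provenance and label; dataset
manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureSequence
from .kinematics import DisplacementSeries, JointAngleSet, QuaternionStream
from .simdata import Recording

__all__ = [
    "read_streams_csv",
    "write_streams_csv",
    "write_angles_csv",
    "write_displacement_csv",
    "write_rating_report",
    "save_feature_sequence",
    "load_feature_sequence",
    "write_manifest",
    "read_manifest",
]

_SITES = ("hand", "forearm", "upperarm")


def read_streams_csv(path) -> dict[str, QuaternionStream]:
    """Read one recording's sensor streams keyed by site."""
    df = pd.read_csv(path)
    required = {"time_s", "q0", "q1", "q2", "q3", "site"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stream CSV missing columns: {sorted(missing)}")
    streams = {}
    for site, grp in df.groupby("site"):
        if site not in _SITES:
            raise ValueError(f"unknown sensor site {site!r}")
        streams[site] = QuaternionStream(
            times=grp["time_s"].to_numpy(),
            quats=grp[["q0", "q1", "q2", "q3"]].to_numpy(),
            site=str(site))
    return streams


def write_streams_csv(streams: dict[str, QuaternionStream], path) -> None:
    frames = []
    for site, s in streams.items():
        frames.append(pd.DataFrame({
            "time_s": s.times, "q0": s.quats[:, 0], "q1": s.quats[:, 1],
            "q2": s.quats[:, 2], "q3": s.quats[:, 3], "site": site}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_angles_csv(angles: JointAngleSet, path) -> None:
    pd.DataFrame({"time_s": angles.times, "WFE": angles.wfe,
                  "WAA": angles.waa, "EPS": angles.eps,
                  "EFE": angles.efe}).to_csv(path, index=False)


def write_displacement_csv(disp: DisplacementSeries, path) -> None:
    pd.DataFrame({"time_s": disp.times, "dx": disp.vectors[:, 0],
                  "dy": disp.vectors[:, 1], "dz": disp.vectors[:, 2],
                  "magnitude": disp.magnitude}).to_csv(path, index=False)


def write_rating_report(records: list[dict], path) -> None:
    """records: [{recording_id, rating, subclinical}, ...]"""
    Path(path).write_text(json.dumps(records, indent=2))


def save_feature_sequence(seq: FeatureSequence, path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), values=seq.values)
    sidecar = {
        "shape": list(seq.values.shape),
        "columns": [[site, f] for site, f in seq.columns],
        "label": seq.label,
        "recording_id": seq.recording_id,
        "subject_id": seq.subject_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_feature_sequence(path) -> FeatureSequence:
    path = Path(path)
    values = np.load(path.with_suffix(".npz"))["values"]
    meta = json.loads(path.with_suffix(".json").read_text())
    if list(values.shape) != meta["shape"]:
        raise ValueError("sidecar shape disagrees with array container")
    return FeatureSequence(
        values=values,
        columns=[(site, float(f)) for site, f in meta["columns"]],
        label=meta["label"], recording_id=meta["recording_id"],
        subject_id=meta["subject_id"])


def write_manifest(recordings: list[Recording], path, seed: int | None = None,
                   preset: str | None = None) -> None:
    manifest = {
        "seed": seed, "preset": preset,
        "recordings": [
            {"recording_id": r.recording_id, "subject_id": r.subject_id,
             "label": r.label, "rating": r.rating,
             "n_samples": {site: len(s) for site, s in r.streams.items()}}
            for r in recordings
        ],
    }
    Path(path).write_text(json.dumps(manifest, indent=2))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
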