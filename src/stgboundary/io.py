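"""Readers and writers for the pipeline's on-disk formats.

Events use BIDS-style TSV (onset, duration, trial_type).  BOLD sessions are
NIfTI volumes (position x depth x 1 x time) with a JSON sidecar carrying the
TR and the strip-position grid, plus motion TSV.  ECoG recordings are a
documented array container: a directory holding ``samples.npy`` (channels x
samples, float32), ``header.json`` (sample rate, channel table) and
``events.tsv``.  Electrode tables are TSV (channel, position_mm).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import BoldSession, EcogRecording, EventSchedule, GyrusModel

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_schedule",
    "read_schedule",
    "write_ecog",
    "read_ecog",
    "write_bold",
    "read_bold",
    "write_electrode_table",
    "read_electrode_table",
]


def write_events_tsv(trials: pd.DataFrame, path: Path | str) -> Path:
    """Write a BIDS-style events table (onset, duration, trial_type[, run])."""
    path = Path(path)
    out = pd.DataFrame(
        {
            "onset": trials["onset_s"],
            "duration": trials["duration_s"] if "duration_s" in trials else 0.0,
            "trial_type": trials["condition"],
        }
    )
    if "run" in trials:
        out["run"] = trials["run"]
    out.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    ren = {"onset": "onset_s", "duration": "duration_s", "trial_type": "condition"}
    return df.rename(columns=ren)


def write_schedule(schedule: EventSchedule, path: Path | str) -> Path:
    """Events TSV plus a JSON sidecar with the acquisition grid."""
    path = Path(path)
    write_events_tsv(schedule.trials, path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "n_runs": schedule.n_runs,
                "tr_s": schedule.tr_s,
                "volumes_per_run": schedule.volumes_per_run,
            },
            indent=1,
            sort_keys=True,
        )
    )
    return path


def read_schedule(path: Path | str) -> EventSchedule:
    path = Path(path)
    trials = read_events_tsv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return EventSchedule(
        trials=trials[["run", "onset_s", "duration_s", "condition"]],
        n_runs=int(meta["n_runs"]),
        tr_s=float(meta["tr_s"]),
        volumes_per_run=int(meta["volumes_per_run"]),
    )


def write_ecog(recording: EcogRecording, directory: Path | str) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "samples.npy", recording.samples)
    header = {
        "sample_rate_hz": recording.sample_rate_hz,
        "channels": recording.channels.fillna({"position_mm": np.nan})
        .replace({np.nan: None})
        .to_dict(orient="records"),
    }
    (directory / "header.json").write_text(json.dumps(header, indent=1, sort_keys=True))
    ev = recording.events.copy()
    ev["duration_s"] = 3.0 if "duration_s" not in ev else ev["duration_s"]
    write_events_tsv(ev, directory / "events.tsv")
    return directory


def read_ecog(directory: Path | str) -> EcogRecording:
    directory = Path(directory)
    header = json.loads((directory / "header.json").read_text())
    channels = pd.DataFrame(header["channels"])
    channels["position_mm"] = channels["position_mm"].astype(float)
    samples = np.load(directory / "samples.npy")
    events = read_events_tsv(directory / "events.tsv")[["onset_s", "condition"]]
    return EcogRecording(
        sample_rate_hz=float(header["sample_rate_hz"]),
        channels=channels,
        samples=samples,
        events=events,
    )


def write_bold(session: BoldSession, directory: Path | str, stem: str = "bold") -> Path:
    """NIfTI (position x depth x 1 x time) + JSON sidecar + motion/events TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    positions = np.unique(session.voxels["position_mm"])
    n_depth = int(session.voxels["depth"].max()) + 1
    n_t = session.data.shape[1]
    vol = np.zeros((positions.size, n_depth, 1, n_t), dtype=np.float32)
    pos_idx = {p: i for i, p in enumerate(positions)}
    for v, row in session.voxels.iterrows():
        vol[pos_idx[row["position_mm"]], int(row["depth"]), 0] = session.data[v]
    spacing = float(positions[1] - positions[0]) if positions.size > 1 else 1.0
    affine = np.diag([spacing, 1.0, 1.0, 1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((spacing, 1.0, 1.0, session.tr_s))
    nib.save(img, directory / f"{stem}.nii")
    sidecar = {
        "RepetitionTime": session.tr_s,
        "position_grid_mm": [float(p) for p in positions],
        "gyrus": {
            "length_mm": session.gyrus.length_mm,
            "node_spacing_mm": session.gyrus.node_spacing_mm,
            "anatomical_landmark_mm": session.gyrus.anatomical_landmark_mm,
            "true_boundary_mm": session.gyrus.true_boundary_mm,
            "standard_offset_mm": session.gyrus.standard_offset_mm,
        },
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    session.motion.to_csv(directory / f"{stem}_motion.tsv", sep="\t", index=False)
    write_schedule(session.schedule, directory / f"{stem}_events.tsv")
    return directory / f"{stem}.nii"


def read_bold(directory: Path | str, stem: str = "bold") -> BoldSession:
    directory = Path(directory)
    img = nib.load(directory / f"{stem}.nii")
    vol = np.asarray(img.dataobj, dtype=np.float64)
    meta = json.loads((directory / f"{stem}.json").read_text())
    positions = np.array(meta["position_grid_mm"], dtype=float)
    n_pos, n_depth, _, n_t = vol.shape
    data = vol.reshape(n_pos * n_depth, n_t, order="C")
    # voxel table in (position-major, depth-minor) order matching the reshape
    voxels = pd.DataFrame(
        {
            "voxel": np.arange(n_pos * n_depth),
            "position_mm": np.repeat(positions, n_depth),
            "depth": np.tile(np.arange(n_depth), n_pos),
        }
    )
    motion = pd.read_csv(directory / f"{stem}_motion.tsv", sep="\t")
    schedule = read_schedule(directory / f"{stem}_events.tsv")
    gy = meta["gyrus"]
    gyrus = GyrusModel(
        length_mm=gy["length_mm"],
        node_spacing_mm=gy["node_spacing_mm"],
        anatomical_landmark_mm=gy["anatomical_landmark_mm"],
        true_boundary_mm=gy["true_boundary_mm"],
        standard_offset_mm=gy["standard_offset_mm"],
    )
    return BoldSession(
        gyrus=gyrus,
        schedule=schedule,
        voxels=voxels,
        data=data,
        motion=motion,
        tr_s=float(meta["RepetitionTime"]),
    )


def write_electrode_table(channels: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    channels.to_csv(path, sep="\t", index=False)
    return path


def read_electrode_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
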