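"""Reading and writing the pipeline's on-disk formats.

Per-frame face-tracking output uses the OpenFace CSV layout (``frame``,
``timestamp``, ``confidence``, ``success``, ``pose_Rx/Ry/Rz``,
``AU.._r`` intensity columns) so real tracker output and the synthetic
generator are interchangeable.  Motion-energy CSVs are one column per ROI
and one row per frame.  Every run can write a manifest (seed, config
hash, versions) for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import os
import platform
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .types import ChannelSeries, DyadRoster, SyncSummary, TimeSeriesBundle

__all__ = [
    "write_openface_csv",
    "read_openface_csv",
    "write_roster_csv",
    "read_roster_csv",
    "write_summary_csv",
    "read_summary_csv",
    "write_manifest",
]

# OpenFace pose rotation columns, mapped onto pitch/yaw/roll
_POSE_COLS = {"pitch": "pose_Rx", "yaw": "pose_Ry", "roll": "pose_Rz"}


def write_openface_csv(path: str, bundle: TimeSeriesBundle) -> None:
    """Write one participant/task bundle in the face-tracker CSV layout."""
    n = bundle.n_frames
    conf = bundle.confidence.values if bundle.confidence is not None else np.ones(n)
    data: Dict[str, np.ndarray] = {
        "frame": np.arange(1, n + 1),
        "timestamp": np.arange(n) / bundle.fps,
        "confidence": conf,
        "success": (conf > 0).astype(int),
    }
    for key, col in _POSE_COLS.items():
        if key in bundle.pose:
            data[col] = bundle.pose[key].values
    for name in sorted(bundle.au):
        data[name] = bundle.au[name].values
    pd.DataFrame(data).to_csv(path, index=False)


def read_openface_csv(
    path: str, participant_id: str = "", task: str = "", fps: float = 30.0
) -> TimeSeriesBundle:
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    bundle = TimeSeriesBundle(participant_id, task, fps)
    valid = None
    if "success" in df.columns:
        valid = df["success"].to_numpy() > 0
    if "confidence" in df.columns:
        bundle.confidence = ChannelSeries("confidence", df["confidence"].to_numpy(float), fps)
    for key, col in _POSE_COLS.items():
        if col in df.columns:
            bundle.pose[key] = ChannelSeries(key, df[col].to_numpy(float), fps, valid)
    for col in df.columns:
        if col.startswith("AU") and col.endswith("_r"):
            bundle.au[col] = ChannelSeries(col, df[col].to_numpy(float), fps, valid)
    return bundle


def write_roster_csv(path: str, roster: DyadRoster) -> None:
    roster.to_frame().to_csv(path, index=False)


def read_roster_csv(path: str) -> DyadRoster:
    return DyadRoster.from_frame(pd.read_csv(path))


def write_summary_csv(
    path: str, summaries: Dict[Tuple[str, str], Dict[str, SyncSummary]]
) -> None:
    """Long-format synchrony summary table: participant, task, channel,
    statistic, value (one row per summary statistic)."""
    rows = []
    for (pid, task), cell in sorted(summaries.items()):
        for channel, summ in sorted(cell.items()):
            for stat, value in summ.as_dict().items():
                rows.append(
                    {
                        "participant_id": pid,
                        "task": task,
                        "channel": channel,
                        "statistic": stat,
                        "value": value,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_summary_csv(path: str) -> Dict[Tuple[str, str], Dict[str, SyncSummary]]:
    df = pd.read_csv(path)
    out: Dict[Tuple[str, str], Dict[str, SyncSummary]] = {}
    for (pid, task, channel), grp in df.groupby(["participant_id", "task", "channel"]):
        vals = dict(zip(grp["statistic"], grp["value"]))
        out.setdefault((str(pid), str(task)), {})[str(channel)] = SyncSummary(**{
            k: float(v) for k, v in vals.items()
        })
    return out


def write_manifest(run_dir: str, seed: int, config: Optional[dict] = None) -> str:
    """Drop a reproducibility manifest (seed, config hash, versions)."""
    import dyadsync

    os.makedirs(run_dir, exist_ok=True)
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config or {},
        "versions": {
            "dyadsync": getattr(dyadsync, "__version__", "unknown"),
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = os.path.join(run_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
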