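"""Motion-energy analysis: per-frame grayscale pixel change within ROIs.

Movement is quantified as the mean absolute grayscale difference between
consecutive frames over the pixels of a fixed rectangular region of
interest, after suppressing sub-threshold differences (sensor noise).
Requires a static camera and stable lighting; no tracking, calibration or
lighting normalization is attempted.
"""

from __future__ import annotations

import os
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .types import ChannelSeries, ROISpec

__all__ = [
    "to_grayscale",
    "frame_difference_energy",
    "motion_energy_series",
    "read_frame_directory",
    "write_mea_csv",
    "read_mea_csv",
    "read_roi_config",
    "DEFAULT_NOISE_THRESHOLD",
]

# grayscale units; suppresses sensor noise in consecutive-frame differences
DEFAULT_NOISE_THRESHOLD = 10.0

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse a color raster to luminance (0.299 R + 0.587 G + 0.114 B).

    Grayscale input passes through unchanged (idempotent).
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if frame.ndim == 2:
        return frame.astype(float)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return frame[..., :3].astype(float) @ _LUMA
    raise ValueError(f"unsupported frame shape {frame.shape}")


def frame_difference_energy(
    prev: np.ndarray,
    curr: np.ndarray,
    roi: ROISpec,
    noise_threshold: float = DEFAULT_NOISE_THRESHOLD,
    normalize: bool = True,
) -> float:
    """Motion energy between two frames inside one ROI.

    Sum of absolute grayscale differences exceeding ``noise_threshold``
    over the ROI pixels, divided by the ROI pixel count (per-area
    normalization; pass ``normalize=False`` for the raw sum).
    """
    prev = to_grayscale(prev)
    curr = to_grayscale(curr)
    if prev.shape != curr.shape:
        raise ValueError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    roi.check_within(prev.shape)
    d = np.abs(
        curr[roi.y0 : roi.y1, roi.x0 : roi.x1] - prev[roi.y0 : roi.y1, roi.x0 : roi.x1]
    )
    total = float(d[d > noise_threshold].sum())
    return total / roi.area if normalize else total


def motion_energy_series(
    frames: Union[np.ndarray, Sequence[np.ndarray]],
    rois: Sequence[ROISpec],
    noise_threshold: float = DEFAULT_NOISE_THRESHOLD,
    fps: float = 30.0,
    normalize: bool = True,
) -> List[ChannelSeries]:
    """One motion-energy series per ROI from an ordered frame stack.

    Series length equals the number of frames; the first value is 0 by
    convention (differencing loses one frame) so the series stays aligned
    with the input.
    """
    frames = [to_grayscale(f) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    shape = frames[0].shape
    for f in frames[1:]:
        if f.shape != shape:
            raise ValueError("all frames must share a shape")
    stack = np.stack(frames)  # t x h x w
    diffs = np.abs(np.diff(stack, axis=0))  # (t-1) x h x w
    out = []
    for roi in rois:
        roi.check_within(shape)
        sub = diffs[:, roi.y0 : roi.y1, roi.x0 : roi.x1]
        masked = np.where(sub > noise_threshold, sub, 0.0)
        energy = masked.sum(axis=(1, 2))
        if normalize:
            energy = energy / roi.area
        values = np.concatenate(([0.0], energy))
        out.append(ChannelSeries(name=f"mea_{roi.label}", values=values, fps=fps))
    return out


# ---------------------------------------------------------------------------
# external interfaces


def read_frame_directory(path: str) -> List[np.ndarray]:
    """Read an ordered stack of image frames (PNG etc.) from a directory."""
    import imageio.v3 as iio

    names = sorted(
        n for n in os.listdir(path) if n.lower().endswith((".png", ".jpg", ".jpeg", ".tif", ".tiff"))
    )
    if not names:
        raise ValueError(f"no image frames found under {path}")
    return [np.asarray(iio.imread(os.path.join(path, n))) for n in names]


def write_mea_csv(path: str, series: Sequence[ChannelSeries], header: bool = False) -> None:
    """MEA-style CSV: one column per ROI, one row per frame, no header by default."""
    df = pd.DataFrame({s.name: s.values for s in series})
    df.to_csv(path, index=False, header=header)


def read_mea_csv(
    path: str, fps: float = 30.0, names: Sequence[str] = (), header: bool = False
) -> List[ChannelSeries]:
    df = pd.read_csv(path, header=0 if header else None)
    cols = list(df.columns)
    out = []
    for i, c in enumerate(cols):
        name = names[i] if i < len(names) else (str(c) if header else f"roi_{i}")
        out.append(ChannelSeries(name=name, values=df[c].to_numpy(float), fps=fps))
    return out


def read_roi_config(path: str) -> List[ROISpec]:
    """ROI config: one `label,x0,y0,x1,y1` line per region (0-based, half-open)."""
    rois = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, x0, y0, x1, y1 = [t.strip() for t in line.split(",")]
            rois.append(ROISpec(label, int(x0), int(y0), int(x1), int(y1)))
    return rois
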