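"""Per-well intensity extraction from fluorescence image stacks.

Wells are located by the device layout, not by segmentation: a layout table
gives each well's pixel center, radius, occupancy and cohort label, and the
trace is the mean over the circular ROI in every frame.  The rasterization
convention is fixed and shared with the renderer: a pixel belongs to the ROI
iff its integer-coordinate center lies strictly within the radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .quench import IntensityTrace

__all__ = [
    "WellROI",
    "disk_mask",
    "load_layout",
    "extract_traces",
    "read_stack",
    "traces_to_csv",
    "traces_from_csv",
]

LAYOUT_COLUMNS = ["well_id", "cx_px", "cy_px", "radius_px", "occupied", "cohort"]


@dataclass(frozen=True)
class WellROI:
    """Circular region of interest for one microwell."""

    well_id: str
    cx: float
    cy: float
    radius: float
    occupied: bool = False
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError(f"well {self.well_id}: radius must be >= 1 px")

    def validate_in_frame(self, frame_h: int, frame_w: int) -> None:
        if (
            self.cx - self.radius < 0
            or self.cx + self.radius > frame_w - 1
            or self.cy - self.radius < 0
            or self.cy + self.radius > frame_h - 1
        ):
            raise ValueError(
                f"well {self.well_id}: ROI (cx={self.cx}, cy={self.cy}, "
                f"r={self.radius}) extends outside {frame_w}x{frame_h} frame"
            )


def disk_mask(shape: tuple[int, int], cx: float, cy: float, radius: float) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within *radius* of (cx, cy).

    Half-open convention: strictly ``< radius``.  Shared by the renderer and
    the extractor so synthetic round trips are rasterization-exact.
    """
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 < radius**2


def load_layout(
    path: str | Path | pd.DataFrame,
    frame_shape: tuple[int, int] | None = None,
) -> list[WellROI]:
    """Read a well-layout CSV into validated ROIs.

    Requires columns well_id, cx_px, cy_px, radius_px, occupied, cohort.
    Duplicate well ids are rejected; with *frame_shape* = (height, width)
    every ROI is checked to lie fully inside the frame.
    """
    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"layout is missing columns: {missing}")
    ids = df["well_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate well_ids in layout: {dupes}")
    rois = [
        WellROI(
            well_id=str(r.well_id),
            cx=float(r.cx_px),
            cy=float(r.cy_px),
            radius=float(r.radius_px),
            occupied=bool(r.occupied),
            cohort=str(r.cohort),
        )
        for r in df.itertuples()
    ]
    if frame_shape is not None:
        for roi in rois:
            roi.validate_in_frame(*frame_shape)
    return rois


def read_stack(path: str | Path) -> np.ndarray:
    """Load a multi-page grayscale TIFF as a (frames, height, width) array."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a grayscale stack, got shape {stack.shape}")
    return stack


def extract_traces(
    stack: np.ndarray,
    rois: list[WellROI],
    frame_rate: float,
) -> list[IntensityTrace]:
    """Mean intensity inside each ROI per frame; time axis = frame/frame_rate."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError(f"stack must be (frames, h, w), got shape {stack.shape}")
    if not frame_rate > 0:
        raise ValueError("frame_rate must be positive")
    n_frames, h, w = stack.shape
    t = np.arange(n_frames) / frame_rate
    flat = stack.reshape(n_frames, -1)
    traces = []
    for roi in rois:
        roi.validate_in_frame(h, w)
        mask = disk_mask((h, w), roi.cx, roi.cy, roi.radius)
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            raise ValueError(f"well {roi.well_id}: ROI mask is empty")
        traces.append(
            IntensityTrace(roi.well_id, t, flat[:, idx].mean(axis=1, dtype=float))
        )
    return traces


def traces_to_csv(traces: list[IntensityTrace], path: str | Path) -> None:
    """Write long-format CSV (well_id, frame, time_s, intensity_au)."""
    frames = [
        pd.DataFrame(
            {
                "well_id": tr.well_id,
                "frame": np.arange(len(tr.time)),
                "time_s": tr.time,
                "intensity_au": tr.intensity,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def traces_from_csv(path: str | Path) -> list[IntensityTrace]:
    """Read the long-format trace CSV back into per-well traces."""
    df = pd.read_csv(path)
    required = {"well_id", "time_s", "intensity_au"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    out = []
    for well_id, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("time_s")
        out.append(
            IntensityTrace(
                str(well_id),
                grp["time_s"].to_numpy(),
                grp["intensity_au"].to_numpy(),
            )
        )
    return out
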