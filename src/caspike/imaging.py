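"""Minimal image front end: stacks, background subtraction, ROI extraction.

Only the steps between a registered multi-frame grayscale recording and a
per-cell intensity table are covered: subtracting a background level
(constant or per-frame percentile) and averaging pixels inside circular
ROIs centred on nuclei.  Registration, segmentation and nucleus tracking
are delegated to dedicated tools.  Stacks are exchanged as plain multi-page
grayscale TIFF, one file per channel, frame order = time order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from caspike.synthetic_data import SimulationConfig, SpikeGroundTruth, simulate_cell_pair
from caspike.trace_model import FluorescenceTrace

ROI_COLUMNS = ("cell_id", "x_px", "y_px", "radius_px", "position_um")


@dataclass(frozen=True)
class ImageStack:
    """Ordered 2-D frames of one channel with a fixed frame interval."""

    frames: np.ndarray  # (n_frames, height, width), values >= 0
    frame_interval_s: float
    channel: str

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (time, height, width) array")
        if np.any(frames < 0):
            raise ValueError("negative pixel intensity")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RoiSpec:
    """Circular region of interest around one nucleus, pixel coordinates."""

    cell_id: str
    x_px: float
    y_px: float
    radius_px: float
    position_um: float | None = None

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError(f"ROI {self.cell_id}: radius must be > 0")


def subtract_background(
    stack: ImageStack, mode: str = "constant", value: float = 0.0
) -> ImageStack:
    """Subtract a background level from every frame, clipping at zero.

    ``constant`` subtracts a fixed level; ``percentile`` subtracts each
    frame's own ``value``-th percentile, which tracks slow illumination
    changes.
    """
    if mode == "constant":
        frames = stack.frames - float(value)
    elif mode == "percentile":
        if not 0.0 <= value <= 100.0:
            raise ValueError(f"percentile must be in [0, 100], got {value}")
        levels = np.percentile(stack.frames, value, axis=(1, 2), keepdims=True)
        frames = stack.frames - levels
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    return dataclasses.replace(stack, frames=np.maximum(frames, 0.0))


def _roi_mask(height: int, width: int, roi: RoiSpec) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width]
    return (xx - roi.x_px) ** 2 + (yy - roi.y_px) ** 2 <= roi.radius_px**2


def extract_roi_traces(
    stack: ImageStack,
    rois: Sequence[RoiSpec],
    *,
    plant_id: str = "plant01",
) -> list[FluorescenceTrace]:
    """Per-frame mean intensity inside each circular ROI.

    A pixel belongs to the ROI when its centre lies within the radius of
    the ROI centre.  ROIs extending beyond the frame bounds are rejected.
    """
    n_frames, height, width = stack.frames.shape
    traces: list[FluorescenceTrace] = []
    for roi in rois:
        if (
            roi.x_px - roi.radius_px < -0.5
            or roi.y_px - roi.radius_px < -0.5
            or roi.x_px + roi.radius_px > width - 0.5
            or roi.y_px + roi.radius_px > height - 0.5
        ):
            raise ValueError(f"ROI {roi.cell_id!r} extends beyond the {height}x{width} frame")
        mask = _roi_mask(height, width, roi)
        if not mask.any():
            raise ValueError(f"ROI {roi.cell_id!r} covers no pixel")
        intensities = stack.frames[:, mask].mean(axis=1)
        traces.append(
            FluorescenceTrace(
                plant_id=plant_id,
                cell_id=roi.cell_id,
                channel=stack.channel,
                times=np.arange(n_frames, dtype=np.float64) * stack.frame_interval_s,
                intensities=intensities,
                frame_interval=stack.frame_interval_s,
                position_um=roi.position_um,
            )
        )
    return traces


def simulate_stack(
    config: SimulationConfig,
    nuclei: Sequence[RoiSpec],
    *,
    frame_shape: tuple[int, int] = (64, 64),
    background_level: float = 20.0,
    pixel_noise_sigma: float = 0.5,
    plant_id: str = "plant01",
) -> tuple[ImageStack, ImageStack, list[SpikeGroundTruth]]:
    """Render simulated nuclei as Gaussian blobs in a two-channel movie.

    Each nucleus receives one nuclear-leading spiking cell pair from the
    trace simulator; its blob's brightness follows the simulated raw trace
    of the corresponding channel, on top of a constant background plus
    Gaussian pixel noise.  Extraction with :func:`extract_roi_traces` after
    constant-background subtraction recovers traces proportional to the
    injected ones.
    """
    height, width = frame_shape
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_frames = int(np.floor(config.duration_s / config.frame_interval_s)) + 1
    yy, xx = np.mgrid[0:height, 0:width]
    channels = {
        "nuclear": np.full((n_frames, height, width), background_level, dtype=np.float64),
        "cytosolic": np.full((n_frames, height, width), background_level, dtype=np.float64),
    }
    truth: list[SpikeGroundTruth] = []
    for roi in nuclei:
        if not (0 <= roi.x_px < width and 0 <= roi.y_px < height):
            raise ValueError(f"nucleus {roi.cell_id!r} outside the frame")
        nuc, cyt, gt = simulate_cell_pair(
            config,
            plant_id=plant_id,
            cell_id=roi.cell_id,
            position_um=roi.position_um,
            rng=rng,
        )
        sigma = roi.radius_px / 2.0
        blob = np.exp(-((xx - roi.x_px) ** 2 + (yy - roi.y_px) ** 2) / (2.0 * sigma**2))
        for channel, trace in (("nuclear", nuc), ("cytosolic", cyt)):
            channels[channel] += blob[None, :, :] * trace.intensities[:, None, None]
        truth.extend(gt)
    for channel in channels:
        if pixel_noise_sigma > 0:
            channels[channel] += pixel_noise_sigma * rng.standard_normal(channels[channel].shape)
        channels[channel] = np.maximum(channels[channel], 0.0)
    nuclear = ImageStack(channels["nuclear"], config.frame_interval_s, "nuclear")
    cytosolic = ImageStack(channels["cytosolic"], config.frame_interval_s, "cytosolic")
    return nuclear, cytosolic, truth


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page float32 grayscale TIFF (time = page order)."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    return path


def read_stack(path: str | Path, frame_interval_s: float, channel: str) -> ImageStack:
    """Read a multi-page grayscale TIFF written by :func:`write_stack`."""
    frames = np.asarray(tifffile.imread(Path(path)), dtype=np.float64)
    if frames.ndim == 2:  # single-frame stack
        frames = frames[None, :, :]
    return ImageStack(frames=frames, frame_interval_s=frame_interval_s, channel=channel)


def read_rois(path: str | Path) -> list[RoiSpec]:
    """Read an ROI CSV: cell_id, x_px, y_px, radius_px, position_um."""
    frame = pd.read_csv(path)
    for column in ("cell_id", "x_px", "y_px", "radius_px"):
        if column not in frame.columns:
            raise ValueError(f"ROI CSV missing column {column!r}")
    rois = []
    for row in frame.itertuples(index=False):
        position = getattr(row, "position_um", None)
        if position is not None and pd.isna(position):
            position = None
        rois.append(
            RoiSpec(
                cell_id=str(row.cell_id),
                x_px=float(row.x_px),
                y_px=float(row.y_px),
                radius_px=float(row.radius_px),
                position_um=None if position is None else float(position),
            )
        )
    return rois
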