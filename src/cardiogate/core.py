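"""Shared containers, error types and file I/O.

Conventions used throughout the package:

* phase is in radians in [0, 2*pi), with phase 0 at the reference anchor
  (end-diastole for the default gating target);
* time is in milliseconds, absolute from the start of a recording;
* frames are 0-indexed; images are float arrays with intensities in [0, 1];
* all geometry is in micrometres (um) internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class CardiogateError(Exception):
    """Base class for all package errors."""


class ParameterError(CardiogateError, ValueError):
    """A simulation or analysis parameter violates its contract."""


class AperiodicInputError(CardiogateError):
    """No periodicity above the confidence floor (e.g. frozen/pause video)."""


class SegmentationError(CardiogateError):
    """Ventricle segmentation produced an empty mask."""


class InsufficientBeatsError(CardiogateError):
    """Fewer beats than the operation requires."""


class InsufficientHistoryError(CardiogateError):
    """Too few usable phase estimates to fit a phase model."""


class InsufficientTracksError(CardiogateError):
    """Too few qualifying cell tracks for a velocity estimate."""


class PackingError(CardiogateError):
    """Nucleus placement could not satisfy the minimum-separation constraint."""


class EmptyMaskError(CardiogateError):
    """A 3-D organ mask came out empty."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class VideoSequence:
    """An ordered stack of single-channel frames with timing and scale metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``, float intensities.
    timestamps_ms
        Strictly increasing acquisition times, one per frame.
    pixel_size_um
        Lateral pixel size in micrometres.
    fps
        Nominal acquisition frame rate (frames per second).
    """

    frames: np.ndarray
    timestamps_ms: np.ndarray
    pixel_size_um: float
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        if self.frames.ndim != 3:
            raise ParameterError("frames must be a (n, h, w) array")
        if len(self.timestamps_ms) != len(self.frames):
            raise ParameterError("timestamps length must equal frame count")
        if len(self.timestamps_ms) > 1 and not np.all(np.diff(self.timestamps_ms) > 0):
            raise ParameterError("timestamps must be strictly increasing")
        if self.pixel_size_um <= 0 or self.fps <= 0:
            raise ParameterError("pixel_size_um and fps must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_interval_ms(self) -> float:
        return 1000.0 / self.fps


@dataclass
class ZStackScene:
    """Multi-channel 3-D confocal scene.

    ``channels`` maps channel names (``gfp``, ``dapi``, optionally ``phh3``
    and ``tunel``) to arrays of identical shape ``(nz, ny, nx)``.
    """

    channels: Mapping[str, np.ndarray]
    z_step_um: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ParameterError("all channels must share one shape")
        if self.z_step_um <= 0 or self.pixel_size_um <= 0:
            raise ParameterError("z_step_um and pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_um3(self) -> float:
        return self.z_step_um * self.pixel_size_um ** 2


# ---------------------------------------------------------------------------
# TIFF / CSV round-tripping
# ---------------------------------------------------------------------------

def write_video_tiff(video: VideoSequence, path: str | Path) -> None:
    """Write a video as a multi-page TIFF (one page per frame, float32)."""
    tifffile.imwrite(
        str(path),
        video.frames.astype(np.float32),
        metadata={
            "axes": "TYX",
            "pixel_size_um": video.pixel_size_um,
            "fps": video.fps,
        },
    )


def read_video_tiff(path: str | Path, pixel_size_um: float | None = None,
                    fps: float | None = None) -> VideoSequence:
    """Read a multi-page TIFF video; metadata can be overridden from config."""
    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[None]
    px = pixel_size_um if pixel_size_um is not None else float(meta.get("pixel_size_um", 1.0))
    rate = fps if fps is not None else float(meta.get("fps", 30.0))
    t = np.arange(len(frames)) * 1000.0 / rate
    return VideoSequence(frames=frames, timestamps_ms=t, pixel_size_um=px, fps=rate)


def write_stack_tiff(scene: ZStackScene, path: str | Path) -> None:
    """Write a z-stack as a CZYX multi-page TIFF with a channel-name tag."""
    names = sorted(scene.channels)
    data = np.stack([scene.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        metadata={
            "axes": "CZYX",
            "channel_names": names,
            "z_step_um": scene.z_step_um,
            "pixel_size_um": scene.pixel_size_um,
        },
    )


def read_stack_tiff(path: str | Path, channel_map: Mapping[str, int] | None = None,
                    z_step_um: float | None = None,
                    pixel_size_um: float | None = None) -> ZStackScene:
    """Read a multi-channel TIFF stack.

    ``channel_map`` maps channel names to axis-0 indices; when omitted the
    ``channel_names`` tag written by :func:`write_stack_tiff` is used.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if channel_map is None:
        names = meta.get("channel_names")
        if names is None:
            raise ParameterError("channel_map required: stack has no channel_names tag")
        channel_map = {n: i for i, n in enumerate(names)}
    channels = {name: data[idx] for name, idx in channel_map.items()}
    return ZStackScene(
        channels=channels,
        z_step_um=z_step_um if z_step_um is not None else float(meta.get("z_step_um", 3.0)),
        pixel_size_um=(pixel_size_um if pixel_size_um is not None
                       else float(meta.get("pixel_size_um", 1.0))),
    )


def write_ground_truth_csv(path: str | Path, phase: np.ndarray, area_um2: np.ndarray) -> None:
    """Sidecar ground-truth table: frame, phase, area."""
    pd.DataFrame({
        "frame": np.arange(len(phase)),
        "phase": phase,
        "area_um2": area_um2,
    }).to_csv(path, index=False)
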