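"""Synthetic data with exact ground truth.

Three generators emulate the raw data the rest of the package analyses:

* :func:`generate_heart_video` — a periodically contracting ventricle seen in
  2-D projection, with optional injury-style pause followed by bradycardia;
* :func:`generate_vessel_video` — erythrocytes drifting along a vessel at a
  known constant velocity;
* :func:`generate_heart_stack` — a multi-channel confocal z-stack of an
  isolated ventricle with known in-mask / out-of-mask nucleus counts, a known
  mitotic subset and known apoptotic puncta.

Every generator is deterministic given its seed, and returns the exact
(pre-noise) ground truth alongside the rendered data.

The contracting ventricle is modelled as an ellipse whose *area* oscillates
sinusoidally between the diastolic and systolic areas, so the true ejection
fraction maps linearly onto the area envelope:

    A(phi) = Ad - (Ad - As) * (1 - cos phi) / 2,   As = Ad * (1 - EF/100)

with phase 0 at end-diastole (maximal area).  A pure area oscillation is
mirror-symmetric in phase (A(phi) = A(-phi)), which no image-matching method
could disambiguate; real hearts are not symmetric — the ventricle translates
and shears as it contracts.  The generator therefore adds a small phase-locked
translation of the ellipse centre (proportional to sin phi) that breaks the
symmetry without changing the projected area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import PackingError, ParameterError, VideoSequence, ZStackScene

TWO_PI = 2.0 * math.pi

#: aspect ratio (major/minor) of the rendered ventricle ellipse
_ELLIPSE_ASPECT = 1.4
#: amplitude (um) of the phase-locked centroid translation that breaks the
#: diastole/systole mirror symmetry
_SHIFT_AMPLITUDE_UM = 6.0


# ---------------------------------------------------------------------------
# Parameter records
# ---------------------------------------------------------------------------

@dataclass
class HeartSimParams:
    """Beating-ventricle simulation parameters.

    Defaults correspond to a healthy 72 hpf embryo imaged at 30 fps: a 400 ms
    cardiac period (150 bpm), 10.1e3 um^2 diastolic area and 20% area-based
    ejection fraction.
    """

    period_ms: float = 400.0
    fps: float = 30.0
    n_frames: int = 150
    diastolic_area_um2: float = 10_100.0
    ef_true_pct: float = 20.0
    pixel_size_um: float = 2.0
    noise_sigma: float = 0.0
    pause_onset_frame: int | None = None
    pause_duration_ms: float = 0.0
    post_pause_period_ms: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_ms <= 0 or self.fps <= 0:
            raise ParameterError("period_ms and fps must be positive")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be a positive integer")
        if not 0.0 <= self.ef_true_pct < 100.0:
            raise ParameterError("ef_true_pct must be in [0, 100)")
        if self.diastolic_area_um2 <= 0:
            raise ParameterError("diastolic_area_um2 must be positive")
        if self.systolic_area_um2 <= 0:
            raise ParameterError("implied systolic area must be positive")
        if self.noise_sigma < 0 or self.pause_duration_ms < 0:
            raise ParameterError("noise_sigma and pause_duration_ms must be >= 0")
        if self.pause_onset_frame is not None and not (
                0 <= self.pause_onset_frame < self.n_frames):
            raise ParameterError("pause_onset_frame must lie within the video")
        if self.post_pause_period_ms is not None and self.post_pause_period_ms <= 0:
            raise ParameterError("post_pause_period_ms must be positive")

    @property
    def systolic_area_um2(self) -> float:
        return self.diastolic_area_um2 * (1.0 - self.ef_true_pct / 100.0)


@dataclass
class VesselSimParams:
    """Caudal-vein erythrocyte simulation parameters.

    Defaults emulate the healthy-control flow regime (~300 um/s) imaged at
    30 fps with 4 tracked cells.
    """

    velocity_um_s: float = 300.0
    n_cells: int = 4
    fps: float = 30.0
    n_frames: int = 30
    pixel_size_um: float = 1.0
    cell_radius_um: float = 3.0
    # long enough that a cell at 400 um/s stays in frame for a 30-frame clip
    field_shape: tuple[int, int] = (64, 512)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.velocity_um_s < 0:
            raise ParameterError("velocity_um_s must be >= 0")
        if self.n_cells < 1 or self.n_frames < 1:
            raise ParameterError("n_cells and n_frames must be positive")
        if self.fps <= 0 or self.pixel_size_um <= 0 or self.cell_radius_um <= 0:
            raise ParameterError("fps, pixel_size_um, cell_radius_um must be positive")
        h_um = self.field_shape[0] * self.pixel_size_um
        w_um = self.field_shape[1] * self.pixel_size_um
        if self.cell_radius_um >= min(h_um, w_um) / 2:
            raise ParameterError("cell_radius_um must be smaller than the field")


@dataclass
class StackSimParams:
    """Confocal z-stack simulation parameters.

    Defaults emulate an isolated control ventricle: ~238 cardiomyocyte nuclei
    inside the GFP-positive myocardial mask, sliced at 3 um z-intervals.
    """

    shape_zyx: tuple[int, int, int] = (36, 160, 160)
    z_step_um: float = 3.0
    pixel_size_um: float = 1.0
    n_nuclei_in_mask: int = 238
    n_nuclei_out_mask: int = 40
    phh3_fraction: float = 0.0
    n_tunel_puncta: int = 0
    nucleus_radius_um: float = 2.5
    # resolvability at 3 um z-sampling needs centre separation above the
    # nucleus diameter plus one z-step; 9 um leaves a 1 um margin
    min_separation_um: float = 9.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape_zyx) < 4:
            raise ParameterError("shape_zyx dimensions must each be >= 4")
        if self.z_step_um <= 0 or self.pixel_size_um <= 0:
            raise ParameterError("z_step_um and pixel_size_um must be positive")
        if self.n_nuclei_in_mask < 0 or self.n_nuclei_out_mask < 0 or self.n_tunel_puncta < 0:
            raise ParameterError("counts must be non-negative")
        if not 0.0 <= self.phh3_fraction <= 1.0:
            raise ParameterError("phh3_fraction must lie in [0, 1]")
        if self.nucleus_radius_um <= 0 or self.min_separation_um <= 0:
            raise ParameterError("nucleus_radius_um and min_separation_um must be positive")


# ---------------------------------------------------------------------------
# Phase timeline and ground truth
# ---------------------------------------------------------------------------

@dataclass
class PhaseTimeline:
    """Piecewise-linear cardiac phase as a function of time.

    ``segments`` is a list of ``(t0_ms, t1_ms, phase0_rad, rate_rad_per_ms)``;
    the unwrapped phase on segment i is ``phase0 + rate * (t - t0)``.  A pause
    is a segment with rate 0.
    """

    segments: list[tuple[float, float, float, float]]

    def unwrapped_phase_at(self, t_ms: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        out = np.empty_like(t)
        for t0, t1, phi0, rate in self.segments:
            sel = (t >= t0) & (t < t1) if t1 < np.inf else (t >= t0)
            out[sel] = phi0 + rate * (t[sel] - t0)
        return out

    def phase_at(self, t_ms: np.ndarray | float) -> np.ndarray:
        return np.mod(self.unwrapped_phase_at(t_ms), TWO_PI)

    def crossings(self, target_phase: float, t_max_ms: float) -> np.ndarray:
        """All times in [0, t_max_ms) at which the phase passes ``target_phase``."""
        target = float(target_phase) % TWO_PI
        times: list[float] = []
        for t0, t1, phi0, rate in self.segments:
            if rate <= 0:
                continue  # frozen phase cannot cross anything
            hi = min(t1, t_max_ms)
            if hi <= t0:
                continue
            # phi0 + rate*(t-t0) = target + 2*pi*k
            k0 = math.ceil((phi0 - target) / TWO_PI - 1e-12)
            k = k0
            while True:
                t = t0 + (target + TWO_PI * k - phi0) / rate
                if t >= hi:
                    break
                if t >= t0 - 1e-9:
                    times.append(t)
                k += 1
        return np.asarray(sorted(times))


@dataclass
class GroundTruth:
    """Exact per-frame truth for a simulated heart video (pre-noise)."""

    phase_per_frame: np.ndarray
    area_per_frame_um2: np.ndarray
    hr_bpm_piecewise: list[tuple[tuple[int, int], float]]
    target_phase_times_ms: np.ndarray
    timeline: PhaseTimeline = field(repr=False, default=None)

    def target_crossings(self, target_phase: float, t_max_ms: float) -> np.ndarray:
        return self.timeline.crossings(target_phase, t_max_ms)


# ---------------------------------------------------------------------------
# Heart video
# ---------------------------------------------------------------------------

def _area_waveform(phase: np.ndarray, ad: float, as_: float) -> np.ndarray:
    return ad - (ad - as_) * (1.0 - np.cos(phase)) / 2.0


def _render_ellipse_frame(area_um2: float, phase: float, shape: tuple[int, int],
                          pixel_size_um: float) -> np.ndarray:
    """Anti-aliased filled ellipse of the given area, centred with a
    phase-locked lateral shift breaking the diastole/systole mirror symmetry."""
    h, w = shape
    b_um = math.sqrt(area_um2 / (math.pi * _ELLIPSE_ASPECT))
    a_um = _ELLIPSE_ASPECT * b_um
    cx_um = _SHIFT_AMPLITUDE_UM * math.sin(phase)
    y = (np.arange(h) - (h - 1) / 2.0) * pixel_size_um
    x = (np.arange(w) - (w - 1) / 2.0) * pixel_size_um - cx_um
    yy, xx = np.meshgrid(y, x, indexing="ij")
    d = np.sqrt((xx / a_um) ** 2 + (yy / b_um) ** 2)
    # ~1 px wide linear edge so that the half-intensity contour is the ellipse
    edge = (1.0 - d) * (b_um / pixel_size_um)
    return np.clip(edge + 0.5, 0.0, 1.0)


def _heart_frame_shape(params: HeartSimParams) -> tuple[int, int]:
    b_um = math.sqrt(params.diastolic_area_um2 / (math.pi * _ELLIPSE_ASPECT))
    a_um = _ELLIPSE_ASPECT * b_um
    half_w = (a_um + _SHIFT_AMPLITUDE_UM) / params.pixel_size_um + 6
    half_h = b_um / params.pixel_size_um + 6
    return (2 * math.ceil(half_h), 2 * math.ceil(half_w))


def _build_timeline(params: HeartSimParams, t_end_ms: float) -> PhaseTimeline:
    omega1 = TWO_PI / params.period_ms
    if params.pause_onset_frame is None or params.pause_duration_ms == 0:
        return PhaseTimeline([(0.0, np.inf, 0.0, omega1)])
    t_pause = params.pause_onset_frame * 1000.0 / params.fps
    phi_pause = omega1 * t_pause
    t_resume = t_pause + params.pause_duration_ms
    omega2 = TWO_PI / (params.post_pause_period_ms or params.period_ms)
    return PhaseTimeline([
        (0.0, t_pause, 0.0, omega1),
        (t_pause, t_resume, phi_pause, 0.0),
        (t_resume, np.inf, phi_pause, omega2),
    ])


def generate_heart_video(params: HeartSimParams) -> tuple[VideoSequence, GroundTruth]:
    """Render a beating-ventricle video and its exact ground truth.

    The returned :class:`GroundTruth` carries the exact per-frame phase and
    area (before noise), the piecewise heart rate, and the true times at which
    the heart passes end-diastole (phase 0).
    """
    dt = 1000.0 / params.fps
    t = np.arange(params.n_frames) * dt
    timeline = _build_timeline(params, t[-1] + dt)
    phase = timeline.phase_at(t)
    area = _area_waveform(phase, params.diastolic_area_um2, params.systolic_area_um2)

    shape = _heart_frame_shape(params)
    frames = np.empty((params.n_frames,) + shape)
    for i in range(params.n_frames):
        frames[i] = _render_ellipse_frame(area[i], phase[i], shape, params.pixel_size_um)

    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        frames = np.clip(frames + rng.normal(0.0, params.noise_sigma, frames.shape), 0.0, 1.0)

    hr1 = 60_000.0 / params.period_ms
    hr_piecewise: list[tuple[tuple[int, int], float]] = []
    if params.pause_onset_frame is None or params.pause_duration_ms == 0:
        hr_piecewise.append(((0, params.n_frames), hr1))
    else:
        p = params.pause_onset_frame
        resume_frame = min(params.n_frames,
                           math.ceil((p * dt + params.pause_duration_ms) / dt))
        hr2 = 60_000.0 / (params.post_pause_period_ms or params.period_ms)
        hr_piecewise.extend([((0, p), hr1), ((p, resume_frame), 0.0),
                             ((resume_frame, params.n_frames), hr2)])

    truth = GroundTruth(
        phase_per_frame=phase,
        area_per_frame_um2=area,
        hr_bpm_piecewise=hr_piecewise,
        target_phase_times_ms=timeline.crossings(0.0, t[-1] + dt),
        timeline=timeline,
    )
    video = VideoSequence(frames=frames, timestamps_ms=t,
                          pixel_size_um=params.pixel_size_um, fps=params.fps)
    return video, truth


# ---------------------------------------------------------------------------
# Vessel video
# ---------------------------------------------------------------------------

def _sample_separated_points(rng: np.random.Generator, n: int,
                             low: np.ndarray, high: np.ndarray,
                             min_sep: float, max_attempts: int) -> np.ndarray:
    """Rejection-sample n points in an axis-aligned box with pairwise
    separation >= min_sep (Euclidean, physical units)."""
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {n} points with separation {min_sep} "
                f"after {max_attempts} attempts")
        cand = rng.uniform(low, high)
        attempts += 1
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
    return np.asarray(pts)


def generate_vessel_video(params: VesselSimParams) -> tuple[VideoSequence, float]:
    """Render erythrocytes drifting along +x at constant velocity.

    Returns the video and the true mean velocity (um/s).  The per-cell,
    per-frame true positions are attached to the video as
    ``video.true_positions_px`` (shape ``(n_cells, n_frames, 2)``, (y, x)).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.field_shape
    r_px = params.cell_radius_um / params.pixel_size_um
    margin = 2.0 * r_px
    disp_px = params.velocity_um_s / params.fps / params.pixel_size_um

    # keep trajectories inside the field when possible; wrap deterministically
    # otherwise
    span = disp_px * (params.n_frames - 1)
    if w - margin - span > margin + 1.0:
        x_low, x_high = margin, w - margin - span
    else:  # trajectory cannot fit: start anywhere and wrap deterministically
        x_low, x_high = 0.0, float(w)
    starts = _sample_separated_points(
        rng, params.n_cells,
        low=np.array([margin, x_low]),
        high=np.array([h - margin, x_high]),
        min_sep=max(6.0 * r_px, 4.0),
        max_attempts=500 * params.n_cells,
    )

    positions = np.empty((params.n_cells, params.n_frames, 2))
    for c, (y0, x0) in enumerate(starts):
        xs = np.mod(x0 + disp_px * np.arange(params.n_frames), w)
        positions[c, :, 0] = y0
        positions[c, :, 1] = xs

    sigma = max(r_px / 2.0, 0.8)
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.zeros((params.n_frames, h, w))
    for i in range(params.n_frames):
        for c in range(params.n_cells):
            y0, x0 = positions[c, i]
            d2 = (yy - y0) ** 2 + (xx - x0) ** 2
            frames[i] += np.exp(-d2 / (2.0 * sigma ** 2))
    frames = np.clip(frames, 0.0, 1.0)
    if params.noise_sigma > 0:
        frames = np.clip(frames + rng.normal(0.0, params.noise_sigma, frames.shape),
                         0.0, 1.0)

    t = np.arange(params.n_frames) * 1000.0 / params.fps
    video = VideoSequence(frames=frames, timestamps_ms=t,
                          pixel_size_um=params.pixel_size_um, fps=params.fps)
    video.true_positions_px = positions
    return video, params.velocity_um_s


# ---------------------------------------------------------------------------
# Confocal z-stack
# ---------------------------------------------------------------------------

def _ellipsoid_distance(coords_um: tuple[np.ndarray, np.ndarray, np.ndarray],
                        center_um: np.ndarray, semiaxes_um: np.ndarray) -> np.ndarray:
    z, y, x = coords_um
    return np.sqrt(((z - center_um[0]) / semiaxes_um[0]) ** 2 +
                   ((y - center_um[1]) / semiaxes_um[1]) ** 2 +
                   ((x - center_um[2]) / semiaxes_um[2]) ** 2)


def _render_spheres(shape: tuple[int, int, int], centers_um: np.ndarray,
                    radius_um: float, z_step: float, px: float) -> np.ndarray:
    """Add anti-aliased solid spheres (physical radius) to a new volume."""
    vol = np.zeros(shape)
    if len(centers_um) == 0:
        return vol
    nz, ny, nx = shape
    for cz, cy, cx in centers_um:
        z0 = max(0, int((cz - radius_um) / z_step) - 1)
        z1 = min(nz, int((cz + radius_um) / z_step) + 2)
        y0 = max(0, int((cy - radius_um) / px) - 1)
        y1 = min(ny, int((cy + radius_um) / px) + 2)
        x0 = max(0, int((cx - radius_um) / px) - 1)
        x1 = min(nx, int((cx + radius_um) / px) + 2)
        zz = (np.arange(z0, z1) + 0.5) * z_step
        yy = (np.arange(y0, y1) + 0.5) * px
        xx = (np.arange(x0, x1) + 0.5) * px
        Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
        d = np.sqrt((Z - cz) ** 2 + (Y - cy) ** 2 + (X - cx) ** 2)
        blob = np.clip((radius_um - d) / px + 0.5, 0.0, 1.0)
        vol[z0:z1, y0:y1, x0:x1] = np.maximum(vol[z0:z1, y0:y1, x0:x1], blob)
    return vol


def generate_heart_stack(params: StackSimParams) -> tuple[ZStackScene, dict]:
    """Render a multi-channel ventricle z-stack with known counts.

    Channels: ``gfp`` (filled ellipsoidal ventricle), ``dapi`` (all nuclei),
    ``phh3`` (mitotic subset of in-mask nuclei), ``tunel`` (apoptotic puncta).
    Returns the scene and a truth dict with keys ``vct``, ``vcm``, ``tunel``,
    ``mask`` (boolean ground-truth ventricle mask) and the nucleus centres.
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.shape_zyx
    zs, px = params.z_step_um, params.pixel_size_um
    extent = np.array([nz * zs, ny * px, nx * px])  # physical (z, y, x), um
    center = extent / 2.0
    semi = 0.38 * extent  # ventricle ellipsoid semi-axes

    # physical voxel-centre coordinate grids
    zz = (np.arange(nz) + 0.5) * zs
    yy = (np.arange(ny) + 0.5) * px
    xx = (np.arange(nx) + 0.5) * px
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    dist = _ellipsoid_distance((Z, Y, X), center, semi)
    mask_true = dist <= 1.0
    gfp = np.clip((1.0 - dist) * (semi.min() / px) + 0.5, 0.0, 1.0)

    r = params.nucleus_radius_um
    margin_in = (r + max(zs, px)) / semi.min()
    max_attempts = 2000 * max(1, params.n_nuclei_in_mask + params.n_nuclei_out_mask)

    def sample_centers(n: int, inside: bool, existing: list[np.ndarray]) -> list[np.ndarray]:
        got: list[np.ndarray] = []
        attempts = 0
        lo = np.array([r + zs, r + px, r + px])
        hi = extent - lo
        while len(got) < n:
            if attempts >= max_attempts:
                raise PackingError(
                    f"could not place {n} nuclei (separation "
                    f"{params.min_separation_um} um) after {max_attempts} attempts")
            cand = rng.uniform(lo, hi)
            attempts += 1
            d = float(_ellipsoid_distance(
                (cand[0:1], cand[1:2], cand[2:3]), center, semi)[0])
            ok_region = (d < 1.0 - margin_in) if inside else (d > 1.0 + margin_in)
            if not ok_region:
                continue
            if all(np.linalg.norm(cand - p) >= params.min_separation_um
                   for p in existing + got):
                got.append(cand)
        return got

    centers_in = sample_centers(params.n_nuclei_in_mask, True, [])
    centers_out = sample_centers(params.n_nuclei_out_mask, False, centers_in)
    all_centers = np.asarray(centers_in + centers_out) if centers_in or centers_out \
        else np.empty((0, 3))

    dapi = _render_spheres(params.shape_zyx, all_centers, r, zs, px)

    vcm = int(round(params.phh3_fraction * params.n_nuclei_in_mask))
    if vcm > 0:
        idx = np.sort(rng.choice(params.n_nuclei_in_mask, size=vcm, replace=False))
        phh3_centers = np.asarray(centers_in)[idx]
    else:
        phh3_centers = np.empty((0, 3))
    phh3 = _render_spheres(params.shape_zyx, phh3_centers, r, zs, px)

    # TUNEL puncta: small bright spots inside the ventricle, kept clear of the
    # shell edge and of one another.  Puncta are smaller than half a z-step,
    # so their z-position is snapped to the nearest sampled slice plane
    # (a punctum falling between planes would simply not be imaged).
    punc_r = 1.2
    tunel_centers: list[np.ndarray] = []
    attempts = 0
    while len(tunel_centers) < params.n_tunel_puncta:
        if attempts >= 2000 * max(1, params.n_tunel_puncta):
            raise PackingError("could not place TUNEL puncta")
        cand = rng.uniform(np.array([punc_r + zs] * 3), extent - punc_r - zs)
        cand[0] = (np.round(cand[0] / zs - 0.5) + 0.5) * zs
        attempts += 1
        d = float(_ellipsoid_distance((cand[0:1], cand[1:2], cand[2:3]), center, semi)[0])
        if d >= 1.0 - (punc_r + zs) / semi.min():
            continue
        if all(np.linalg.norm(cand - p) >= 4.0 * punc_r for p in tunel_centers):
            tunel_centers.append(cand)
    tunel = _render_spheres(params.shape_zyx,
                            np.asarray(tunel_centers) if tunel_centers else np.empty((0, 3)),
                            punc_r, zs, px)

    channels = {"gfp": gfp, "dapi": dapi, "phh3": phh3, "tunel": tunel}
    if params.noise_sigma > 0:
        for name in channels:
            channels[name] = np.clip(
                channels[name] + rng.normal(0.0, params.noise_sigma, params.shape_zyx),
                0.0, 1.0)

    scene = ZStackScene(channels=channels, z_step_um=zs, pixel_size_um=px)
    truth = {
        "vct": params.n_nuclei_in_mask,
        "vcm": vcm,
        "tunel": params.n_tunel_puncta,
        "mask": mask_true,
        "centers_in_um": np.asarray(centers_in) if centers_in else np.empty((0, 3)),
        "centers_out_um": np.asarray(centers_out) if centers_out else np.empty((0, 3)),
        "phh3_centers_um": phh3_centers,
        "tunel_centers_um": np.asarray(tunel_centers) if tunel_centers else np.empty((0, 3)),
    }
    return scene, truth
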