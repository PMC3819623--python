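"""Prospective cardiac gating from live video.

The gating loop mirrors how a laser is synchronized to the cardiac cycle of
an embryonic heart: the user picks a target frame in one recorded cycle
(typically end-diastole, the frame of maximal ventricular area), the software
matches every incoming frame against that reference cycle to estimate the
instantaneous cardiac phase, extrapolates the phase forward in time, and
emits a trigger timed so the pulse lands exactly when the heart next reaches
the target phase.  Hardware is mocked: the output is a list of
:class:`TriggerEvent` records, not device I/O.

Pipeline (each step is a public function):

1. :func:`estimate_period` — temporal self-similarity of the video;
2. :func:`build_reference` — one cycle of frames with phases assigned
   uniformly by time, phase 0 at the anchor;
3. :func:`estimate_phase` — zero-normalized cross-correlation (ZNCC) against
   the reference cycle, sub-frame refinement by quadratic interpolation;
4. :func:`unwrap_and_fit` — circular unwrapping + least-squares line
   phase(t), i.e. a locally constant heart rate;
5. :func:`predict_trigger` — next target-phase crossing of the fitted line,
   minus the configured system latency;
6. :func:`gate_stream` — the online loop with confidence gating, a refractory
   interval between fires and an explicit withhold path for pauses and
   arrhythmia.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (AperiodicInputError, InsufficientHistoryError, ParameterError,
                   VideoSequence)

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSet:
    """One full cardiac cycle of frames with phases in [0, 2*pi).

    Phase 0 is assigned to the anchor frame; subsequent reference phases are
    assigned uniformly by acquisition time within the cycle.
    """

    ref_frames: np.ndarray
    ref_phases: np.ndarray
    period_ms: float
    target_phase: float
    _norm_matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.ref_frames) != len(self.ref_phases):
            raise ParameterError("one phase per reference frame required")
        if len(self.ref_phases) < 3:
            raise ParameterError("a reference cycle needs at least 3 frames")
        if self.ref_phases[0] != 0.0 or not np.all(np.diff(self.ref_phases) > 0):
            raise ParameterError("ref_phases must start at 0 and increase strictly")

    @property
    def norm_matrix(self) -> np.ndarray:
        """Reference frames flattened, zero-mean, unit-norm (for ZNCC)."""
        if self._norm_matrix is None:
            flat = self.ref_frames.reshape(len(self.ref_frames), -1).astype(float)
            flat = flat - flat.mean(axis=1, keepdims=True)
            norms = np.linalg.norm(flat, axis=1, keepdims=True)
            self._norm_matrix = flat / np.maximum(norms, 1e-12)
        return self._norm_matrix


@dataclass
class PhaseEstimate:
    """Phase of one frame with the quality of its reference match."""

    frame_index: int
    phase: float
    score: float
    confidence: float


@dataclass
class PhaseFit:
    """Least-squares line through circularly unwrapped phase estimates."""

    slope_rad_per_ms: float
    intercept_rad: float
    residual_rad: float
    n_points: int
    t_last_ms: float


@dataclass
class TriggerEvent:
    """A predicted laser-fire time for a target phase (or a withheld event)."""

    fire_time_ms: float
    target_phase: float
    predicted_period_ms: float
    confidence: float
    withheld: bool = False
    reason: str = ""


@dataclass
class LaserPulseSpec:
    """Laser pulse energy/timing; the default is a 0.9 mJ, 3 ms pulse."""

    energy_mJ: float = 0.9
    duration_ms: float = 3.0
    n_pulses: int = 1
    inter_pulse_interval_s: float = 0.0

    def __post_init__(self) -> None:
        if self.energy_mJ <= 0:
            raise ParameterError("energy_mJ must be positive")
        if self.duration_ms <= 0:
            raise ParameterError("duration_ms must be positive")
        if self.n_pulses < 1:
            raise ParameterError("n_pulses must be >= 1")
        if self.n_pulses > 1 and self.inter_pulse_interval_s <= 0:
            raise ParameterError("inter_pulse_interval_s required for multi-pulse")


@dataclass
class GateConfig:
    """Tunable parameters of the online gating loop.

    The refractory interval defaults to 60 s, matching a multi-pulse injury
    protocol of up to 5 pulses at 1-minute intervals.
    """

    window: int = 8
    confidence_floor: float = 0.5
    margin_scale: float = 0.05
    slope_floor_rad_per_ms: float = TWO_PI / 3000.0  # periods above 3 s = asystole
    residual_tol_rad: float = 0.35
    latency_ms: float = 0.0
    n_pulses: int = 5
    refractory_ms: float = 60_000.0
    guard_ms: float | None = None  # default: one predicted period
    guard_tol_rad: float = 0.9


def circular_distance(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Smallest absolute angular difference between phases (radians)."""
    return np.abs(np.mod(np.asarray(a) - b + math.pi, TWO_PI) - math.pi)


# ---------------------------------------------------------------------------
# Period estimation
# ---------------------------------------------------------------------------

def _normalized_flat(frames: np.ndarray) -> np.ndarray:
    flat = frames.reshape(len(frames), -1).astype(float)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1, keepdims=True)
    return flat / np.maximum(norms, 1e-12)


def estimate_period(video: VideoSequence,
                    search_range_ms: tuple[float, float] = (150.0, 1500.0),
                    prominence_floor: float = 0.02) -> float:
    """Cardiac period (ms) maximizing temporal self-similarity.

    For every candidate lag L (frames) the mean ZNCC between frames i and
    i+L is computed; the best lag is refined to sub-frame resolution by
    quadratic interpolation of the similarity-vs-lag curve.

    Raises
    ------
    AperiodicInputError
        If the video carries no periodic structure above the prominence
        floor (e.g. a frozen heart or pure noise).
    """
    n = len(video)
    dt = video.frame_interval_ms
    frames = video.frames
    if float(np.ptp(frames)) < 1e-9:
        raise AperiodicInputError("video frames are identical: no periodicity")

    lag_min = max(2, int(math.floor(search_range_ms[0] / dt)))
    lag_max = min(n - 3, int(math.ceil(search_range_ms[1] / dt)))
    if lag_max <= lag_min:
        raise ParameterError("video too short for the requested period range "
                             "(need >= 2 cardiac cycles)")

    norm = _normalized_flat(frames)
    corr = norm @ norm.T
    lags = np.arange(lag_min, lag_max + 1)
    score = np.array([np.mean(np.diagonal(corr, offset=int(L))) for L in lags])

    prominence = float(np.max(score)) - float(np.median(score))
    if prominence < prominence_floor:
        raise AperiodicInputError("no self-similarity peak above prominence floor")

    # integer multiples of the period score as well as the period itself:
    # take the smallest-lag local maximum within tolerance of the best score
    from scipy.signal import find_peaks as _find_peaks
    peak_idx, _ = _find_peaks(score)
    tol = max(0.25 * prominence, 1e-3)
    candidates = [int(p) for p in peak_idx if score[p] >= np.max(score) - tol]
    best = candidates[0] if candidates else int(np.argmax(score))

    delta = 0.0
    if 0 < best < len(score) - 1:
        ym, y0, yp = score[best - 1], score[best], score[best + 1]
        denom = ym - 2 * y0 + yp
        if denom < -1e-12:
            delta = float(np.clip(0.5 * (ym - yp) / denom, -1.0, 1.0))
    return (lags[best] + delta) * dt


# ---------------------------------------------------------------------------
# Reference cycle
# ---------------------------------------------------------------------------

def build_reference(video: VideoSequence, period_ms: float, anchor_frame: int = 0,
                    target_phase: float | str = "end-diastole") -> ReferenceSet:
    """Extract one cardiac cycle as the phase-matching dictionary.

    ``target_phase`` may be a phase in radians or the string ``"end-diastole"``,
    in which case the anchor is moved to the cycle frame of maximal segmented
    ventricular area and the stored target phase is 0.
    """
    from .cardiofunc import segment_ventricle  # local import: no cycle at import time

    if period_ms <= 0:
        raise ParameterError("period_ms must be positive")
    t = video.timestamps_ms
    if anchor_frame < 0 or anchor_frame >= len(video):
        raise ParameterError("anchor_frame outside the video")
    if t[anchor_frame] + period_ms > t[-1] + video.frame_interval_ms:
        raise ParameterError("period longer than remaining video after anchor")

    def cycle_indices(a: int) -> np.ndarray:
        sel = (t >= t[a]) & (t < t[a] + period_ms)
        return np.nonzero(sel)[0]

    if isinstance(target_phase, str):
        if target_phase != "end-diastole":
            raise ParameterError(f"unknown target phase name: {target_phase!r}")
        idx = cycle_indices(anchor_frame)
        areas = np.array([segment_ventricle(video.frames[i], video.pixel_size_um)[1]
                          for i in idx])
        if float(np.ptp(areas)) / float(np.max(areas)) < 1e-3:
            raise ParameterError(
                "no identifiable end-diastole: ventricular area is constant")
        anchor_frame = int(idx[int(np.argmax(areas))])
        if t[anchor_frame] + period_ms > t[-1] + video.frame_interval_ms:
            raise ParameterError("period longer than remaining video after "
                                 "end-diastole anchor")
        target_value = 0.0
    else:
        target_value = float(target_phase) % TWO_PI

    idx = cycle_indices(anchor_frame)
    phases = TWO_PI * (t[idx] - t[anchor_frame]) / period_ms
    return ReferenceSet(ref_frames=video.frames[idx].copy(), ref_phases=phases,
                        period_ms=float(period_ms), target_phase=target_value)


# ---------------------------------------------------------------------------
# Phase estimation
# ---------------------------------------------------------------------------

def _scores_to_estimate(scores: np.ndarray, refs: ReferenceSet, frame_index: int,
                        margin_scale: float) -> PhaseEstimate:
    k = len(scores)
    j = int(np.argmax(scores))
    best = float(scores[j])

    # sub-frame refinement over the circular similarity curve, skipped for a
    # bit-exact reference match so that exact frames return exact phases
    phase = float(refs.ref_phases[j])
    if best < 1.0 - 1e-9:
        ym, y0, yp = scores[(j - 1) % k], best, scores[(j + 1) % k]
        denom = ym - 2 * y0 + yp
        if denom < -1e-12:
            delta = float(np.clip(0.5 * (ym - yp) / denom, -1.0, 1.0))
            phase = (phase + delta * TWO_PI / k) % TWO_PI

    # confidence from the margin between the best match and the best
    # non-neighbouring match (immediate circular neighbours are always close)
    excluded = {(j - 1) % k, j, (j + 1) % k}
    rivals = [scores[i] for i in range(k) if i not in excluded]
    margin = best - max(rivals) if rivals else best
    confidence = float(np.clip(margin / margin_scale, 0.0, 1.0))
    return PhaseEstimate(frame_index=frame_index, phase=phase, score=best,
                         confidence=confidence)


def estimate_phase(frame: np.ndarray, refs: ReferenceSet, frame_index: int = -1,
                   margin_scale: float = 0.05) -> PhaseEstimate:
    """Cardiac phase of a single frame by ZNCC against the reference cycle."""
    if frame.shape != refs.ref_frames.shape[1:]:
        raise ParameterError("frame shape does not match the reference set")
    flat = frame.reshape(-1).astype(float)
    flat = flat - flat.mean()
    norm = np.linalg.norm(flat)
    scores = refs.norm_matrix @ (flat / max(norm, 1e-12))
    return _scores_to_estimate(scores, refs, frame_index, margin_scale)


def estimate_phases(video: VideoSequence, refs: ReferenceSet,
                    margin_scale: float = 0.05) -> list[PhaseEstimate]:
    """Vectorized :func:`estimate_phase` over a whole video."""
    if video.frames.shape[1:] != refs.ref_frames.shape[1:]:
        raise ParameterError("frame shape does not match the reference set")
    scores = _normalized_flat(video.frames) @ refs.norm_matrix.T
    return [_scores_to_estimate(scores[i], refs, i, margin_scale)
            for i in range(len(video))]


# ---------------------------------------------------------------------------
# Phase model fit and trigger prediction
# ---------------------------------------------------------------------------

def unwrap_and_fit(history: Sequence[PhaseEstimate], timestamps_ms: Sequence[float],
                   window: int = 8, confidence_floor: float = 0.5) -> PhaseFit:
    """Least-squares line through the last ``window`` phase estimates.

    Estimates below the confidence floor are dropped; at least 3 usable
    estimates are required.  Phases are circularly unwrapped (adding 2*pi at
    wraps) before the fit, so the slope is the angular heart rate in rad/ms.
    """
    if len(history) != len(timestamps_ms):
        raise ParameterError("one timestamp per estimate required")
    recent = list(zip(history, timestamps_ms))[-window:]
    usable = [(pe, t) for pe, t in recent if pe.confidence >= confidence_floor]
    if len(usable) < 3:
        raise InsufficientHistoryError(
            f"only {len(usable)} estimates above confidence floor (need >= 3)")
    phases = np.unwrap(np.array([pe.phase for pe, _ in usable]))
    times = np.array([t for _, t in usable], dtype=float)
    slope, intercept = np.polyfit(times, phases, 1)
    resid = phases - (slope * times + intercept)
    return PhaseFit(slope_rad_per_ms=float(slope), intercept_rad=float(intercept),
                    residual_rad=float(np.sqrt(np.mean(resid ** 2))),
                    n_points=len(usable), t_last_ms=float(times[-1]))


def predict_trigger(fit: PhaseFit, target_phase: float, now_ms: float,
                    latency_ms: float = 0.0,
                    slope_floor_rad_per_ms: float = TWO_PI / 3000.0,
                    residual_tol_rad: float = 0.35) -> TriggerEvent:
    """Latency-compensated fire time for the next target-phase crossing.

    The fire time is the smallest t > now + latency at which the fitted phase
    line passes the target phase (mod 2*pi), minus the latency.  The event is
    withheld (not raised) when the slope is below the asystole floor or the
    fit residual exceeds the arrhythmia tolerance.
    """
    target = float(target_phase) % TWO_PI
    if fit.slope_rad_per_ms <= slope_floor_rad_per_ms:
        return TriggerEvent(fire_time_ms=math.nan, target_phase=target,
                            predicted_period_ms=math.inf, confidence=0.0,
                            withheld=True, reason="pause/asystole")
    period = TWO_PI / fit.slope_rad_per_ms
    if fit.residual_rad > residual_tol_rad:
        return TriggerEvent(fire_time_ms=math.nan, target_phase=target,
                            predicted_period_ms=period, confidence=0.0,
                            withheld=True, reason="arrhythmia")
    phi_now = fit.slope_rad_per_ms * (now_ms + latency_ms) + fit.intercept_rad
    k = math.floor((phi_now - target) / TWO_PI + 1e-9) + 1
    t_cross = (target + TWO_PI * k - fit.intercept_rad) / fit.slope_rad_per_ms
    confidence = float(np.clip(1.0 - fit.residual_rad / residual_tol_rad, 0.0, 1.0))
    return TriggerEvent(fire_time_ms=t_cross - latency_ms, target_phase=target,
                        predicted_period_ms=period, confidence=confidence)


# ---------------------------------------------------------------------------
# Online gating loop
# ---------------------------------------------------------------------------

def gate_stream(video: VideoSequence, refs: ReferenceSet,
                config: GateConfig | None = None) -> list[TriggerEvent]:
    """Run the full prospective-gating loop over a recorded video.

    Per frame: estimate phase, refit the phase line over the sliding window,
    and commit a trigger when the predicted crossing falls before the next
    frame arrives.  Commits respect the refractory interval and the pulse
    budget, and are verified against the frames inside a guard window after
    the predicted crossing: if the heart stops following the fitted phase
    line there (a pause freezes the image, so estimates stop advancing), the
    trigger is withheld instead of fired.  Withheld events are recorded once
    per contiguous withheld episode.
    """
    cfg = config or GateConfig()
    t = video.timestamps_ms
    estimates = estimate_phases(video, refs, margin_scale=cfg.margin_scale)
    events: list[TriggerEvent] = []
    fires = 0
    last_fire_ms: float | None = None
    in_withheld_episode = False

    for i in range(len(video) - 1):
        try:
            fit = unwrap_and_fit(estimates[:i + 1], t[:i + 1], window=cfg.window,
                                 confidence_floor=cfg.confidence_floor)
        except InsufficientHistoryError:
            continue
        candidate = predict_trigger(
            fit, refs.target_phase, now_ms=t[i], latency_ms=cfg.latency_ms,
            slope_floor_rad_per_ms=cfg.slope_floor_rad_per_ms,
            residual_tol_rad=cfg.residual_tol_rad)
        if candidate.withheld:
            if not in_withheld_episode:
                events.append(candidate)
                in_withheld_episode = True
            continue
        in_withheld_episode = False

        t_cross = candidate.fire_time_ms + cfg.latency_ms
        if not (t[i] < t_cross <= t[i + 1]):
            continue  # crossing not due before the next frame arrives
        if fires >= cfg.n_pulses:
            continue
        if last_fire_ms is not None and \
                candidate.fire_time_ms - last_fire_ms < cfg.refractory_ms:
            continue

        guard = cfg.guard_ms if cfg.guard_ms is not None else candidate.predicted_period_ms
        ok = True
        for j in range(i + 1, len(video)):
            if t[j] > t_cross + guard:
                break
            predicted = (fit.slope_rad_per_ms * t[j] + fit.intercept_rad) % TWO_PI
            dev = float(circular_distance(estimates[j].phase, predicted))
            if estimates[j].confidence < cfg.confidence_floor or dev > cfg.guard_tol_rad:
                ok = False
                break
        if ok:
            events.append(candidate)
            fires += 1
            last_fire_ms = candidate.fire_time_ms
        else:
            events.append(replace(candidate, fire_time_ms=math.nan, confidence=0.0,
                                  withheld=True, reason="pause/asystole"))
            in_withheld_episode = True
    return events


# ---------------------------------------------------------------------------
# Laser pulse arithmetic
# ---------------------------------------------------------------------------

def pulse_power(spec: LaserPulseSpec) -> float:
    """Average optical power in mW: energy (mJ) / duration (ms) * 1000."""
    if spec.duration_ms <= 0:
        raise ParameterError("duration_ms must be positive")
    return spec.energy_mJ / spec.duration_ms * 1000.0
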