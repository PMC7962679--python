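"""Binocular velocity-threshold (Engbert–Kliegl) microsaccade detection.

The detector classifies samples as saccadic when the 2-D eye velocity
exceeds an elliptic threshold of ``lambda_`` median-based standard
deviations per component, separately per eye, then keeps only binocular
events (at least one sample of overlap between the eyes), merges events
closer than a minimum intersaccadic interval, and classifies events with
amplitude below 2 degrees in both eyes as microsaccades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .preprocess import ValidityMask

__all__ = [
    "DetectionParams",
    "VelocityThreshold",
    "SaccadeEvent",
    "compute_velocity",
    "estimate_threshold",
    "detect_monocular",
    "pair_binocular",
    "measure_and_classify",
    "detect_saccades",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    """Detection settings; defaults follow the study conventions.

    lambda_
        Velocity-threshold multiplier applied to the median-based SD.
    min_duration_ms
        Minimum saccade duration; shorter suprathreshold runs are dropped
        (after ISI merging).
    min_isi_ms
        Minimum intersaccadic interval; suprathreshold runs separated by a
        shorter subthreshold gap are merged into a single event, treating
        the second run as an overshoot correction rather than a new saccade.
    max_microsaccade_amplitude_deg
        Events whose amplitude is strictly below this bound in *both* eyes
        are flagged as microsaccades.
    min_binocular_overlap_samples
        Minimum left/right overlap for an event to count as binocular.
    velocity_window
        Width in samples of the moving-average velocity stencil.
    min_usable_samples
        Minimum usable velocity samples required to estimate a threshold.
    sigma_floor
        Lower bound on the velocity SD estimate (degenerate-input guard).
    """

    lambda_: float = 6.0
    min_duration_ms: float = 6.0
    min_isi_ms: float = 20.0
    max_microsaccade_amplitude_deg: float = 2.0
    min_binocular_overlap_samples: int = 1
    velocity_window: int = 5
    min_usable_samples: int = 50
    sigma_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.min_duration_ms <= 0:
            raise ValueError("min_duration_ms must be positive")
        if self.max_microsaccade_amplitude_deg <= 0:
            raise ValueError("max_microsaccade_amplitude_deg must be positive")
        if self.velocity_window != 5:
            raise ValueError("only the 5-sample velocity stencil is supported")


@dataclass(frozen=True)
class VelocityThreshold:
    """Elliptic velocity threshold for one eye: eta = lambda * sigma."""

    eta_x: float
    eta_y: float
    sigma_x: float
    sigma_y: float
    degenerate: bool = False


@dataclass
class SaccadeEvent:
    """A binocular (or ground-truth) saccadic event.

    The event interval ``[onset_sample, offset_sample)`` is the union of the
    paired monocular intervals; per-eye kinematics are measured over each
    eye's own interval and then averaged across eyes.
    """

    onset_sample: int
    offset_sample: int
    amp_l: float = np.nan
    amp_r: float = np.nan
    pv_l: float = np.nan
    pv_r: float = np.nan
    is_microsaccade: bool = True
    is_binocular: bool = True
    left_interval: tuple[int, int] | None = None
    right_interval: tuple[int, int] | None = None
    kind: str = "saccade"

    @property
    def mean_amplitude(self) -> float:
        return 0.5 * (self.amp_l + self.amp_r)

    @property
    def mean_peak_velocity(self) -> float:
        return 0.5 * (self.pv_l + self.pv_r)

    @property
    def duration_samples(self) -> int:
        return self.offset_sample - self.onset_sample


def compute_velocity(positions: np.ndarray, sampling_rate: float,
                     usable: np.ndarray | None = None) -> np.ndarray:
    """Moving-average velocity estimate (deg/s) over an (n, 2) position series.

    Uses the 5-sample stencil ``v_n = (x_{n+2} + x_{n+1} - x_{n-1} - x_{n-2})
    * rate / 6``, exact for linear motion.  The first and last two samples,
    and any sample whose stencil touches an unusable sample, are NaN; the
    estimate therefore never crosses masked gaps.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    v = np.full_like(positions, np.nan)
    if n < 5:
        log.info("segment of %d samples is shorter than the velocity window; skipped", n)
        return v
    v[2:-2] = (positions[4:] + positions[3:-1]
               - positions[1:-3] - positions[:-4]) * (sampling_rate / 6.0)
    if usable is not None:
        ok = np.asarray(usable, bool).copy()
        # a velocity sample is usable only if the whole 5-sample stencil is
        for shift in (-2, -1, 1, 2):
            ok[max(0, -shift):n - max(0, shift)] &= \
                np.asarray(usable, bool)[max(0, shift):n - max(0, -shift)]
        v[~ok] = np.nan
    return v


def _median_sigma(component: np.ndarray, floor: float) -> tuple[float, bool]:
    med = np.median(component)
    var = np.median(component ** 2) - med ** 2
    sigma = np.sqrt(max(var, 0.0))
    if sigma < floor:
        return floor, True
    return sigma, False


def estimate_threshold(velocity: np.ndarray,
                       params: DetectionParams = DetectionParams()) -> VelocityThreshold:
    """Median-based velocity threshold: sigma^2 = median(v^2) - median(v)^2.

    Computed per component over all usable (finite) samples of the trial;
    a configurable floor guards against zero-variance inputs.  Raises
    ``ValueError`` if fewer than ``min_usable_samples`` are usable.
    """
    finite = np.isfinite(velocity).all(axis=1)
    if finite.sum() < params.min_usable_samples:
        raise ValueError(
            f"only {int(finite.sum())} usable velocity samples "
            f"(< {params.min_usable_samples}); threshold not estimable")
    vx, vy = velocity[finite, 0], velocity[finite, 1]
    sx, deg_x = _median_sigma(vx, params.sigma_floor)
    sy, deg_y = _median_sigma(vy, params.sigma_floor)
    if deg_x or deg_y:
        log.warning("degenerate velocity distribution; sigma floored at %g",
                    params.sigma_floor)
    return VelocityThreshold(eta_x=params.lambda_ * sx, eta_y=params.lambda_ * sy,
                             sigma_x=sx, sigma_y=sy, degenerate=deg_x or deg_y)


def _bool_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open intervals."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], flags, [False])).astype(np.int8)))
    return list(zip(idx[::2].tolist(), idx[1::2].tolist()))


def detect_monocular(velocity: np.ndarray, threshold: VelocityThreshold,
                     params: DetectionParams, sampling_rate: float) -> list[tuple[int, int]]:
    """Candidate events for one eye as half-open sample intervals.

    A candidate is a maximal run of samples with
    ``(v_x/eta_x)^2 + (v_y/eta_y)^2 > 1``.  Runs separated by a subthreshold
    gap shorter than ``min_isi_ms`` are merged *before* the minimum-duration
    test.  NaN velocity never exceeds threshold, so runs cannot span masked
    samples.
    """
    with np.errstate(invalid="ignore"):
        crit = (velocity[:, 0] / threshold.eta_x) ** 2 \
             + (velocity[:, 1] / threshold.eta_y) ** 2 > 1.0
    runs = _bool_runs(crit)  # NaN compares False, so runs never cross masked gaps
    min_isi = int(round(params.min_isi_ms * sampling_rate / 1000.0))
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < min_isi:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    min_dur = int(round(params.min_duration_ms * sampling_rate / 1000.0))
    return [r for r in merged if r[1] - r[0] >= min_dur]


def pair_binocular(left_events: Sequence[tuple[int, int]],
                   right_events: Sequence[tuple[int, int]],
                   params: DetectionParams = DetectionParams()) -> list[SaccadeEvent]:
    """Pair monocular candidates into binocular events.

    Greedy largest-overlap matching (ties broken by earlier onset); each
    monocular event joins at most one binocular event; unpaired events are
    discarded.  The binocular interval is the union of the paired intervals.
    """
    pairs = []
    for i, (l0, l1) in enumerate(left_events):
        for j, (r0, r1) in enumerate(right_events):
            overlap = min(l1, r1) - max(l0, r0)
            if overlap >= params.min_binocular_overlap_samples:
                pairs.append((-overlap, min(l0, r0), l0, r0, i, j))
    pairs.sort()
    used_l: set[int] = set()
    used_r: set[int] = set()
    events = []
    for _, _, _, _, i, j in pairs:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        l, r = left_events[i], right_events[j]
        events.append(SaccadeEvent(onset_sample=min(l[0], r[0]),
                                   offset_sample=max(l[1], r[1]),
                                   left_interval=tuple(l), right_interval=tuple(r)))
    events.sort(key=lambda e: e.onset_sample)
    return events


def _measure_eye(interval: tuple[int, int], positions: np.ndarray,
                 velocity: np.ndarray) -> tuple[float, float]:
    a, b = interval
    disp = positions[b - 1] - positions[a]
    amplitude = float(np.hypot(disp[0], disp[1]))
    speed = np.hypot(velocity[a:b, 0], velocity[a:b, 1])
    peak = float(np.nanmax(speed)) if np.isfinite(speed).any() else np.nan
    return amplitude, peak


def measure_and_classify(events: Sequence[SaccadeEvent],
                         positions_l: np.ndarray, positions_r: np.ndarray,
                         velocity_l: np.ndarray, velocity_r: np.ndarray,
                         params: DetectionParams = DetectionParams()) -> list[SaccadeEvent]:
    """Fill per-eye amplitude/peak velocity and the microsaccade flag.

    Amplitude is the onset-to-offset Euclidean displacement over each eye's
    own interval; a microsaccade requires amplitude strictly below the bound
    in both eyes.
    """
    out = []
    for ev in events:
        amp_l, pv_l = _measure_eye(ev.left_interval or (ev.onset_sample, ev.offset_sample),
                                   positions_l, velocity_l)
        amp_r, pv_r = _measure_eye(ev.right_interval or (ev.onset_sample, ev.offset_sample),
                                   positions_r, velocity_r)
        cap = params.max_microsaccade_amplitude_deg
        out.append(replace(ev, amp_l=amp_l, amp_r=amp_r, pv_l=pv_l, pv_r=pv_r,
                           is_microsaccade=bool(amp_l < cap and amp_r < cap)))
    return out


def detect_saccades(recording, mask: ValidityMask | None = None,
                    params: DetectionParams = DetectionParams()) -> list[SaccadeEvent]:
    """Run the full binocular detection chain on one trial.

    Velocity is estimated per eye over the valid samples of the mask (all
    samples if no mask is given), the threshold per eye over all usable
    samples of the trial, and candidates are detected, paired binocularly,
    measured and classified.  Returns the final event list; a trial whose
    threshold cannot be estimated raises ``ValueError``.
    """
    usable = mask.valid if mask is not None else None
    pos_l = recording.positions("left")
    pos_r = recording.positions("right")
    vel_l = compute_velocity(pos_l, recording.sampling_rate, usable)
    vel_r = compute_velocity(pos_r, recording.sampling_rate, usable)
    thr_l = estimate_threshold(vel_l, params)
    thr_r = estimate_threshold(vel_r, params)
    cand_l = detect_monocular(vel_l, thr_l, params, recording.sampling_rate)
    cand_r = detect_monocular(vel_r, thr_r, params, recording.sampling_rate)
    events = pair_binocular(cand_l, cand_r, params)
    return measure_and_classify(events, pos_l, pos_r, vel_l, vel_r, params)
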