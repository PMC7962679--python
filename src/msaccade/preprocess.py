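"""Artifact screening of raw gaze data.

Blinks (missing pupil), semi-blinks (very fast pupil-area transients where
the pupil is never fully occluded) and erroneous position samples are
identified, padded by 200 ms on each side to cut off the ramps where the
pupil is still partially occluded, and removed from analysis via a
per-sample validity mask.  An artifact in either eye invalidates the sample
for both eyes, because only binocular events are analysed downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ValidityMask",
    "REASON_CODES",
    "detect_blinks",
    "detect_semiblinks",
    "detect_erroneous",
    "apply_padding_and_mask",
    "screen_recording",
]

Interval = tuple[int, int]

#: per-sample reason codes, in increasing precedence
REASON_CODES = {"ok": 0, "padding": 1, "erroneous": 2, "semiblink": 3, "missing": 4}
_REASON_NAMES = {v: k for k, v in REASON_CODES.items()}


def _merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Sort and merge overlapping or abutting half-open intervals."""
    merged: list[Interval] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _runs_true(flags: np.ndarray) -> list[Interval]:
    edges = np.flatnonzero(np.diff(np.concatenate(([False], flags, [False])).astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


@dataclass
class ValidityMask:
    """Per-sample validity after screening, shared by both eyes.

    ``segments`` are the maximal half-open runs of valid samples; they tile
    the True entries of ``valid`` exactly.  ``reasons`` carries the
    per-sample code with precedence missing > semiblink > erroneous >
    padding > ok.
    """

    valid: np.ndarray
    reasons: np.ndarray
    sampling_rate: float

    @property
    def segments(self) -> list[Interval]:
        return _runs_true(self.valid)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def valid_duration_s(self) -> float:
        return self.n_valid / self.sampling_rate

    def report(self) -> dict:
        """Screening report: samples discarded per reason, valid duration."""
        counts = {name: int((self.reasons == code).sum())
                  for name, code in REASON_CODES.items()}
        return {
            "n_samples": int(self.valid.size),
            "n_valid": self.n_valid,
            "valid_duration_s": self.valid_duration_s,
            "discarded_by_reason": {k: v for k, v in counts.items() if k != "ok"},
            "n_segments": len(self.segments),
        }

    def report_json(self) -> str:
        return json.dumps(self.report(), indent=2)

    def reason_names(self) -> np.ndarray:
        return np.array([_REASON_NAMES[c] for c in self.reasons])


def detect_blinks(pupil_l: np.ndarray, pupil_r: np.ndarray) -> list[Interval]:
    """Maximal runs of missing pupil (NaN) in either eye.

    An all-missing trial returns one full-trial interval; downstream stages
    then see zero valid duration and flag the trial.
    """
    missing = ~np.isfinite(np.asarray(pupil_l, float)) \
            | ~np.isfinite(np.asarray(pupil_r, float))
    return _runs_true(missing)


def detect_semiblinks(pupil_l: np.ndarray, pupil_r: np.ndarray,
                      rate_threshold: float = 50.0) -> list[Interval]:
    """Maximal runs where |Delta pupil| strictly exceeds the threshold in either eye.

    The first difference is taken on the raw pupil-area series; a flagged
    difference between samples ``i`` and ``i+1`` marks both samples.  The
    default threshold of 50 units/sample is tracker-specific ("units" are
    arbitrary pupil-area units); the inequality is strict, so a change of
    exactly 50 is not flagged.
    """
    if rate_threshold <= 0:
        raise ValueError("rate_threshold must be positive")
    flagged = np.zeros(len(pupil_l), dtype=bool)
    for pupil in (np.asarray(pupil_l, float), np.asarray(pupil_r, float)):
        with np.errstate(invalid="ignore"):
            fast = np.abs(np.diff(pupil)) > rate_threshold
        flagged[:-1] |= fast
        flagged[1:] |= fast
    return _runs_true(flagged)


def detect_erroneous(recording, x_range: tuple[float, float] = (-45.0, 45.0),
                     y_range: tuple[float, float] = (-45.0, 45.0)) -> list[Interval]:
    """Temporary-intermittent-signal screening: position out of range or
    non-finite while the pupil is present.

    The study reports no numeric criterion for "erroneous" data, so the
    operational rule (configurable gaze-position bounds) is a package
    convention.
    """
    pupil_ok = np.isfinite(recording.pupil_l) & np.isfinite(recording.pupil_r)
    bad = np.zeros(recording.n_samples, dtype=bool)
    for x, y in ((recording.x_l, recording.y_l), (recording.x_r, recording.y_r)):
        finite = np.isfinite(x) & np.isfinite(y)
        with np.errstate(invalid="ignore"):
            in_range = (x > x_range[0]) & (x < x_range[1]) \
                     & (y > y_range[0]) & (y < y_range[1])
        bad |= pupil_ok & (~finite | ~in_range)
    return _runs_true(bad)


def apply_padding_and_mask(recording, blink_intervals: Sequence[Interval],
                           semiblink_intervals: Sequence[Interval],
                           erroneous_intervals: Sequence[Interval] = (),
                           pad_ms: float = 200.0) -> ValidityMask:
    """Build the validity mask, padding every artifact by ``pad_ms`` each side.

    Padding is clipped at the trial boundaries.  Reason precedence:
    missing > semiblink > erroneous > padding.
    """
    n = recording.n_samples
    rate = recording.sampling_rate
    pad = int(round(pad_ms * rate / 1000.0))
    valid = np.ones(n, dtype=bool)
    reasons = np.zeros(n, dtype=np.uint8)

    groups = (("padding", erroneous_intervals), ("padding", semiblink_intervals),
              ("padding", blink_intervals))
    # padded extent first (lowest precedence) ...
    for _, intervals in groups:
        for a, b in intervals:
            if not (0 <= a < b <= n):
                raise ValueError(f"interval ({a}, {b}) outside trial bounds [0, {n})")
            lo, hi = max(0, a - pad), min(n, b + pad)
            valid[lo:hi] = False
            reasons[lo:hi] = np.maximum(reasons[lo:hi], REASON_CODES["padding"])
    # ... then the artifact cores in increasing precedence
    for name, intervals in (("erroneous", erroneous_intervals),
                            ("semiblink", semiblink_intervals),
                            ("missing", blink_intervals)):
        for a, b in intervals:
            reasons[a:b] = np.maximum(reasons[a:b], REASON_CODES[name])
    return ValidityMask(valid=valid, reasons=reasons, sampling_rate=rate)


def screen_recording(recording, pad_ms: float = 200.0,
                     semiblink_threshold: float = 50.0,
                     position_bounds: tuple[tuple[float, float], tuple[float, float]]
                     = ((-45.0, 45.0), (-45.0, 45.0))) -> ValidityMask:
    """Full screening of one trial: blinks, semi-blinks, erroneous data, padding."""
    blinks = detect_blinks(recording.pupil_l, recording.pupil_r)
    semis = detect_semiblinks(recording.pupil_l, recording.pupil_r, semiblink_threshold)
    errs = detect_erroneous(recording, *position_bounds)
    return apply_padding_and_mask(recording, blinks, semis, errs, pad_ms)
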