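"""Detector benchmarking against simulated ground truth."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detect import SaccadeEvent

__all__ = ["MatchResult", "match_events", "evaluate_detection"]


@dataclass
class MatchResult:
    """Outcome of matching detected events to ground truth."""

    n_truth: int
    n_detected: int
    n_matched: int
    matches: list[tuple[int, int]]  # (truth index, detected index)

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else np.nan

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else np.nan


def match_events(truth: Sequence[SaccadeEvent], detected: Sequence[SaccadeEvent],
                 sampling_rate: float, onset_tolerance_ms: float = 10.0) -> MatchResult:
    """Greedy one-to-one matching by onset proximity.

    A detected event matches a true event when their onsets differ by at
    most ``onset_tolerance_ms``; candidate pairs are taken in order of
    increasing onset distance and each event participates at most once.
    """
    tol = onset_tolerance_ms * sampling_rate / 1000.0
    pairs = []
    for i, t in enumerate(truth):
        for j, d in enumerate(detected):
            dist = abs(t.onset_sample - d.onset_sample)
            if dist <= tol:
                pairs.append((dist, i, j))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    matches = []
    for _, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        matches.append((i, j))
    return MatchResult(n_truth=len(truth), n_detected=len(detected),
                       n_matched=len(matches), matches=matches)


def evaluate_detection(trial_pairs, sampling_rate: float,
                       min_truth_amplitude_deg: float = 0.0,
                       onset_tolerance_ms: float = 10.0) -> dict:
    """Pooled recall/precision over ``(truth_events, detected_events)`` pairs.

    Recall is restricted to true events with amplitude at or above
    ``min_truth_amplitude_deg``; precision counts every detected event
    against the full truth list (a detection of a small true event is not a
    false positive).
    """
    n_truth = n_det = hits_truth = hits_det = 0
    for truth, detected in trial_pairs:
        res_all = match_events(truth, detected, sampling_rate, onset_tolerance_ms)
        big = [t for t in truth
               if t.mean_amplitude >= min_truth_amplitude_deg]
        res_big = match_events(big, detected, sampling_rate, onset_tolerance_ms)
        n_truth += res_big.n_truth
        hits_truth += res_big.n_matched
        n_det += res_all.n_detected
        hits_det += res_all.n_matched
    return {
        "recall": hits_truth / n_truth if n_truth else np.nan,
        "precision": hits_det / n_det if n_det else np.nan,
        "n_truth": n_truth,
        "n_detected": n_det,
    }
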