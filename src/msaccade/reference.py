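"""Plain-loop reference implementation of the binocular detector.

A deliberately naive, sample-by-sample re-statement of the detection rules
(elliptic velocity criterion, ISI merging before the duration test, greedy
largest-overlap binocular pairing, per-eye measurement).  It shares no code
with :mod:`msaccade.detect` beyond the parameter container, and exists as
an independent validation path: on any segment both implementations must
produce identical event lists.
"""

from __future__ import annotations

import math

import numpy as np

from .detect import DetectionParams, SaccadeEvent, VelocityThreshold

__all__ = ["reference_detect"]


def _ref_velocity(positions, sampling_rate, usable=None):
    n = len(positions)
    v = [[math.nan, math.nan] for _ in range(n)]
    for i in range(2, n - 2):
        if usable is not None and not all(usable[i + k] for k in (-2, -1, 0, 1, 2)):
            continue
        for c in range(2):
            v[i][c] = (positions[i + 2][c] + positions[i + 1][c]
                       - positions[i - 1][c] - positions[i - 2][c]) * (sampling_rate / 6.0)
    return v


def _ref_threshold(v, params):
    usable = [s for s in v if math.isfinite(s[0]) and math.isfinite(s[1])]
    if len(usable) < params.min_usable_samples:
        raise ValueError("too few usable samples")
    etas = []
    sigmas = []
    for c in range(2):
        comp = sorted(s[c] for s in usable)
        med = _median(comp)
        med_sq = _median(sorted(x * x for x in comp))
        sigma = math.sqrt(max(med_sq - med * med, 0.0))
        sigma = max(sigma, params.sigma_floor)
        sigmas.append(sigma)
        etas.append(params.lambda_ * sigma)
    return VelocityThreshold(eta_x=etas[0], eta_y=etas[1],
                             sigma_x=sigmas[0], sigma_y=sigmas[1])


def _median(sorted_values):
    n = len(sorted_values)
    mid = n // 2
    if n % 2:
        return sorted_values[mid]
    return 0.5 * (sorted_values[mid - 1] + sorted_values[mid])


def _ref_monocular(v, thr, params, sampling_rate):
    n = len(v)
    above = []
    for i in range(n):
        vx, vy = v[i]
        if math.isfinite(vx) and math.isfinite(vy):
            above.append((vx / thr.eta_x) ** 2 + (vy / thr.eta_y) ** 2 > 1.0)
        else:
            above.append(False)
    runs = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    min_isi = int(round(params.min_isi_ms * sampling_rate / 1000.0))
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < min_isi:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    min_dur = int(round(params.min_duration_ms * sampling_rate / 1000.0))
    return [tuple(r) for r in merged if r[1] - r[0] >= min_dur]


def _ref_pair(left, right, params):
    candidates = []
    for i, (l0, l1) in enumerate(left):
        for j, (r0, r1) in enumerate(right):
            ov = min(l1, r1) - max(l0, r0)
            if ov >= params.min_binocular_overlap_samples:
                candidates.append((-ov, min(l0, r0), l0, r0, i, j))
    candidates.sort()
    taken_l, taken_r, pairs = set(), set(), []
    for _, _, _, _, i, j in candidates:
        if i not in taken_l and j not in taken_r:
            taken_l.add(i)
            taken_r.add(j)
            pairs.append((left[i], right[j]))
    pairs.sort(key=lambda p: min(p[0][0], p[1][0]))
    return pairs


def _ref_measure(interval, positions, v):
    a, b = interval
    dx = positions[b - 1][0] - positions[a][0]
    dy = positions[b - 1][1] - positions[a][1]
    amp = math.hypot(dx, dy)
    peak = max(math.hypot(v[i][0], v[i][1]) for i in range(a, b)
               if math.isfinite(v[i][0]))
    return amp, peak


def reference_detect(recording, mask=None,
                     params: DetectionParams = DetectionParams()) -> list[SaccadeEvent]:
    """Full brute-force detection chain on one trial (see module docstring)."""
    usable = list(mask.valid) if mask is not None else None
    pos_l = [tuple(p) for p in np.asarray(recording.positions("left"))]
    pos_r = [tuple(p) for p in np.asarray(recording.positions("right"))]
    v_l = _ref_velocity(pos_l, recording.sampling_rate, usable)
    v_r = _ref_velocity(pos_r, recording.sampling_rate, usable)
    thr_l = _ref_threshold(v_l, params)
    thr_r = _ref_threshold(v_r, params)
    cand_l = _ref_monocular(v_l, thr_l, params, recording.sampling_rate)
    cand_r = _ref_monocular(v_r, thr_r, params, recording.sampling_rate)
    events = []
    for l_int, r_int in _ref_pair(cand_l, cand_r, params):
        amp_l, pv_l = _ref_measure(l_int, pos_l, v_l)
        amp_r, pv_r = _ref_measure(r_int, pos_r, v_r)
        cap = params.max_microsaccade_amplitude_deg
        events.append(SaccadeEvent(
            onset_sample=min(l_int[0], r_int[0]),
            offset_sample=max(l_int[1], r_int[1]),
            amp_l=amp_l, amp_r=amp_r, pv_l=pv_l, pv_r=pv_r,
            is_microsaccade=amp_l < cap and amp_r < cap,
            left_interval=l_int, right_interval=r_int))
    return events
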