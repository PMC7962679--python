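"""End-to-end analysis pipeline: screen -> detect -> rates -> statistics.

Runs per-trial screening and binocular detection, aggregates per-trial
microsaccade rates into subject-level cell means, and applies the
repeated-measures battery (two-way RM-ANOVA with Greenhouse-Geisser
correction, Bonferroni pairwise comparisons, linear trend over visual
load).  Accepts either recorded trials or a simulated experiment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect, preprocess, rates, simulate, stats

__all__ = ["analyze_trials", "run_simulated_experiment", "analyze_rate_table",
           "write_bundle", "events_to_frame"]

log = logging.getLogger(__name__)


def events_to_frame(events, sampling_rate: float, trial_id="") -> pd.DataFrame:
    """Event table in the pipeline's tabular layout."""
    rows = []
    for e in events:
        rows.append({
            "trial_id": trial_id,
            "onset_sample": e.onset_sample,
            "offset_sample": e.offset_sample,
            "onset_ms": e.onset_sample * 1000.0 / sampling_rate,
            "duration_ms": e.duration_samples * 1000.0 / sampling_rate,
            "amp_left_deg": e.amp_l, "amp_right_deg": e.amp_r,
            "amp_mean_deg": e.mean_amplitude,
            "pv_left": e.pv_l, "pv_right": e.pv_r,
            "pv_mean": e.mean_peak_velocity,
            "is_microsaccade": e.is_microsaccade,
        })
    return pd.DataFrame(rows)


def analyze_trial(recording, params=None, pad_ms: float = 200.0,
                  semiblink_threshold: float = 50.0):
    """Screen and detect one trial; returns ``(mask, events)``."""
    params = params or detect.DetectionParams()
    mask = preprocess.screen_recording(recording, pad_ms=pad_ms,
                                       semiblink_threshold=semiblink_threshold)
    if mask.n_valid == 0:
        log.warning("trial has no valid samples after screening")
        return mask, []
    try:
        events = detect.detect_saccades(recording, mask, params)
    except ValueError as err:
        log.warning("trial skipped: %s", err)
        return mask, None
    return mask, events


def analyze_trials(trial_iter, params=None, pad_ms: float = 200.0,
                   rate_denominator: str = "valid_time") -> list[rates.TrialResult]:
    """Per-trial results for an iterable of :class:`simulate.TrialRecord`."""
    out = []
    for tr in trial_iter:
        mask, events = analyze_trial(tr.recording, params, pad_ms)
        if events is None:
            continue
        out.append(rates.microsaccade_rate(
            events, mask, subject=tr.subject, view=tr.view,
            count_level=tr.count, block=tr.block,
            rate_denominator=rate_denominator))
    return out


def _stats_bundle(cells: pd.DataFrame, view_order, count_order) -> dict:
    """Repeated-measures battery on a tidy subject x cell rate table."""
    wide = cells.pivot_table(index="subject", columns=["view", "count_level"],
                             values="rate")
    wide = wide.reindex(columns=pd.MultiIndex.from_product([view_order, count_order]))
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        log.warning("%d subjects dropped listwise (incomplete cells)", dropped)
    cube = complete.to_numpy().reshape(len(complete), len(view_order), len(count_order))
    anova = stats.rm_anova_two_way(cube)
    view_means = cube.mean(axis=2)
    count_means = cube.mean(axis=1)
    trend_f, trend_df, trend_p = stats.linear_trend(view_means)
    return {
        "anova": anova,
        "pairwise_view": stats.bonferroni_pairwise(view_means, view_order),
        "pairwise_count": stats.bonferroni_pairwise(count_means, count_order),
        "linear_trend_view": {"F": trend_f, "df": trend_df, "p": trend_p},
        "n_subjects_analyzed": len(complete),
    }


def analyze_rate_table(trials, view_order=("free", "easy", "hard"),
                       count_order=("no", "easy", "hard")) -> dict:
    """Summaries + statistics from a tidy per-trial rate table or TrialResults."""
    summary = rates.summarize_conditions(trials, view_order, count_order)
    cells = rates.subject_cell_means(trials)
    bundle = {"summary": summary}
    bundle.update(_stats_bundle(cells, list(view_order), list(count_order)))
    return bundle


def run_simulated_experiment(design=None, config=None, seed: int = 0,
                             params=None, keep_truth: bool = False) -> dict:
    """Simulate a full experiment and run the complete analysis chain.

    Returns a bundle with the per-trial table, condition summary, ANOVA,
    pairwise and trend results; with ``keep_truth`` the per-trial ground
    truth event lists and detections are retained for benchmarking.
    """
    design = design or simulate.ExperimentDesign()
    config = config or simulate.SimConfig()
    params = params or detect.DetectionParams()
    trial_results = []
    truth_pairs = []
    injected = {}
    for tr in simulate.simulate_experiment(design, config, seed):
        mask, events = analyze_trial(tr.recording, params)
        if events is None:
            continue
        trial_results.append(rates.microsaccade_rate(
            events, mask, subject=tr.subject, view=tr.view,
            count_level=tr.count, block=tr.block))
        injected.setdefault((tr.view, tr.count), []).append(tr.ms_rate)
        if keep_truth:
            truth_pairs.append((tr.truth.events,
                                [e for e in events if e.is_microsaccade]))
    bundle = analyze_rate_table(trial_results,
                                design.view_levels, design.count_levels)
    bundle["trials"] = rates.trials_to_frame(trial_results)
    bundle["design"] = design
    bundle["injected_cell_rates"] = {k: float(np.mean(v))
                                     for k, v in injected.items()}
    if keep_truth:
        bundle["truth_pairs"] = truth_pairs
    return bundle


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def write_bundle(bundle: dict, out_dir) -> None:
    """Write the result bundle as TSV tables plus a JSON statistics file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "trials" in bundle:
        bundle["trials"].to_csv(out / "trials.tsv", sep="\t", index=False)
    summary = bundle.get("summary", {})
    for name in ("cells", "view_marginals", "count_marginals"):
        if name in summary:
            summary[name].to_csv(out / f"summary_{name}.tsv", sep="\t", index=False)
    stats_obj = {
        "anova": [_jsonify(r) for r in bundle.get("anova", [])],
        "pairwise_view": [_jsonify(r) for r in bundle.get("pairwise_view", [])],
        "pairwise_count": [_jsonify(r) for r in bundle.get("pairwise_count", [])],
        "linear_trend_view": _jsonify(bundle.get("linear_trend_view", {})),
        "n_subjects_analyzed": bundle.get("n_subjects_analyzed"),
    }
    (out / "statistics.json").write_text(json.dumps(stats_obj, indent=2))
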