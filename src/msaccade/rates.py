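"""Per-trial microsaccade rates and condition-level summaries.

The dependent variable of the whole analysis is the microsaccade rate: the
number of detected microsaccades divided by the artifact-free (valid)
recording time of the trial.  Blocks are averaged within subject before any
across-subject statistics, mirroring the within-subject design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import SaccadeEvent
from .preprocess import ValidityMask

__all__ = ["TrialResult", "microsaccade_rate", "trials_to_frame",
           "summarize_conditions", "subject_cell_means"]

log = logging.getLogger(__name__)


@dataclass
class TrialResult:
    """Microsaccade count, valid duration and rate for one trial."""

    subject: int | str
    view: str
    count_level: str
    block: int
    n_microsaccades: int
    valid_duration_s: float
    rate: float
    mean_amplitude_deg: float
    mean_peak_velocity_deg_s: float
    excluded: bool = False


def microsaccade_rate(events: Sequence[SaccadeEvent], mask: ValidityMask,
                      subject=0, view="", count_level="", block=0,
                      rate_denominator: str = "valid_time") -> TrialResult:
    """Compute one trial's microsaccade rate.

    Only events flagged ``is_microsaccade`` are counted.  The denominator
    defaults to the valid (artifact-free) recording time, since no events
    can be detected on masked samples; ``rate_denominator="trial_time"``
    uses the nominal trial duration instead, for sensitivity analyses.
    A trial with zero valid duration is excluded (rate NaN, flag set).
    """
    if rate_denominator not in ("valid_time", "trial_time"):
        raise ValueError(f"unknown rate_denominator {rate_denominator!r}")
    micro = [e for e in events if e.is_microsaccade]
    duration = (mask.valid_duration_s if rate_denominator == "valid_time"
                else mask.valid.size / mask.sampling_rate)
    if duration <= 0:
        log.warning("trial (%s, %s, %s, block %s) has zero valid duration; excluded",
                    subject, view, count_level, block)
        return TrialResult(subject, view, count_level, block, len(micro), 0.0,
                           np.nan, np.nan, np.nan, excluded=True)
    amp = float(np.mean([e.mean_amplitude for e in micro])) if micro else np.nan
    pv = float(np.mean([e.mean_peak_velocity for e in micro])) if micro else np.nan
    return TrialResult(subject, view, count_level, block, len(micro),
                       duration, len(micro) / duration, amp, pv)


def trials_to_frame(trials: Sequence[TrialResult]) -> pd.DataFrame:
    df = pd.DataFrame([t.__dict__ for t in trials])
    return df[~df["excluded"]].drop(columns="excluded")


def subject_cell_means(trials) -> pd.DataFrame:
    """Average blocks within subject x cell; flags subjects with missing cells.

    Returns a tidy frame (subject, view, count_level, rate, ...).  Subjects
    lacking any of the cells present in the data are dropped (listwise
    exclusion for the repeated-measures stage) with a logged notice.
    """
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    agg = {"rate": ("rate", "mean"),
           "n_microsaccades": ("n_microsaccades", "sum"),
           "valid_duration_s": ("valid_duration_s", "sum"),
           "mean_amplitude_deg": ("mean_amplitude_deg", "mean"),
           "mean_peak_velocity_deg_s": ("mean_peak_velocity_deg_s", "mean")}
    agg = {k: v for k, v in agg.items() if v[0] in df.columns}
    cells = (df.groupby(["subject", "view", "count_level"])
               .agg(**agg).reset_index())
    n_cells = cells.groupby("subject")["rate"].count()
    expected = cells[["view", "count_level"]].drop_duplicates().shape[0]
    incomplete = n_cells[n_cells < expected].index.tolist()
    if incomplete:
        log.warning("subjects %s have missing cells; excluded listwise", incomplete)
        cells = cells[~cells["subject"].isin(incomplete)]
    return cells


def summarize_conditions(trials,
                         view_order: Sequence[str] = ("free", "easy", "hard"),
                         count_order: Sequence[str] = ("no", "easy", "hard")) -> dict:
    """Cell and marginal mean +/- SD of microsaccade rate across subjects.

    Subject-level aggregation first (blocks averaged within subject and
    cell), then means and SDs across subjects.  Returns a dict with a 3x3
    ``cells`` table and ``view_marginals`` / ``count_marginals`` frames
    mirroring the marginal structure of the design.
    """
    cells = subject_cell_means(trials)

    def _stats(group_cols, order, name):
        per_subj = cells.groupby(["subject"] + group_cols)["rate"].mean().reset_index()
        agg = (per_subj.groupby(group_cols)["rate"]
               .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
               .reset_index())
        if len(group_cols) == 1:
            agg[group_cols[0]] = pd.Categorical(agg[group_cols[0]], order, ordered=True)
            agg = agg.sort_values(group_cols[0]).reset_index(drop=True)
        return agg

    cell_table = _stats(["view", "count_level"], None, "cell")
    cell_table["view"] = pd.Categorical(cell_table["view"], view_order, ordered=True)
    cell_table["count_level"] = pd.Categorical(cell_table["count_level"],
                                               count_order, ordered=True)
    cell_table = cell_table.sort_values(["view", "count_level"]).reset_index(drop=True)
    return {
        "cells": cell_table,
        "view_marginals": _stats(["view"], view_order, "view"),
        "count_marginals": _stats(["count_level"], count_order, "count"),
        "n_subjects": cells["subject"].nunique(),
    }
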