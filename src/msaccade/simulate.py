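"""Synthetic binocular gaze recordings with ground-truth event labels.

The generator emulates an EyeLink-style 1000 Hz binocular recording of a
fixating observer over 60 s trials:

* slow fixational **drift** as an Ornstein–Uhlenbeck process (random walk
  with mean reversion toward the fixation center), shared by both eyes;
* **tremor / instrument noise** as per-eye AR(1)-correlated Gaussian noise
  normalized to 0.01 deg RMS (tracker output is low-pass filtered, so the
  noise is temporally correlated rather than white);
* **microsaccades** injected as a rate-compensated Poisson process with a
  post-event refractory gap, raised-cosine velocity profiles, lognormal
  amplitudes capped below 2 deg, and main-sequence peak velocities
  ``V = coeff * A ** exponent``;
* **blinks** (missing pupil and position) and **semi-blinks** (triangular
  pupil-area transients steeper than the screening threshold, pupil never
  fully occluded).

Events are conjugate (same displacement in both eyes) up to a small per-eye
onset jitter that exercises the one-sample binocular overlap rule, and are
never injected inside or near a blink/semi-blink, so all ground truth is
recoverable after screening.

A full 3 (visual load) x 3 (mental load) within-subject experiment is
generated by :func:`simulate_experiment`; its default per-cell rates are an
additive reconstruction of the study's marginal mean rates.  A lightweight
event-count-level counterpart, :func:`simulate_rate_experiment`, draws
per-trial microsaccade counts directly (no waveforms) for statistical
calibration studies that need thousands of replicate experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.signal import lfilter

from .detect import SaccadeEvent

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ExperimentDesign",
    "TrialRecord",
    "VIEW_MARGINAL_RATES",
    "COUNT_MARGINAL_RATES",
    "rate_matrix_from_marginals",
    "draw_poisson_onsets",
    "simulate_trial",
    "simulate_experiment",
    "simulate_rate_experiment",
    "trial_rng",
]

#: marginal mean microsaccade rates (events/s) by visual-load level
#: (free / easy / hard view) used as default simulator inputs
VIEW_MARGINAL_RATES = (0.53, 0.92, 1.09)
#: marginal mean rates (events/s) by mental-load level (no / easy / hard count)
COUNT_MARGINAL_RATES = (0.96, 0.80, 0.79)


class ConfigurationError(ValueError):
    """A simulator configuration field is invalid."""


@dataclass(frozen=True)
class SimConfig:
    """Trial-level simulation settings.

    Units: rates in events/s (blinks and semi-blinks in events/min),
    durations in ms unless suffixed ``_s``, positions/amplitudes in degrees
    of visual angle, pupil in arbitrary tracker units.
    """

    sampling_rate: float = 1000.0
    trial_duration_s: float = 60.0
    # fixational drift (Ornstein-Uhlenbeck position process, both eyes)
    drift_diffusion: float = 0.002      # deg^2/s
    drift_pullback: float = 2.0         # 1/s mean reversion toward center
    # tremor / instrument noise, per eye
    tremor_sd: float = 0.01             # deg RMS
    tremor_ar: float = 0.95             # AR(1) coefficient; 0 = white noise
    # microsaccade injection
    ms_rate: float = 0.85               # events/s
    ms_amplitude_log_mean: float = math.log(0.5)
    ms_amplitude_log_sd: float = 0.45
    ms_amplitude_cap_deg: float = 2.0   # exclusive upper bound
    main_seq_coeff: float = 90.0        # deg/s at 1 deg amplitude
    main_seq_exponent: float = 0.9
    ms_duration_ms: tuple[float, float] = (6.0, 25.0)
    ms_refractory_ms: float = 50.0      # dead time after each event
    ms_onset_jitter_samples: int = 1    # per-eye onset disconjugacy
    ms_direction_mode: str = "uniform"  # or "corrective"
    # artifacts
    blink_rate: float = 10.0            # events/min
    blink_duration_ms: tuple[float, float] = (100.0, 300.0)
    semiblink_rate: float = 3.0         # events/min
    semiblink_ramp_samples: tuple[int, int] = (4, 8)
    artifact_pad_ms: float = 200.0      # keep events clear of padded artifacts
    # pupil channel
    pupil_baseline: float = 1000.0
    pupil_noise_sd: float = 3.0
    pupil_transient_rate: float = 80.0  # units/sample during semi-blinks
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("ms_rate", "blink_rate", "semiblink_rate", "drift_diffusion"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.trial_duration_s <= 0:
            raise ConfigurationError("trial_duration_s must be positive")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        n = self.sampling_rate * self.trial_duration_s
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "sampling_rate * trial_duration_s must be an integer sample count")
        if self.ms_amplitude_cap_deg > 2.0:
            raise ConfigurationError(
                "ms_amplitude_cap_deg must be <= 2.0 so ground truth stays "
                "inside the microsaccade definition")
        if not 0 <= self.tremor_ar < 1:
            raise ConfigurationError("tremor_ar must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.trial_duration_s))


@dataclass
class GroundTruth:
    """True injected events and artifact intervals for one simulated trial."""

    events: list[SaccadeEvent]
    blink_intervals: list[tuple[int, int]]
    semiblink_intervals: list[tuple[int, int]]


@dataclass
class TrialRecord:
    """One simulated trial of an experiment, with its design coordinates."""

    subject: int
    view: str
    count: str
    block: int
    ms_rate: float
    recording: "object"
    truth: GroundTruth


def rate_matrix_from_marginals(
    view_means: Sequence[float] = VIEW_MARGINAL_RATES,
    count_means: Sequence[float] = COUNT_MARGINAL_RATES,
) -> np.ndarray:
    """Additive 3x3 rate matrix whose row/column means match the marginals.

    The two sets of marginal means do not share an identical grand mean, so
    both are rescaled to their common average grand mean first; afterwards
    ``M[i, j] = view_i + count_j - grand`` reproduces both sets of marginal
    means exactly.
    """
    v = np.asarray(view_means, dtype=float)
    c = np.asarray(count_means, dtype=float)
    grand = 0.5 * (v.mean() + c.mean())
    v = v * (grand / v.mean())
    c = c * (grand / c.mean())
    matrix = v[:, None] + c[None, :] - grand
    if np.any(matrix <= 0):
        raise ConfigurationError("rate_matrix derived from marginals is not "
                                 "strictly positive")
    return matrix


@dataclass(frozen=True)
class ExperimentDesign:
    """The 3x3 within-subject design: visual load x mental load."""

    view_levels: tuple[str, ...] = ("free", "easy", "hard")
    count_levels: tuple[str, ...] = ("no", "easy", "hard")
    n_subjects: int = 18
    n_blocks: int = 3
    rate_matrix: np.ndarray = field(default_factory=rate_matrix_from_marginals)
    subject_sd: float = 0.17   # between-subject lognormal SD of the rate multiplier

    def __post_init__(self) -> None:
        m = np.asarray(self.rate_matrix, dtype=float)
        if m.shape != (len(self.view_levels), len(self.count_levels)):
            raise ConfigurationError(
                f"rate_matrix shape {m.shape} does not match the "
                f"{len(self.view_levels)}x{len(self.count_levels)} design")
        if np.any(m <= 0):
            raise ConfigurationError("rate_matrix must be strictly positive")
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        object.__setattr__(self, "rate_matrix", m)


# ---------------------------------------------------------------------------
# seeding

def trial_rng(master_seed: int, *spawn_key: int) -> Generator:
    """Deterministic child generator for one unit of work.

    Children are derived with ``SeedSequence(master_seed, spawn_key=key)``:
    a splittable scheme, so adding subjects/trials never perturbs the
    streams of existing ones.  Never uses wall-clock entropy.
    """
    return default_rng(SeedSequence(master_seed, spawn_key=spawn_key))


# ---------------------------------------------------------------------------
# event-time sampling

def draw_poisson_onsets(rate: float, duration_s: float, rng: Generator) -> np.ndarray:
    """Onset times (s) of a homogeneous Poisson process on [0, duration)."""
    if rate <= 0:
        return np.array([])
    onsets = []
    t = rng.exponential(1.0 / rate)
    while t < duration_s:
        onsets.append(t)
        t += rng.exponential(1.0 / rate)
    return np.array(onsets)


def _in_blocked(t: float, zones: Sequence[tuple[float, float]]) -> bool:
    return any(a <= t < b for a, b in zones)


def _mean_event_duration_s(config: SimConfig) -> float:
    # E[D] = (2/coeff) * E[A^(1-e)] for lognormal amplitudes (truncation at
    # the 2-deg cap is negligible for the defaults); clipped into the
    # configured duration range.
    p = 1.0 - config.main_seq_exponent
    mean_pow = math.exp(p * config.ms_amplitude_log_mean
                        + 0.5 * (p * config.ms_amplitude_log_sd) ** 2)
    d = 2.0 * mean_pow / config.main_seq_coeff
    lo, hi = (x / 1000.0 for x in config.ms_duration_ms)
    return min(max(d, lo), hi)


def _draw_event_onsets(config: SimConfig, rng: Generator,
                       blocked: Sequence[tuple[float, float]]) -> list[float]:
    """Event onset times: renewal process with post-event dead time.

    Each accepted event is followed by ``duration + refractory`` of dead
    time; the exponential gap rate is compensated so that the realized
    long-run rate equals ``ms_rate`` exactly.  Candidates falling in a
    blocked zone (near an artifact) are thinned.
    """
    r = config.ms_rate
    if r <= 0:
        return []
    tau = _mean_event_duration_s(config) + config.ms_refractory_ms / 1000.0
    if r * tau >= 0.9:
        raise ConfigurationError(
            f"ms_rate {r}/s is too high for the refractory dead time {tau:.3f} s")
    r_comp = r / (1.0 - r * tau)
    mean_dur = _mean_event_duration_s(config)
    onsets: list[float] = []
    t = rng.exponential(1.0 / r_comp)
    while t + mean_dur < config.trial_duration_s:
        if _in_blocked(t, blocked):
            t += rng.exponential(1.0 / r_comp)
            continue
        onsets.append(t)
        t += tau + rng.exponential(1.0 / r_comp)
    return onsets


# ---------------------------------------------------------------------------
# waveform pieces

def _ou_process(n: int, rate: float, diffusion: float, pullback: float,
                rng: Generator) -> np.ndarray:
    """Exact-discretization OU sample path started at the fixation center."""
    if diffusion == 0:
        return np.zeros(n)
    noise = rng.standard_normal(n)
    dt = 1.0 / rate
    if pullback == 0:
        return np.cumsum(math.sqrt(diffusion * dt) * noise)
    a = math.exp(-pullback * dt)
    innov_sd = math.sqrt(diffusion / (2.0 * pullback) * (1.0 - a * a))
    return lfilter([innov_sd], [1.0, -a], noise)


def _tremor(n: int, sd: float, ar: float, rng: Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    noise = rng.standard_normal(n)
    if ar == 0:
        return sd * noise
    return lfilter([sd * math.sqrt(1.0 - ar * ar)], [1.0, -ar], noise)


def _raised_cosine_steps(amplitude: float, n_ev: int) -> np.ndarray:
    """Per-sample displacement magnitudes of a raised-cosine velocity pulse.

    The profile is smooth with zero endpoints; the weights are normalized so
    the summed displacement equals ``amplitude`` exactly.
    """
    k = np.arange(n_ev)
    profile = 1.0 - np.cos(2.0 * math.pi * (k + 0.5) / n_ev)
    return amplitude * profile / profile.sum()


def _draw_amplitude(config: SimConfig, rng: Generator) -> float:
    for _ in range(1000):
        a = float(rng.lognormal(config.ms_amplitude_log_mean,
                                config.ms_amplitude_log_sd))
        if a < config.ms_amplitude_cap_deg:
            return a
    raise ConfigurationError("amplitude distribution mass lies almost "
                             "entirely above ms_amplitude_cap_deg")


def _draw_artifacts(config: SimConfig, rng: Generator
                    ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Blink and semi-blink sample intervals, mutually separated."""
    n = config.n_samples
    rate = config.sampling_rate
    blinks: list[tuple[int, int]] = []
    for t in draw_poisson_onsets(config.blink_rate / 60.0, config.trial_duration_s, rng):
        dur = rng.uniform(*config.blink_duration_ms) / 1000.0
        a = int(t * rate)
        b = min(n, a + max(1, int(round(dur * rate))))
        if blinks and a < blinks[-1][1] + int(0.1 * rate):
            continue  # keep blinks separated by >= 100 ms
        blinks.append((a, b))
    semis: list[tuple[int, int]] = []
    guard = int(0.1 * rate)
    for t in draw_poisson_onsets(config.semiblink_rate / 60.0,
                                 config.trial_duration_s, rng):
        d = int(rng.integers(config.semiblink_ramp_samples[0],
                             config.semiblink_ramp_samples[1] + 1))
        a = int(t * rate)
        b = a + 2 * d - 1
        if b >= n:
            continue
        near_blink = any(a < bb + guard and b > ba - guard for ba, bb in blinks)
        near_semi = any(a < sb + guard and b > sa - guard for sa, sb in semis)
        if near_blink or near_semi:
            continue
        semis.append((a, b))
    return blinks, sorted(semis)


# ---------------------------------------------------------------------------
# trial and experiment generation

def simulate_trial(config: SimConfig = SimConfig(), seed: int | None = None,
                   meta: dict | None = None):
    """Simulate one binocular trial; returns ``(GazeRecording, GroundTruth)``.

    Identical ``(config, seed)`` pairs produce bit-identical output.
    """
    from .io import GazeRecording  # local import to avoid a cycle

    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = default_rng(seed) if not isinstance(seed, Generator) else seed
    n = config.n_samples
    rate = config.sampling_rate

    blinks, semis = _draw_artifacts(config, rng)

    # zones where no event may start: padded artifact extent plus the
    # longest possible event duration before it, so events end clear of the
    # screening padding
    pad_s = config.artifact_pad_ms / 1000.0
    max_dur_s = config.ms_duration_ms[1] / 1000.0
    blocked = [(a / rate - pad_s - max_dur_s, b / rate + pad_s)
               for a, b in blinks + semis]

    drift_x = _ou_process(n, rate, config.drift_diffusion, config.drift_pullback, rng)
    drift_y = _ou_process(n, rate, config.drift_diffusion, config.drift_pullback, rng)
    tremor = {eye: (_tremor(n, config.tremor_sd, config.tremor_ar, rng),
                    _tremor(n, config.tremor_sd, config.tremor_ar, rng))
              for eye in ("l", "r")}

    onsets = _draw_event_onsets(config, rng, blocked)
    jitter_max = config.ms_onset_jitter_samples
    inc = {eye: (np.zeros(n), np.zeros(n)) for eye in ("l", "r")}
    events: list[SaccadeEvent] = []
    cum_offset = np.zeros(2)  # running gaze offset, for the corrective mode
    for t in onsets:
        amplitude = _draw_amplitude(config, rng)
        v_peak = config.main_seq_coeff * amplitude ** config.main_seq_exponent
        dur_s = min(max(2.0 * amplitude / v_peak, config.ms_duration_ms[0] / 1000.0),
                    config.ms_duration_ms[1] / 1000.0)
        n_ev = max(3, int(round(dur_s * rate)))
        onset = int(t * rate)
        if onset < jitter_max or onset + n_ev + jitter_max >= n:
            continue
        if config.ms_direction_mode == "corrective" and np.linalg.norm(cum_offset) > 0.5:
            center = math.atan2(-cum_offset[1], -cum_offset[0])
            phi = center + rng.normal(0.0, 0.5)
        else:
            phi = rng.uniform(0.0, 2.0 * math.pi)
        steps = _raised_cosine_steps(amplitude, n_ev)
        dx, dy = steps * math.cos(phi), steps * math.sin(phi)
        cum_offset += (amplitude * math.cos(phi), amplitude * math.sin(phi))
        pv = float(steps.max() * rate)
        for eye in ("l", "r"):
            j = int(rng.integers(-jitter_max, jitter_max + 1)) if jitter_max else 0
            o = onset + j
            inc[eye][0][o:o + n_ev] += dx
            inc[eye][1][o:o + n_ev] += dy
        events.append(SaccadeEvent(onset_sample=onset, offset_sample=onset + n_ev,
                                   amp_l=amplitude, amp_r=amplitude,
                                   pv_l=pv, pv_r=pv, is_microsaccade=True,
                                   is_binocular=True, kind="microsaccade"))

    pos = {}
    for eye in ("l", "r"):
        pos[f"x_{eye}"] = drift_x + np.cumsum(inc[eye][0]) + tremor[eye][0]
        pos[f"y_{eye}"] = drift_y + np.cumsum(inc[eye][1]) + tremor[eye][1]

    pupil = {}
    for eye in ("l", "r"):
        p = config.pupil_baseline + config.pupil_noise_sd * rng.standard_normal(n)
        for a, b in semis:
            d = (b - a + 1) // 2
            dip = config.pupil_transient_rate * np.concatenate(
                [np.arange(1, d + 1), np.arange(d - 1, 0, -1)])
            p[a:b] -= dip
        for a, b in blinks:
            p[a:b] = np.nan
        pupil[f"pupil_{eye}"] = p
    for a, b in blinks:
        for key in pos:
            pos[key][a:b] = np.nan

    recording = GazeRecording(
        t_ms=np.arange(n) * (1000.0 / rate), sampling_rate=rate,
        meta=dict(meta or {}), **pos, **pupil)
    truth = GroundTruth(events=events, blink_intervals=blinks,
                        semiblink_intervals=semis)
    return recording, truth


def simulate_experiment(design: ExperimentDesign = ExperimentDesign(),
                        config: SimConfig = SimConfig(),
                        seed: int = 0) -> Iterator[TrialRecord]:
    """Generate a full within-subject experiment, one trial per cell per block.

    Yields :class:`TrialRecord` lazily (a full default experiment holds
    486 one-minute trials, which is better streamed than materialized).
    Each subject receives a single lognormal rate multiplier (mean 1,
    log-SD ``subject_sd``); trial seeds derive deterministically from the
    master seed via the splittable spawn-key scheme of :func:`trial_rng`.
    """
    subj_rng = trial_rng(seed, 1)
    mult = np.exp(subj_rng.normal(-0.5 * design.subject_sd ** 2,
                                  design.subject_sd, size=design.n_subjects))
    for s in range(design.n_subjects):
        for i, view in enumerate(design.view_levels):
            for j, count in enumerate(design.count_levels):
                for b in range(design.n_blocks):
                    cell_rate = float(mult[s] * design.rate_matrix[i, j])
                    cfg = replace(config, ms_rate=cell_rate)
                    rng = trial_rng(seed, 2, s, i, j, b)
                    rec, truth = simulate_trial(
                        cfg, rng, meta={"subject": s, "view": view,
                                        "count": count, "block": b})
                    yield TrialRecord(subject=s, view=view, count=count,
                                      block=b, ms_rate=cell_rate,
                                      recording=rec, truth=truth)


def simulate_rate_experiment(design: ExperimentDesign = ExperimentDesign(),
                             trial_duration_s: float = 60.0,
                             seed: int = 0):
    """Event-count-level experiment: per-trial Poisson microsaccade counts.

    Draws, for every subject x cell x block, the number of microsaccades in
    a trial directly from ``Poisson(multiplier * cell_rate * duration)`` —
    the same generative rate model as the waveform simulator, without the
    waveforms.  Intended for calibration studies (type-I error, ordering
    stability) that need thousands of replicate experiments.

    Returns a tidy DataFrame with columns subject, view, count_level,
    block, n_microsaccades, valid_duration_s, rate.
    """
    import pandas as pd

    rng = default_rng(seed) if not isinstance(seed, Generator) else seed
    mult = np.exp(rng.normal(-0.5 * design.subject_sd ** 2,
                             design.subject_sd, size=design.n_subjects))
    rows = []
    for s in range(design.n_subjects):
        for i, view in enumerate(design.view_levels):
            for j, count in enumerate(design.count_levels):
                lam = mult[s] * design.rate_matrix[i, j] * trial_duration_s
                for b in range(design.n_blocks):
                    k = int(rng.poisson(lam))
                    rows.append({"subject": s, "view": view, "count_level": count,
                                 "block": b, "n_microsaccades": k,
                                 "valid_duration_s": trial_duration_s,
                                 "rate": k / trial_duration_s})
    return pd.DataFrame(rows)
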