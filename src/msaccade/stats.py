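"""Repeated-measures analysis of the 3x3 within-subject design.

Implements the univariate repeated-measures ANOVA with Greenhouse-Geisser
sphericity correction, Mauchly's sphericity test, Bonferroni-corrected
pairwise comparisons and the ordered linear-trend contrast — the test
battery applied to per-subject cell means of microsaccade rate.

Conventions: the input is always a complete-cases array of per-subject
condition means (``subjects x k`` or ``subjects x a x b``); all p-values
are two-sided; Greenhouse-Geisser epsilon is computed per within-subject
effect from that effect's contrast covariance and clipped to its analytic
range ``[1/df_effect, 1]``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "MauchlyResult",
    "RmAnovaResult",
    "PairwiseResult",
    "mauchly_test",
    "gg_epsilon",
    "rm_anova_two_way",
    "bonferroni_pairwise",
    "linear_trend",
]

log = logging.getLogger(__name__)


@dataclass
class MauchlyResult:
    W: float
    chi2: float
    df: int
    p: float


@dataclass
class RmAnovaResult:
    """One within-subject effect of the repeated-measures ANOVA."""

    effect: str
    F: float
    df_num: float
    df_den: float
    epsilon_gg: float
    df_num_corr: float
    df_den_corr: float
    p_raw: float
    p_gg: float
    ss_effect: float
    ss_error: float
    mauchly: MauchlyResult | None = None


@dataclass
class PairwiseResult:
    pair: tuple
    mean_difference: float
    t: float
    df: int
    p_raw: float
    p_bonferroni: float


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """Helmert-style orthonormal contrast matrix, shape (k, k-1)."""
    raw = np.zeros((k, k - 1))
    for j in range(k - 1):
        raw[: j + 1, j] = 1.0
        raw[j + 1, j] = -(j + 1)
    return raw / np.linalg.norm(raw, axis=0)


def _as_matrix(data) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a subjects x conditions matrix")
    if np.isnan(x).any():
        raise ValueError("input contains missing values; supply complete cases")
    return x


def mauchly_test(data) -> MauchlyResult:
    """Mauchly's sphericity test on a subjects x k condition matrix.

    ``W = det(S*) / (tr(S*)/(k-1))^(k-1)`` on the covariance ``S*`` of
    ``k-1`` orthonormal contrasts; the chi-square approximation uses the
    standard correction factor.  A singular contrast covariance yields
    ``W = 0`` (sphericity maximally violated) with p = 0 rather than an
    error.  For k = 2 sphericity is trivially satisfied.
    """
    x = _as_matrix(data)
    n, k = x.shape
    if n <= k - 1:
        raise ValueError(f"need more than {k - 1} subjects for Mauchly's test")
    if k == 2:
        return MauchlyResult(W=1.0, chi2=0.0, df=0, p=1.0)
    c = _orthonormal_contrasts(k)
    s = np.cov(x @ c, rowvar=False, ddof=1)
    return _mauchly_from_cov(np.atleast_2d(s), k - 1, n)


def _mauchly_from_cov(s: np.ndarray, d: int, n: int) -> MauchlyResult:
    """Mauchly's statistic from a d x d orthonormal-contrast covariance."""
    df = d * (d + 1) // 2 - 1
    det = float(np.linalg.det(s))
    tr = float(np.trace(s))
    if det <= 0 or tr <= 0:
        log.warning("singular contrast covariance: sphericity maximally violated")
        return MauchlyResult(W=0.0, chi2=math.inf, df=df, p=0.0)
    W = det / (tr / d) ** d
    correction = (2 * d * d + d + 2) / (6.0 * d * (n - 1))
    chi2 = max(-(1.0 - correction) * (n - 1) * math.log(W), 0.0)
    p = float(sps.chi2.sf(chi2, df))
    return MauchlyResult(W=float(W), chi2=float(chi2), df=df, p=p)


def _epsilon_from_contrast_cov(s: np.ndarray, d: int) -> float:
    lam = np.linalg.eigvalsh(s)
    lam = np.clip(lam, 0.0, None)
    denom = d * float((lam ** 2).sum())
    if denom <= 0:
        log.warning("degenerate contrast covariance; epsilon set to lower bound")
        return 1.0 / d
    eps = float(lam.sum()) ** 2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def gg_epsilon(data) -> float:
    """Greenhouse-Geisser epsilon for a subjects x k condition matrix.

    Equals ``(sum lambda_i)^2 / ((k-1) sum lambda_i^2)`` over the
    eigenvalues of the double-centered condition covariance (equivalently,
    of the orthonormal-contrast covariance), clipped to ``[1/(k-1), 1]``.
    """
    x = _as_matrix(data)
    n, k = x.shape
    c = _orthonormal_contrasts(k)
    s = np.atleast_2d(np.cov(x @ c, rowvar=False, ddof=1))
    return _epsilon_from_contrast_cov(s, k - 1)


def _f_and_p(ss_eff: float, df_eff: float, ss_err: float, df_err: float,
             eps: float) -> tuple[float, float, float]:
    """F statistic plus raw and epsilon-corrected p; flat data give F=0, p=1."""
    if ss_err <= 1e-12 * max(ss_eff, 1.0):
        if ss_eff <= 1e-12:
            return 0.0, 1.0, 1.0
        return math.inf, 0.0, 0.0
    F = (ss_eff / df_eff) / (ss_err / df_err)
    p_raw = float(sps.f.sf(F, df_eff, df_err))
    p_gg = float(sps.f.sf(F, eps * df_eff, eps * df_err))
    return float(F), p_raw, p_gg


def rm_anova_two_way(data) -> list[RmAnovaResult]:
    """Two-way fully within-subject ANOVA on ``subjects x a x b`` cell means.

    Returns results for the two main effects and the interaction, each with
    its own error term (effect-by-subject interaction), Greenhouse-Geisser
    epsilon from that effect's contrast covariance, raw and corrected
    p-values, and Mauchly diagnostics.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("expected a subjects x a x b array of cell means")
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.isnan(y).any():
        raise ValueError("input contains missing cells; apply listwise deletion first")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))            # per subject
    m_a = y.mean(axis=(0, 2))            # per level of A
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)                # n x a
    m_sb = y.mean(axis=1)                # n x b
    m_ab = y.mean(axis=0)                # a x b

    ss_a = n * b * float(((m_a - grand) ** 2).sum())
    ss_b = n * a * float(((m_b - grand) ** 2).sum())
    ss_ab = n * float(((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_as = b * float(((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum())
    ss_bs = a * float(((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum())
    resid = (y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - grand)
    ss_abs = float((resid ** 2).sum())

    c_a = _orthonormal_contrasts(a)
    c_b = _orthonormal_contrasts(b)
    ones_a = np.full(a, 1.0 / math.sqrt(a))
    ones_b = np.full(b, 1.0 / math.sqrt(b))
    flat = y.reshape(n, a * b)

    def _effect(name, ss_eff, df_eff, ss_err, df_err, contrast):
        s = np.atleast_2d(np.cov(flat @ contrast, rowvar=False, ddof=1))
        d = contrast.shape[1]
        eps = _epsilon_from_contrast_cov(s, d)
        F, p_raw, p_gg = _f_and_p(ss_eff, df_eff, ss_err, df_err, eps)
        return RmAnovaResult(
            effect=name, F=F, df_num=df_eff, df_den=df_err,
            epsilon_gg=eps, df_num_corr=eps * df_eff, df_den_corr=eps * df_err,
            p_raw=p_raw, p_gg=p_gg, ss_effect=ss_eff, ss_error=ss_err,
            mauchly=_mauchly_from_cov(s, d, n))

    return [
        _effect("view", ss_a, a - 1, ss_as, (a - 1) * (n - 1),
                np.kron(c_a, ones_b[:, None])),
        _effect("count", ss_b, b - 1, ss_bs, (b - 1) * (n - 1),
                np.kron(ones_a[:, None], c_b)),
        _effect("view x count", ss_ab, (a - 1) * (b - 1), ss_abs,
                (a - 1) * (b - 1) * (n - 1), np.kron(c_a, c_b)),
    ]


def bonferroni_pairwise(data, labels=None) -> list[PairwiseResult]:
    """Paired t-tests for every level pair with Bonferroni correction.

    ``p_bonferroni = min(1, m * p_raw)`` with ``m = k(k-1)/2``.  A pair of
    identical columns (zero-variance, zero-mean difference) yields t = 0,
    p = 1 by convention.
    """
    x = _as_matrix(data)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least two levels")
    labels = list(labels) if labels is not None else list(range(k))
    m = k * (k - 1) // 2
    out = []
    for i, j in combinations(range(k), 2):
        diff = x[:, i] - x[:, j]
        sd = diff.std(ddof=1)
        if sd == 0:
            if abs(diff.mean()) > 0:
                t, p = math.inf, 0.0
            else:
                log.info("pair (%s, %s): zero-variance zero-mean difference; p = 1",
                         labels[i], labels[j])
                t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(x[:, i], x[:, j])
            t, p = float(t), float(p)
        out.append(PairwiseResult(pair=(labels[i], labels[j]),
                                  mean_difference=float(diff.mean()),
                                  t=t, df=n - 1, p_raw=p,
                                  p_bonferroni=min(1.0, m * p)))
    return out


def linear_trend(data) -> tuple[float, tuple[int, int], float]:
    """Linear-trend contrast over 3 ordered levels (e.g. free < easy < hard).

    Per subject ``L = -x1 + 0*x2 + x3``; ``F = t^2`` of the one-sample t of
    L against zero, with df ``(1, n-1)``.  Returns ``(F, (1, n-1), p)``.
    Flat data give F = 0, p = 1.
    """
    x = _as_matrix(data)
    n, k = x.shape
    if k != 3:
        raise ValueError("linear_trend expects exactly 3 ordered levels")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    L = x[:, 2] - x[:, 0]
    sd = L.std(ddof=1)
    if sd == 0:
        if abs(L.mean()) > 0:
            return math.inf, (1, n - 1), 0.0
        return 0.0, (1, n - 1), 1.0
    t = L.mean() / (sd / math.sqrt(n))
    F = t * t
    p = float(sps.f.sf(F, 1, n - 1))
    return float(F), (1, n - 1), p
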