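"""Discrimination and score-separation statistics for risk models.

* AUC as the Mann-Whitney concordance probability (ties count 1/2), with 95%
  confidence intervals from stratified bootstrap resampling (positives and
  negatives resampled separately).
* Paired bootstrap tests for AUC differences between two score sets on the
  same samples (two-sided p from the normal approximation of the resampled
  difference distribution).
* A proportional-odds (ordinal logistic) model of biopsy outcome on risk,
  reported as the odds ratio per 0.1 risk increase.
* Bias-corrected and accelerated (BCa) bootstrap intervals for group mean
  differences of risk scores.
* Threshold/spillover summaries: the score cut-off needed to reach a target
  sensitivity and the fraction of negatives misclassified at it.

Evaluation always uses the categorical biopsy outcome, never the continuous
training label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from ._rng import child_rng
from .errors import MetricError, ValidationError

__all__ = [
    "ENDPOINTS",
    "RocSummary",
    "EffectEstimate",
    "OrdinalEffect",
    "binary_endpoint",
    "auc",
    "auc_ci",
    "auc_difference_test",
    "proportional_odds_or",
    "mean_diff_bca",
    "threshold_for_sensitivity",
    "ordinal_levels",
]

#: Clinically relevant binary biopsy endpoints.
ENDPOINTS: tuple[str, ...] = ("any_cancer", "gs_ge_3p4", "gs_ge_4p3")

_POSITIVE_BY_ENDPOINT = {
    "any_cancer": {"Gs6", "Gs3+4", "Gs4+3", "Gs8plus"},
    "gs_ge_3p4": {"Gs3+4", "Gs4+3", "Gs8plus"},
    "gs_ge_4p3": {"Gs4+3", "Gs8plus"},
}

#: Ordered outcome levels for the proportional-odds model: no cancer
#: (unbiopsied NEC pooled with biopsy-negative), Gleason 6, Gleason 3+4,
#: Gleason >= 4+3.
_ORDINAL_LEVEL_BY_OUTCOME = {
    "NEC": 0,
    "BiopsyNegative": 0,
    "Gs6": 1,
    "Gs3+4": 2,
    "Gs4+3": 3,
    "Gs8plus": 3,
}


def binary_endpoint(outcome: str | Sequence[str], endpoint: str):
    """Binary disease status under an endpoint; NEC/biopsy-negative are negative."""
    if endpoint not in _POSITIVE_BY_ENDPOINT:
        raise MetricError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
    positives = _POSITIVE_BY_ENDPOINT[endpoint]
    if isinstance(outcome, str):
        return outcome in positives
    return np.array([o in positives for o in outcome], dtype=bool)


def ordinal_levels(outcomes: Sequence[str]) -> np.ndarray:
    """Four ordered outcome levels (0=no cancer .. 3=Gleason >= 4+3)."""
    return np.array([_ORDINAL_LEVEL_BY_OUTCOME[o] for o in outcomes], dtype=int)


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have the same length")
    ok = np.isfinite(scores)
    scores, labels = scores[ok], labels[ok]
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise MetricError("AUC undefined: both classes must be present")
    return pos, neg


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos, neg = _split(scores, labels)
    return _auc_from_split(pos, neg)


def _auc_from_split(pos: np.ndarray, neg: np.ndarray) -> float:
    n1, n0 = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class RocSummary:
    """AUC with a stratified-bootstrap confidence interval."""

    endpoint: str
    auc: float
    ci_lower: float
    ci_upper: float
    n_resamples: int
    stratified: bool = True


def auc_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_resamples: int = 1000,
    seed: int = 0,
    endpoint: str = "",
) -> RocSummary:
    """AUC with a percentile CI from stratified bootstrap resampling.

    Positives and negatives are resampled separately (so every resample
    contains both classes); bounds are the 2.5/97.5 percentiles.
    """
    if n_resamples < 2:
        raise ValidationError("n_resamples must be >= 2")
    pos, neg = _split(scores, labels)
    point = _auc_from_split(pos, neg)
    rng = child_rng(seed, "auc_ci")
    boot = np.empty(n_resamples)
    for b in range(n_resamples):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        boot[b] = _auc_from_split(bp, bn)
    if n_resamples == 2:
        lo, hi = float(boot.min()), float(boot.max())
    else:
        lo, hi = (float(v) for v in np.percentile(boot, [2.5, 97.5]))
    return RocSummary(
        endpoint=endpoint,
        auc=point,
        ci_lower=lo,
        ci_upper=hi,
        n_resamples=n_resamples,
    )


def auc_difference_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
    n_resamples: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Paired bootstrap test of AUC(a) - AUC(b) on identical samples.

    Returns ``(delta_auc, p_value)``.  Each resample draws positives and
    negatives (stratified, with replacement) and evaluates both score sets on
    the same resampled indices; the two-sided p comes from the normal
    approximation of the resampled difference distribution (mean/SD).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ValidationError("paired scores must align with labels")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b, y = a[ok], b[ok], y[ok]
    pos_idx, neg_idx = np.flatnonzero(y), np.flatnonzero(~y)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise MetricError("AUC undefined: both classes must be present")
    delta = auc(a, y) - auc(b, y)
    rng = child_rng(seed, "auc_diff")
    boot = np.empty(n_resamples)
    for r in range(n_resamples):
        pi = pos_idx[rng.integers(0, len(pos_idx), len(pos_idx))]
        ni = neg_idx[rng.integers(0, len(neg_idx), len(neg_idx))]
        boot[r] = _auc_from_split(a[pi], a[ni]) - _auc_from_split(b[pi], b[ni])
    sd = float(boot.std(ddof=1))
    if sd == 0:
        return delta, 1.0
    z = float(boot.mean()) / sd
    p = float(2 * stats.norm.sf(abs(z)))
    return delta, p


@dataclass
class OrdinalEffect:
    """Proportional-odds slope reported as an OR per 0.1 risk increase."""

    beta: float  # per unit risk
    or_per_01: float
    ci_lower: float
    ci_upper: float
    converged: bool


def proportional_odds_or(
    scores: Sequence[float],
    outcomes: Sequence[str],
    per: float = 0.1,
) -> OrdinalEffect:
    """Ordinal logistic regression of outcome level on risk score.

    Outcome levels are the four ordered classes of :func:`ordinal_levels`.
    The reported odds ratio is ``exp(per * beta)`` with a delta-method CI.
    """
    scores = np.asarray(scores, dtype=float)
    ok = np.isfinite(scores)
    scores = scores[ok]
    levels = ordinal_levels(np.asarray(outcomes, dtype=object)[ok])
    if np.unique(levels).size < 3:
        raise MetricError("need >= 3 ordered outcome levels for a proportional-odds fit")
    endog = pd.Series(
        pd.Categorical(levels, categories=sorted(np.unique(levels)), ordered=True)
    )
    model = OrderedModel(endog, scores[:, None], distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(method="bfgs", maxiter=200, disp=False)
    beta = float(fit.params.iloc[0])
    se = float(fit.bse.iloc[0])
    converged = bool(fit.mle_retvals.get("converged", True) and np.isfinite(se))
    z975 = float(stats.norm.ppf(0.975))
    return OrdinalEffect(
        beta=beta,
        or_per_01=float(np.exp(per * beta)),
        ci_lower=float(np.exp(per * (beta - z975 * se))),
        ci_upper=float(np.exp(per * (beta + z975 * se))),
        converged=converged,
    )


@dataclass
class EffectEstimate:
    """Bootstrap mean-difference estimate with a BCa interval."""

    group: str
    reference: str
    delta: float
    ci_lower: float
    ci_upper: float
    n_resamples: int
    method: str = "bca"


def mean_diff_bca(
    group_values: Sequence[float],
    reference_values: Sequence[float],
    n_resamples: int = 1000,
    seed: int = 0,
    group: str = "group",
    reference: str = "reference",
) -> EffectEstimate:
    """BCa bootstrap CI for ``mean(group) - mean(reference)``.

    Bias correction comes from the fraction of resampled differences below
    the observed difference; acceleration from the jackknife skewness over
    both groups' observations.  With a group of size 1 the acceleration is
    undefined and the interval falls back to plain percentiles (with a
    warning).
    """
    g = np.asarray(group_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    g, r = g[np.isfinite(g)], r[np.isfinite(r)]
    if len(g) == 0 or len(r) == 0:
        raise ValidationError("both groups must be non-empty")
    delta = float(g.mean() - r.mean())
    rng = child_rng(seed, "bca")
    boot = (
        g[rng.integers(0, len(g), size=(n_resamples, len(g)))].mean(axis=1)
        - r[rng.integers(0, len(r), size=(n_resamples, len(r)))].mean(axis=1)
    )
    if np.allclose(boot, delta):
        return EffectEstimate(group, reference, delta, delta, delta, n_resamples, "degenerate")

    method = "bca"
    if len(g) < 2 or len(r) < 2:
        warnings.warn("group of size 1: acceleration undefined, using percentile bounds")
        lo, hi = np.percentile(boot, [2.5, 97.5])
        method = "percentile"
    else:
        prop = np.mean(boot < delta)
        prop = min(max(prop, 1.0 / (2 * n_resamples)), 1 - 1.0 / (2 * n_resamples))
        z0 = stats.norm.ppf(prop)
        # Jackknife over every observation of both groups.
        jack = np.concatenate(
            [
                (g.sum() - g) / (len(g) - 1) - r.mean(),
                g.mean() - (r.sum() - r) / (len(r) - 1),
            ]
        )
        resid = jack.mean() - jack
        denom = float((resid**2).sum()) ** 1.5
        a = float((resid**3).sum()) / (6 * denom) if denom > 0 else 0.0
        z = stats.norm.ppf([0.025, 0.975])
        adj = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
        lo, hi = np.percentile(boot, 100 * adj)
    return EffectEstimate(group, reference, delta, float(lo), float(hi), n_resamples, method)


def threshold_for_sensitivity(
    scores: Sequence[float],
    labels: Sequence[bool],
    target_sens: float,
) -> tuple[float, float]:
    """Largest score cut-off reaching a target sensitivity, plus spillover.

    Classification is ``score >= threshold``; spillover is the fraction of
    negatives at or above the returned threshold (the patients who would be
    sent for an unnecessary biopsy).  ``target_sens=1`` returns the minimum
    positive score.
    """
    if not 0 < target_sens <= 1:
        raise ValidationError("target_sens must be in (0, 1]")
    pos, neg = _split(scores, labels)
    pos_sorted = np.sort(pos)
    n1 = len(pos_sorted)
    k = int(np.ceil(target_sens * n1))  # need at least k positives above cut
    threshold = float(pos_sorted[n1 - k])
    spillover = float(np.mean(neg >= threshold))
    return threshold, spillover
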