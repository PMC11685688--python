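"""Causal-effect estimators for two-sample MR.

Per-SNP Wald ratios b_j = beta_out_j / beta_exp_j with first-order
delta-method standard errors s_j = se_out_j / |beta_exp_j| (exposure-side
uncertainty ignored, the standard two-sample convention) are combined by
inverse-variance weighting:

    beta_IVW = sum(w_j b_j) / sum(w_j),   w_j = 1 / s_j^2
    se_fixed = sqrt(1 / sum(w_j))

Heterogeneity is measured by Cochran's Q = sum(w_j (b_j - beta_IVW)^2)
on k - 1 degrees of freedom. The multiplicative random-effects variant
keeps the same point estimate and inflates the standard error by
sqrt(Q / (k - 1)), floored at 1 so it is never narrower than the
fixed-effects interval.

Model selection follows the instrument count k: a single SNP uses the
Wald ratio, k = 2 the fixed-effects IVW, and k >= 3 the multiplicative
random-effects IVW. Effects are reported as odds ratios with normal
95% confidence intervals on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import DegenerateInstrumentError, DomainError, WrongMethodError
from .gwas_io import MIN_PVALUE
from .harmonize import HarmonizedPair

WALD_RATIO = "wald_ratio"
IVW_FIXED = "ivw_fixed"
IVW_RANDOM = "ivw_random"

#: z-quantile for a 95% interval, kept at full precision internally
Z_975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log(OR) scale with OR-scale reporting."""

    method: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    pvalue: float
    k: int
    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    q_pvalue: Optional[float] = None
    scale_factor: float = 1.0


def to_odds_ratio(
    beta: float, se: float, alpha: float = 0.05
) -> Tuple[float, float, float, float]:
    """OR, (1-alpha) CI bounds and two-sided normal p for a log-scale effect."""
    if not se > 0:
        raise DomainError(f"se must be > 0, got {se}")
    z_crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    or_ = math.exp(beta)
    ci_low = math.exp(beta - z_crit * se)
    ci_high = math.exp(beta + z_crit * se)
    pvalue = float(np.clip(2.0 * stats.norm.sf(abs(beta) / se), MIN_PVALUE, 1.0))
    return or_, ci_low, ci_high, pvalue


def _finish(method: str, beta: float, se: float, k: int, alpha: float = 0.05,
            q_stat=None, q_df=None, q_pvalue=None, scale_factor: float = 1.0) -> MREstimate:
    or_, lo, hi, p = to_odds_ratio(beta, se, alpha)
    return MREstimate(
        method=method, beta=beta, se=se, or_=or_, ci_low=lo, ci_high=hi,
        pvalue=p, k=k, q_stat=q_stat, q_df=q_df, q_pvalue=q_pvalue,
        scale_factor=scale_factor,
    )


def _ratios(pairs: Sequence[HarmonizedPair]) -> Tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their delta-method standard errors."""
    b_exp = np.array([p.beta_exp for p in pairs])
    if np.any(b_exp == 0.0):
        raise DegenerateInstrumentError("instrument with beta_exp = 0")
    b = np.array([p.beta_out for p in pairs]) / b_exp
    s = np.array([p.se_out for p in pairs]) / np.abs(b_exp)
    return b, s


def wald_ratio(pair: HarmonizedPair, alpha: float = 0.05) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp."""
    if not pair.kept:
        raise WrongMethodError("cannot estimate from a dropped pair")
    b, s = _ratios([pair])
    return _finish(WALD_RATIO, float(b[0]), float(s[0]), k=1, alpha=alpha)


def ivw_fixed(pairs: Sequence[HarmonizedPair], alpha: float = 0.05) -> MREstimate:
    """Fixed-effects inverse-variance weighted estimate over k >= 2 instruments."""
    pairs = [p for p in pairs if p.kept]
    k = len(pairs)
    if k < 2:
        raise WrongMethodError(f"ivw_fixed needs k >= 2 instruments, got {k}")
    b, s = _ratios(pairs)
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (b - beta) ** 2))
    q_df = k - 1
    q_p = float(stats.chi2.sf(q, q_df))
    return _finish(IVW_FIXED, beta, se, k, alpha, q_stat=q, q_df=q_df, q_pvalue=q_p)


def cochran_q(
    pairs: Sequence[HarmonizedPair], beta_hat: float
) -> Tuple[float, int, float]:
    """Cochran's heterogeneity Q about ``beta_hat`` with its df and chi-square p."""
    pairs = [p for p in pairs if p.kept]
    k = len(pairs)
    if k < 2:
        raise DomainError(f"Cochran's Q needs k >= 2, got {k}")
    b, s = _ratios(pairs)
    w = 1.0 / s**2
    q = float(np.sum(w * (b - beta_hat) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw_random(pairs: Sequence[HarmonizedPair], alpha: float = 0.05) -> MREstimate:
    """Multiplicative random-effects IVW: fixed point estimate, se scaled by
    sqrt(max(1, Q/(k-1)))."""
    fixed = ivw_fixed(pairs, alpha)
    scale = math.sqrt(max(1.0, fixed.q_stat / fixed.q_df))
    return _finish(
        IVW_RANDOM, fixed.beta, fixed.se * scale, fixed.k, alpha,
        q_stat=fixed.q_stat, q_df=fixed.q_df, q_pvalue=fixed.q_pvalue,
        scale_factor=scale,
    )


def select_model(k: int, random_min_k: int = 3) -> str:
    """Estimator choice by instrument count: 1 -> Wald ratio, up to
    ``random_min_k - 1`` -> fixed-effects IVW, otherwise random-effects IVW."""
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if k == 1:
        return WALD_RATIO
    if k < random_min_k:
        return IVW_FIXED
    return IVW_RANDOM


_ESTIMATORS = {WALD_RATIO: None, IVW_FIXED: ivw_fixed, IVW_RANDOM: ivw_random}


def estimate(
    pairs: Sequence[HarmonizedPair],
    alpha: float = 0.05,
    random_min_k: int = 3,
) -> MREstimate:
    """Apply the k-based model-selection rule and the chosen estimator."""
    kept = [p for p in pairs if p.kept]
    if not kept:
        raise WrongMethodError("no kept instruments to estimate from")
    method = select_model(len(kept), random_min_k)
    if method == WALD_RATIO:
        return wald_ratio(kept[0], alpha)
    return _ESTIMATORS[method](kept, alpha)
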