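"""Univariable two-sample MR estimators and diagnostics.

All estimators consume a :class:`~mrvalve.harmonize.HarmonizedSet` of
per-variant exposure effects γ̂_j (SD units), outcome effects Γ̂_j
(log-odds) and their standard errors, and report the causal effect on the
log-odds scale per 1 SD of exposure, with the exponentiated odds-ratio
triplet alongside.

Implemented methods
-------------------
* inverse-variance weighted (IVW) with multiplicative random effects:
  the weighted regression of Γ̂ on γ̂ through the origin with weights
  1/σ_Γ²; the fixed-effect SE is inflated by sqrt(max(1, Q/(J−1))) where
  Q is Cochran's heterogeneity statistic.  Valid when all instruments are
  valid or pleiotropy is balanced.
* MR-Egger: the same regression with an unconstrained intercept after
  orienting every variant to its exposure-increasing allele.  The slope
  is consistent under InSIDE even with directional pleiotropy; the
  intercept estimates the average directional pleiotropic effect and its
  test is reported alongside.  Inference uses t with J−2 df.
* weighted median: the 50 %-cumulative-weight quantile of the ordered
  Wald ratios, consistent when at least half the weight comes from valid
  instruments; SE by parametric bootstrap.

Plus leave-one-out IVW re-estimation and plot-ready funnel data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedSet, orient_positive_exposure

__all__ = [
    "MRFitResult",
    "IVW_RE",
    "EGGER",
    "WEIGHTED_MEDIAN",
    "PRESSO_CORRECTED",
    "wald_ratios",
    "ivw_random_effects",
    "mr_egger",
    "weighted_median",
    "leave_one_out",
    "funnel_data",
]

IVW_RE = "IVW_RE"
EGGER = "EGGER"
WEIGHTED_MEDIAN = "WEIGHTED_MEDIAN"
PRESSO_CORRECTED = "PRESSO_CORRECTED"

Z975 = 1.959963984540054  # Phi^-1(0.975)


@dataclass
class MRFitResult:
    """One estimator's causal estimate with uncertainty and diagnostics.

    ``beta`` is the log-odds change in the outcome per 1 SD increase in
    the exposure; ``or_`` etc. are the exponentiated triplet.  Method
    specific diagnostics (Cochran's Q for IVW; the intercept triple for
    Egger) live in ``extras``.  ``applicable`` is False when the method's
    minimum variant count was not met (a reportable non-result, distinct
    from an error).
    """

    method: str
    beta: float = math.nan
    se: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    pval: float = math.nan
    n_variants: int = 0
    extras: dict = field(default_factory=dict)
    applicable: bool = True

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_variants": self.n_variants,
            "applicable": self.applicable,
        }
        if self.applicable:
            d.update(or_=self.or_, or_low=self.or_low, or_high=self.or_high)
        d["extras"] = dict(self.extras)
        return d


def _not_applicable(method: str, n: int, reason: str) -> MRFitResult:
    return MRFitResult(method=method, n_variants=n, applicable=False, extras={"reason": reason})


def wald_ratios(hset: HarmonizedSet) -> pd.DataFrame:
    """Per-variant ratio estimates r_j = Γ̂_j/γ̂_j with first-order SEs.

    The first-order (delta-method) SE, σ_Γj/|γ̂_j|, ignores uncertainty
    in γ̂ and yields exactly the weights under which IVW equals weighted
    regression through the origin.
    """
    if len(hset) == 0:
        raise ValueError("empty harmonized set")
    bx, sx, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise ValueError("zero exposure effect; run orient_positive_exposure first")
    return pd.DataFrame(
        {
            "variant_id": hset.variant_ids,
            "ratio": by / bx,
            "se": sy / np.abs(bx),
        }
    )


def ivw_random_effects(hset: HarmonizedSet) -> MRFitResult:
    """IVW estimate with multiplicative random-effects SE inflation.

    Weights w_j = γ̂_j²/σ_Γj² (inverse variance of the Wald ratio under
    the first-order SE).  β̂ = Σw_j r_j / Σw_j; Cochran's
    Q = Σ w_j (r_j − β̂)² with J−1 df; SE = (Σw)^{-1/2} · max(1, √(Q/(J−1))).
    For a single variant the result reduces to the Wald ratio.
    """
    J = len(hset)
    if J == 0:
        raise ValueError("empty harmonized set")
    bx, sx, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise ValueError("zero exposure effect; run orient_positive_exposure first")
    r = by / bx
    w = bx**2 / sy**2
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    extras: dict = {}
    if J == 1:
        se = se_fixed
        extras["single_variant"] = True
    else:
        q = float(np.sum(w * (r - beta) ** 2))
        q_df = J - 1
        extras.update(Q=q, Q_df=q_df, Q_p=float(stats.chi2.sf(q, q_df)))
        se = se_fixed * max(1.0, math.sqrt(q / q_df))
    pval = float(2.0 * stats.norm.sf(abs(beta) / se))
    return MRFitResult(
        method=IVW_RE,
        beta=beta,
        se=se,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        pval=max(pval, np.finfo(float).tiny),
        n_variants=J,
        extras=extras,
    )


def mr_egger(hset: HarmonizedSet) -> MRFitResult:
    """MR-Egger weighted regression with intercept.

    The set is first oriented to positive exposure effects.  A weighted
    (1/σ_Γ²) regression of Γ̂ on γ̂ with intercept gives the slope as the
    causal estimate and the intercept β₀ as the average directional
    pleiotropy.  Both SEs are inflated by sqrt(max(1, RSS_w/(J−2))) and
    tested against t with J−2 df; CIs use t quantiles (small-J honesty).
    """
    J = len(hset)
    if J < 3:
        return _not_applicable(EGGER, J, "MR-Egger requires >= 3 variants")
    hset = orient_positive_exposure(hset)
    bx, sx, by, sy = hset.arrays()
    J = len(hset)
    if J < 3:
        return _not_applicable(EGGER, J, "fewer than 3 variants after orientation")
    w = 1.0 / sy**2
    # weighted simple regression closed form
    sw = w.sum()
    xbar = np.sum(w * bx) / sw
    ybar = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - xbar) ** 2)
    if sxx <= 0:
        return _not_applicable(EGGER, J, "no variation in exposure effects")
    slope = float(np.sum(w * (bx - xbar) * (by - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = by - intercept - slope * bx
    rss_w = float(np.sum(w * resid**2))
    df = J - 2
    infl = math.sqrt(max(1.0, rss_w / df))
    se_slope = float(sxx**-0.5) * infl
    se_int = float(math.sqrt(1.0 / sw + xbar**2 / sxx)) * infl
    tq = float(stats.t.ppf(0.975, df))
    p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, df))
    p_int = float(2.0 * stats.t.sf(abs(intercept) / se_int, df))
    return MRFitResult(
        method=EGGER,
        beta=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        pval=max(p_slope, np.finfo(float).tiny),
        n_variants=J,
        extras={
            "intercept": intercept,
            "intercept_se": se_int,
            "intercept_ci_low": intercept - tq * se_int,
            "intercept_ci_high": intercept + tq * se_int,
            "intercept_p": max(p_int, np.finfo(float).tiny),
            "rss_w": rss_w,
            "df": df,
        },
    )


def weighted_median_estimate(ratio: np.ndarray, weight: np.ndarray) -> float:
    """The 50 %-cumulative-weight quantile of ordered ratios.

    Ratios are sorted ascending; with normalized weights w'_j the
    cumulative midpoints are s_j = Σ_{k<=j} w'_k − w'_j/2 and the estimate
    interpolates ratio against s at s = 0.5.
    """
    total = weight.sum()
    if not total > 0:
        raise ValueError("total weight is zero")
    order = np.argsort(ratio, kind="stable")
    r = ratio[order]
    wn = weight[order] / total
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: Optional[int] = None
) -> MRFitResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Each bootstrap replicate perturbs every observed (γ̂_j, Γ̂_j) pair by
    its Gaussian standard errors and recomputes the estimate; the SE is
    the standard deviation across ``n_boot`` replicates; p from the
    normal approximation.
    """
    J = len(hset)
    if J < 3:
        return _not_applicable(WEIGHTED_MEDIAN, J, "weighted median requires >= 3 variants")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    bx, sx, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise ValueError("zero exposure effect; run orient_positive_exposure first")
    w = bx**2 / sy**2
    beta = weighted_median_estimate(by / bx, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(J)
        bys = by + sy * rng.standard_normal(J)
        bxs = np.where(bxs == 0.0, np.finfo(float).tiny, bxs)
        boots[b] = weighted_median_estimate(bys / bxs, bxs**2 / sy**2)
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else float("nan")
    pval = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else math.nan
    return MRFitResult(
        method=WEIGHTED_MEDIAN,
        beta=beta,
        se=se,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        pval=max(pval, np.finfo(float).tiny),
        n_variants=J,
        extras={"n_boot": n_boot},
    )


def leave_one_out(hset: HarmonizedSet) -> list[tuple[str, MRFitResult]]:
    """IVW re-estimation dropping each variant in turn.

    Large swings in the estimate when one variant is removed indicate an
    influential, possibly pleiotropic, instrument.
    """
    if len(hset) < 3:
        raise ValueError("leave-one-out requires >= 3 variants")
    out = []
    for vid in hset.variant_ids:
        out.append((vid, ivw_random_effects(hset.drop([vid]))))
    return out


def funnel_data(hset: HarmonizedSet) -> pd.DataFrame:
    """Plot-ready funnel table: per-variant ratio and precision 1/σ_r.

    Asymmetry of ratio against precision indicates directional
    pleiotropy, analogously to publication-bias funnels in meta-analysis.
    """
    ratios = wald_ratios(hset)
    return pd.DataFrame(
        {
            "variant_id": ratios["variant_id"],
            "ratio": ratios["ratio"],
            "precision": 1.0 / ratios["se"],
        }
    )
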