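"""MR-PRESSO: residual-sum-of-squares pleiotropy test with outlier correction.

The global test compares the observed leave-one-out residual sum of
squares against a parametric null simulated from the estimated effects;
the per-variant outlier test compares each variant's residual
contribution to its own simulated distribution with a Bonferroni-corrected
threshold; the corrected estimate re-runs IVW without the flagged
outliers; and the distortion test asks whether removing the flagged set
shifts the estimate more than removing random subsets of the same size.
When no outlier is flagged the corrected estimate and distortion p are
absent and tables render them as "NA" (no significant outliers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .estimators import MRFitResult, PRESSO_CORRECTED, ivw_random_effects
from .harmonize import HarmonizedSet

__all__ = ["PressoReport", "presso"]


@dataclass
class PressoReport:
    """MR-PRESSO global/outlier/distortion results.

    ``corrected`` and ``distortion_p`` are ``None`` unless at least one
    outlier was declared.  ``applicable`` is False below the 4-variant
    minimum.
    """

    rss_obs: float = math.nan
    global_p: float = math.nan
    n_sim: int = 0
    outlier_ids: list[str] = field(default_factory=list)
    outlier_pvals: dict[str, float] = field(default_factory=dict)
    corrected: Optional[MRFitResult] = None
    distortion_p: Optional[float] = None
    seed: Optional[int] = None
    applicable: bool = True
    reason: Optional[str] = None

    @property
    def outliers_found(self) -> bool:
        return len(self.outlier_ids) > 0

    def to_dict(self) -> dict:
        return {
            "applicable": self.applicable,
            "reason": self.reason,
            "rss_obs": self.rss_obs,
            "global_p": self.global_p,
            "n_sim": self.n_sim,
            "outlier_ids": list(self.outlier_ids),
            "outlier_pvals": dict(self.outlier_pvals),
            "corrected": None if self.corrected is None else self.corrected.to_dict(),
            "distortion_p": self.distortion_p,
            "seed": self.seed,
        }


def _loo_slopes(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Leave-one-out origin-regression slopes from per-variant terms.

    ``num``/``den`` are the per-variant contributions γ̂Γ̂/σ_Γ² and
    γ̂²/σ_Γ² along the last axis; the j-th slope omits the j-th term.
    """
    tot_n = num.sum(axis=-1, keepdims=True)
    tot_d = den.sum(axis=-1, keepdims=True)
    return (tot_n - num) / (tot_d - den)


def presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: Optional[int] = None,
) -> PressoReport:
    """Run the full MR-PRESSO procedure on a harmonized set.

    Parameters
    ----------
    n_sim
        Parametric simulations for the empirical null (>= 100).
    outlier_alpha
        Per-family outlier significance; the per-variant threshold is
        Bonferroni-corrected to ``outlier_alpha / J``.
    seed
        Seeds the simulation; the distortion test uses an independent
        child stream so each component is separately reproducible.

    Notes
    -----
    Empirical p-values use the add-one estimator
    ``(1 + #{sim >= obs}) / (n_sim + 1)`` and are therefore never zero.
    """
    if n_sim < 100:
        raise ValueError(f"n_sim must be >= 100, got {n_sim}")
    J = len(hset)
    if J < 4:
        return PressoReport(
            applicable=False, reason="MR-PRESSO requires >= 4 variants", seed=seed, n_sim=n_sim
        )
    bx, sx, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise ValueError("zero exposure effect; run orient_positive_exposure first")
    ids = hset.variant_ids
    ss = np.random.SeedSequence(seed)
    rng_sim, rng_dist = (np.random.default_rng(s) for s in ss.spawn(2))

    inv_v = 1.0 / sy**2
    num = bx * by * inv_v
    den = bx**2 * inv_v
    beta_loo = _loo_slopes(num, den)
    contrib_obs = (by - beta_loo * bx) ** 2 * inv_v
    rss_obs = float(contrib_obs.sum())

    # parametric null: exposure effects re-drawn around the estimates,
    # outcome effects around the leave-one-out predicted values
    bx_s = bx + sx * rng_sim.standard_normal((n_sim, J))
    by_s = beta_loo * bx + sy * rng_sim.standard_normal((n_sim, J))
    num_s = bx_s * by_s * inv_v
    den_s = bx_s**2 * inv_v
    beta_loo_s = _loo_slopes(num_s, den_s)
    contrib_s = (by_s - beta_loo_s * bx_s) ** 2 * inv_v
    rss_s = contrib_s.sum(axis=1)

    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))
    pvals = (1 + np.sum(contrib_s >= contrib_obs[None, :], axis=0)) / (n_sim + 1)
    outlier_pvals = {vid: float(p) for vid, p in zip(ids, pvals)}
    threshold = outlier_alpha / J
    outlier_ids = [vid for vid, p in zip(ids, pvals) if p < threshold]

    corrected = None
    distortion_p = None
    if len(outlier_ids) >= J:  # degenerate: every variant flagged
        outlier_ids = []
    if outlier_ids:
        corrected = ivw_random_effects(hset.drop(outlier_ids))
        corrected.method = PRESSO_CORRECTED
        beta_all = float(num.sum() / den.sum())
        d_obs = abs((beta_all - corrected.beta) / corrected.beta)
        m = len(outlier_ids)
        d_sim = np.empty(n_sim)
        idx = np.arange(J)
        for s in range(n_sim):
            drop = rng_dist.choice(idx, size=m, replace=False)
            keep = np.setdiff1d(idx, drop, assume_unique=True)
            b_sub = float(num[keep].sum() / den[keep].sum())
            d_sim[s] = abs((beta_all - b_sub) / b_sub)
        distortion_p = float((1 + np.sum(d_sim >= d_obs)) / (n_sim + 1))

    return PressoReport(
        rss_obs=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        outlier_ids=outlier_ids,
        outlier_pvals=outlier_pvals,
        corrected=corrected,
        distortion_p=distortion_p,
        seed=seed,
    )
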