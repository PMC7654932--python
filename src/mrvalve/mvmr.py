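"""Multivariable MR: joint direct effects of several correlated exposures.

With K exposures instrumented by a union set of J variants, the outcome
effects Γ̂_j are regressed on the J×K matrix of exposure effects without
intercept, weighted by 1/σ_Γj².  The k-th coefficient is the direct
effect of exposure k holding the others fixed — the estimand behind the
mutually-adjusted lipid odds ratios (and their LP(a)-adjusted variant).
SEs are inflated multiplicatively by sqrt(max(1, Q_mv/(J−K))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MRFitResult, Z975
from .harmonize import (
    COMPLEMENT,
    DROPPED_MISMATCH,
    DROPPED_PALINDROMIC,
    DROPPED_UNMATCHED,
    HarmonizationError,
    harmonize,
)
from .sumstats import TraitPanel

__all__ = ["MVHarmonizedSet", "CollinearityError", "mv_harmonize", "mv_ivw"]


class CollinearityError(ValueError):
    """The exposure-effect matrix is rank deficient."""


@dataclass
class MVHarmonizedSet:
    """Union-instrument exposure-effect matrix aligned to one outcome.

    ``beta_exp``/``se_exp`` are J×K arrays in ``exposure_names`` column
    order; ``audit`` records the fate of every candidate variant,
    including which panel a dropped variant was missing from.
    """

    exposure_names: list[str]
    outcome_name: str
    variant_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    audit: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        J, K = self.beta_exp.shape
        if K != len(self.exposure_names):
            raise ValueError("beta_exp column count != number of exposures")
        if not (len(self.variant_ids) == J == len(self.beta_out) == len(self.se_out)):
            raise ValueError("inconsistent variant dimensions")
        if np.any(self.se_out <= 0):
            raise ValueError("se_out must be > 0")

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)


def mv_harmonize(
    panels: Sequence[TraitPanel],
    outcome: TraitPanel,
    palindrome_policy: str = "infer_by_frequency",
    ambiguity_band: float = 0.08,
) -> MVHarmonizedSet:
    """Align K exposure panels and one outcome to a common effect allele.

    The instrument set is the union of variants across exposure panels,
    restricted to variants present in *all* panels and the outcome (the
    exposure-effect matrix must be complete).  The first panel listing a
    variant fixes its reference orientation; every other panel's effect is
    flipped to match using the univariable harmonization rules.

    Raises
    ------
    HarmonizationError
        When the retained variant count J is <= K (underdetermined).
    """
    if len(panels) < 2:
        raise ValueError("multivariable MR needs >= 2 exposure panels")
    names = [p.trait_name for p in panels]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate exposure names: {names}")
    all_records = [p.records() for p in panels]
    union_ids: list[str] = []
    seen = set()
    for recs in all_records:
        for vid in recs:
            if vid not in seen:
                seen.add(vid)
                union_ids.append(vid)

    # outcome aligned once to the reference (first) panel's coding
    h0 = harmonize(
        panels[0],
        outcome,
        palindrome_policy=palindrome_policy,
        ambiguity_band=ambiguity_band,
    )
    outcome_rows = {
        row.variant_id: (float(row.beta_out), float(row.se_out))
        for row in h0.data.itertuples(index=False)
    }

    audit: dict[str, str] = {}
    rows = []
    for vid in union_ids:
        missing_from = [n for n, recs in zip(names, all_records) if vid not in recs]
        if missing_from:
            audit[vid] = f"dropped_missing_from:{','.join(missing_from)}"
            continue
        act = h0.audit.get(vid, DROPPED_UNMATCHED)
        if vid not in outcome_rows:
            audit[vid] = act if act.startswith("dropped") else DROPPED_UNMATCHED
            continue
        # reference orientation: the first exposure panel's coding
        ref = all_records[0][vid]
        betas, ses = [ref.beta], [ref.se]
        ok = True
        for recs in all_records[1:]:
            rec = recs[vid]
            aligned = _align_to(ref, rec)
            if aligned is None:
                audit[vid] = DROPPED_MISMATCH
                ok = False
                break
            betas.append(aligned)
            ses.append(rec.se)
        if not ok:
            continue
        audit[vid] = act
        beta_out, se_out = outcome_rows[vid]
        rows.append(
            {
                "variant_id": vid,
                "beta_exp": betas,
                "se_exp": ses,
                "beta_out": beta_out,
                "se_out": se_out,
            }
        )
    K = len(panels)
    if len(rows) <= K:
        raise HarmonizationError(
            f"only {len(rows)} variants retained for {K} exposures: underdetermined"
        )
    return MVHarmonizedSet(
        exposure_names=names,
        outcome_name=outcome.trait_name,
        variant_ids=[r["variant_id"] for r in rows],
        beta_exp=np.array([r["beta_exp"] for r in rows], float),
        se_exp=np.array([r["se_exp"] for r in rows], float),
        beta_out=np.array([r["beta_out"] for r in rows], float),
        se_out=np.array([r["se_out"] for r in rows], float),
        audit=audit,
    )


def _align_to(ref, rec) -> Optional[float]:
    """rec.beta re-signed to ref's effect allele; None when incompatible."""
    ea, oa = ref.effect_allele, ref.other_allele
    pair = {rec.effect_allele, rec.other_allele}
    r_ea, r_oa = rec.effect_allele, rec.other_allele
    if pair == {COMPLEMENT[ea], COMPLEMENT[oa]} and pair != {ea, oa}:
        r_ea, r_oa = COMPLEMENT[r_ea], COMPLEMENT[r_oa]
    if (r_ea, r_oa) == (ea, oa):
        return rec.beta
    if (r_ea, r_oa) == (oa, ea):
        return -rec.beta
    return None


def _warn_weak_conditional_instruments(mvset: MVHarmonizedSet, floor: float = 10.0) -> None:
    """Warn when an exposure's instruments are conditionally weak.

    The conditional strength of exposure k is approximated by the mean
    squared z-score of the part of its effect column orthogonal (in the
    unweighted sense) to the other exposures' columns — a rough
    conditional-F.  Diagnostics only; never a hard filter.
    """
    import warnings

    X, S = mvset.beta_exp, mvset.se_exp
    J, K = X.shape
    if J <= K + 1:
        return
    for k in range(K):
        others = np.delete(X, k, axis=1)
        proj, *_ = np.linalg.lstsq(others, X[:, k], rcond=None)
        resid = X[:, k] - others @ proj
        f_cond = float(np.mean((resid / S[:, k]) ** 2))
        if f_cond < floor:
            warnings.warn(
                f"conditionally weak instruments for {mvset.exposure_names[k]} "
                f"(approximate conditional F = {f_cond:.1f} < {floor:g})",
                stacklevel=3,
            )


def mv_ivw(mvset: MVHarmonizedSet) -> list[MRFitResult]:
    """Weighted multiple regression of outcome on exposure effects.

    No intercept; weights 1/σ_Γ².  The heterogeneity statistic Q_mv is
    the weighted residual sum of squares on J−K df, and SEs are inflated
    by sqrt(max(1, Q_mv/(J−K))) as in the univariable IVW.  Returns one
    :class:`MRFitResult` per exposure in panel order.
    """
    J, K = mvset.beta_exp.shape
    if J <= K:
        raise ValueError(f"J={J} variants for K={K} exposures: underdetermined")
    X = mvset.beta_exp
    y = mvset.beta_out
    w = 1.0 / mvset.se_out**2
    Xw = X * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    xtx = Xw.T @ Xw
    rank = np.linalg.matrix_rank(xtx)
    if rank < K:
        # name the columns involved in the deficiency via tiny singular vectors
        _, sv, vt = np.linalg.svd(Xw, full_matrices=False)
        bad = vt[rank:]
        cols = sorted(
            {
                mvset.exposure_names[k]
                for row in bad
                for k in np.nonzero(np.abs(row) > 1e-8)[0]
            }
        )
        raise CollinearityError(f"exposure-effect matrix rank deficient; columns: {cols}")
    _warn_weak_conditional_instruments(mvset)
    coef = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yw - Xw @ coef
    q_mv = float(resid @ resid)
    df = J - K
    infl = math.sqrt(max(1.0, q_mv / df))
    cov = np.linalg.inv(xtx)
    ses = np.sqrt(np.diag(cov)) * infl
    results = []
    for k, name in enumerate(mvset.exposure_names):
        beta, se = float(coef[k]), float(ses[k])
        pval = float(2.0 * stats.norm.sf(abs(beta) / se))
        results.append(
            MRFitResult(
                method="MV_IVW",
                beta=beta,
                se=se,
                ci_low=beta - Z975 * se,
                ci_high=beta + Z975 * se,
                pval=max(pval, np.finfo(float).tiny),
                n_variants=J,
                extras={"exposure": name, "Q_mv": q_mv, "Q_df": df},
            )
        )
    return results
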