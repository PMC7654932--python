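"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs the exposure and outcome effect for each variant
expressed with respect to the same effect allele.  Variants are matched by
id; when the outcome panel reports the swapped allele pair the outcome
beta is negated (and eaf complemented); strand-complement codings are
resolved first when the pair is unambiguous.  Palindromic variants (A/T,
C/G) cannot be strand-resolved from alleles alone: they are either always
dropped, or their orientation is inferred from allele frequency when both
frequencies fall clearly on the same or opposite sides of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .sumstats import TraitPanel

__all__ = [
    "HarmonizedSet",
    "HarmonizationError",
    "harmonize",
    "orient_positive_exposure",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# audit actions
KEPT = "kept"
FLIPPED = "flipped"
INFERRED_PALINDROMIC = "inferred_palindromic"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_UNMATCHED = "dropped_unmatched"
DROPPED_MISMATCH = "dropped_mismatched_alleles"
DROPPED_NULL_EXPOSURE = "dropped_null_exposure"


class HarmonizationError(ValueError):
    """No variants survive harmonization; estimation impossible."""


@dataclass
class HarmonizedSet:
    """Aligned per-variant exposure/outcome effects ready for estimation.

    ``data`` columns: ``variant_id, beta_exp, se_exp, beta_out, se_out,
    eaf`` for retained variants; ``audit`` maps every input variant id to
    the action taken.
    """

    exposure_name: str
    outcome_name: str
    data: pd.DataFrame
    audit: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.data["variant_id"])

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        d = self.data
        return (
            d["beta_exp"].to_numpy(float),
            d["se_exp"].to_numpy(float),
            d["beta_out"].to_numpy(float),
            d["se_out"].to_numpy(float),
        )

    def subset(self, variant_ids) -> "HarmonizedSet":
        keep = self.data[self.data["variant_id"].isin(set(variant_ids))]
        return replace(self, data=keep.reset_index(drop=True))

    def drop(self, variant_ids) -> "HarmonizedSet":
        keep = self.data[~self.data["variant_id"].isin(set(variant_ids))]
        return replace(self, data=keep.reset_index(drop=True))

    def to_frame(self) -> pd.DataFrame:
        """Retained variants plus the action column (for TSV export)."""
        out = self.data.copy()
        out["action"] = [self.audit[v] for v in out["variant_id"]]
        return out


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def harmonize(
    exposure: TraitPanel,
    outcome: TraitPanel,
    palindrome_policy: str = "infer_by_frequency",
    ambiguity_band: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per variant.

    Parameters
    ----------
    palindrome_policy
        ``"drop_ambiguous"`` drops every palindromic variant;
        ``"infer_by_frequency"`` keeps a palindromic variant when both
        panels report an eaf outside ``0.5 ± ambiguity_band``, inferring
        orientation from whether the frequencies fall on the same side
        of 0.5.
    ambiguity_band
        Half-width of the frequency interval around 0.5 inside which a
        palindromic variant is considered unresolvable.

    Raises
    ------
    HarmonizationError
        When no variant is retained.
    """
    if palindrome_policy not in ("drop_ambiguous", "infer_by_frequency"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    out_by_id = {r.variant_id: r for r in outcome.records().values()}
    audit: dict[str, str] = {}
    rows = []
    for rec in exposure.records().values():
        orec = out_by_id.get(rec.variant_id)
        if orec is None:
            audit[rec.variant_id] = DROPPED_UNMATCHED
            continue
        ea, oa = rec.effect_allele, rec.other_allele
        o_ea, o_oa = orec.effect_allele, orec.other_allele
        beta_out, eaf_out = orec.beta, orec.eaf

        if _is_palindromic(ea, oa):
            # outcome alleles must be the same pair (complement is identical)
            if {o_ea, o_oa} != {ea, oa}:
                audit[rec.variant_id] = DROPPED_MISMATCH
                continue
            if palindrome_policy == "drop_ambiguous":
                audit[rec.variant_id] = DROPPED_PALINDROMIC
                continue
            lo, hi = 0.5 - ambiguity_band, 0.5 + ambiguity_band
            if (
                rec.eaf is None
                or eaf_out is None
                or lo <= rec.eaf <= hi
                or lo <= eaf_out <= hi
            ):
                audit[rec.variant_id] = DROPPED_PALINDROMIC
                continue
            # nominal-same-allele frequency: as reported if labels match,
            # complemented if labels are swapped
            freq_same = eaf_out if o_ea == ea else 1.0 - eaf_out
            same_side = (rec.eaf < 0.5) == (freq_same < 0.5)
            if same_side:
                if o_ea != ea:  # labels swapped but frequencies say same strand allele
                    beta_out = -beta_out
                    eaf_out = None if eaf_out is None else 1.0 - eaf_out
            else:
                if o_ea == ea:
                    beta_out = -beta_out
                    eaf_out = None if eaf_out is None else 1.0 - eaf_out
            audit[rec.variant_id] = INFERRED_PALINDROMIC
        else:
            pair = {o_ea, o_oa}
            if pair == {ea, oa}:
                pass  # direct coding
            elif pair == {COMPLEMENT[ea], COMPLEMENT[oa]}:
                o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
            else:
                audit[rec.variant_id] = DROPPED_MISMATCH
                continue
            if o_ea == ea and o_oa == oa:
                audit[rec.variant_id] = KEPT
            else:  # swapped
                beta_out = -beta_out
                eaf_out = None if eaf_out is None else 1.0 - eaf_out
                audit[rec.variant_id] = FLIPPED
        rows.append(
            {
                "variant_id": rec.variant_id,
                "beta_exp": rec.beta,
                "se_exp": rec.se,
                "beta_out": beta_out,
                "se_out": orec.se,
                "eaf": np.nan if rec.eaf is None else rec.eaf,
            }
        )
    if not rows:
        raise HarmonizationError(
            f"no variants retained harmonizing {exposure.trait_name} "
            f"against {outcome.trait_name}"
        )
    data = pd.DataFrame(
        rows, columns=["variant_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf"]
    )
    return HarmonizedSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        data=data,
        audit=audit,
    )


def orient_positive_exposure(hset: HarmonizedSet) -> HarmonizedSet:
    """Recode alleles so every exposure effect is non-negative.

    MR-Egger's estimate depends on allele orientation; the convention is
    to orient each variant to its exposure-increasing allele.  Negating
    both betas leaves every Wald ratio unchanged.  Variants with exactly
    zero exposure effect have an undefined ratio and are excluded.
    """
    if len(hset) == 0:
        raise HarmonizationError("empty harmonized set")
    data = hset.data.copy()
    audit = dict(hset.audit)
    zero = data["beta_exp"] == 0.0
    if zero.any():
        import warnings

        dropped = list(data.loc[zero, "variant_id"])
        warnings.warn(
            f"excluding {len(dropped)} variant(s) with zero exposure effect: {dropped}",
            stacklevel=2,
        )
        for v in dropped:
            audit[v] = DROPPED_NULL_EXPOSURE
        data = data[~zero].reset_index(drop=True)
    neg = data["beta_exp"] < 0
    data.loc[neg, ["beta_exp", "beta_out"]] *= -1.0
    data.loc[neg, "eaf"] = 1.0 - data.loc[neg, "eaf"]
    return replace(hset, data=data, audit=audit)
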