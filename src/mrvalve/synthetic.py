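"""Synthetic two-sample GWAS summary statistics with known ground truth.

Emulates the statistical structure of the study's data sources: a lipid
consortium exposure panel (independent genome-wide-significant SNPs whose
per-allele effects, in SD units, jointly explain a target fraction of
trait variance) and a biobank-scale binary-outcome panel (log-odds
effects with score-test standard errors scaled by the case fraction).
The two panels' sampling errors are independent, matching the two-sample
design.  Ground truth (per-variant effects, pleiotropy assignments,
corruption actions) is returned alongside for recovery tests.

Per variant j with minor-allele frequency p_j and standardized exposure:

* exposure effect γ_j (SD per effect allele), rescaled so that
  Σ 2p_j(1−p_j)γ_j² equals ``target_r2``;
* exposure SE σ_γj = 1/sqrt(n_exp · 2p_j(1−p_j));
* outcome effect Γ_j = β γ_j + α_j, with α_j = 0 for valid instruments
  and α_j ~ N(μ_α, σ_α²) for the invalid fraction π (optionally
  correlated with γ_j to violate InSIDE);
* outcome SE σ_Γj = 1/sqrt(n_out · K(1−K) · 2p_j(1−p_j)), the score-test
  approximation for a log-odds GWAS with case fraction K.

Effect alleles are generated as the exposure-increasing allele, so
directional pleiotropy is genuinely directional after harmonization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import CANONICAL_FIELDS, TraitPanel

__all__ = [
    "Pleiotropy",
    "Corruption",
    "MVSettings",
    "SynthConfig",
    "simulate_two_sample",
    "simulate_mv",
    "preset",
    "PRESETS",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


@dataclass(frozen=True)
class Pleiotropy:
    """Horizontal-pleiotropy regime of the generator.

    ``fraction_invalid`` of variants receive a direct outcome effect
    drawn from N(mean, sd²); ``inside_lambda`` adds λ·γ_j to it,
    violating the InSIDE condition when nonzero.
    """

    fraction_invalid: float = 0.0
    mean: float = 0.0
    sd: float = 0.0
    inside_lambda: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_invalid <= 1.0:
            raise ValueError("fraction_invalid must be in [0, 1]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class Corruption:
    """Allele-coding corruption applied to the outcome panel.

    ``allele_swap_rate``: effect/other labels exchanged with beta negated
    and eaf complemented (exactly invertible by harmonization);
    ``strand_flip_rate``: alleles replaced by their complements
    (invertible for non-palindromic variants); ``palindromic_rate``:
    fraction of variants generated with A/T or C/G allele pairs.
    """

    allele_swap_rate: float = 0.0
    strand_flip_rate: float = 0.0
    palindromic_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("allele_swap_rate", "strand_flip_rate", "palindromic_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class MVSettings:
    """Multi-exposure extension: K exposures with equicorrelated effects."""

    k_exposures: int = 2
    exposure_correlation: float = 0.0
    true_direct_effects: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.k_exposures < 1:
            raise ValueError("k_exposures must be >= 1")
        if len(self.true_direct_effects) != self.k_exposures:
            raise ValueError("true_direct_effects length must equal k_exposures")
        k = self.k_exposures
        if k > 1:
            rho = self.exposure_correlation
            if not -1.0 / (k - 1) < rho < 1.0:
                raise ValueError("exposure_correlation makes the matrix non-positive-definite")


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters of a simulated two-sample dataset.

    Defaults mirror the study's scale: 57 instruments (the LDL panel),
    an exposure GWAS of 83 198, a biobank outcome sample of 432 173 with
    1961 cases, and instruments explaining 12 % of exposure variance.
    """

    n_variants: int = 57
    n_exposure: int = 83_198
    n_outcome: int = 432_173
    case_fraction: float = 1961 / 432_173
    true_beta: float = 0.0
    target_r2: float = 0.12
    maf_range: tuple[float, float] = (0.05, 0.5)
    pleiotropy: Pleiotropy = Pleiotropy()
    mv: Optional[MVSettings] = None
    corruption: Optional[Corruption] = None
    seed: int = 0
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0.0 < self.target_r2 < 1.0:
            raise ValueError("target_r2 must be in (0, 1)")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must be within (0, 0.5]")


def _positions(j: int) -> tuple[str, int]:
    """Deterministic layout: >= 2 Mb spacing within each chromosome."""
    chrom = str(j % 22 + 1)
    pos = 2_000_000 * (j // 22 + 1)
    return chrom, pos


def _panel_frame(
    ids, chroms, poss, eas, oas, eafs, betas, ses, ns
) -> pd.DataFrame:
    pvals = 2.0 * stats.norm.sf(np.abs(np.asarray(betas) / np.asarray(ses)))
    pvals = np.maximum(pvals, np.finfo(float).tiny)
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chroms,
            "position": poss,
            "effect_allele": eas,
            "other_allele": oas,
            "eaf": eafs,
            "beta": betas,
            "se": ses,
            "pval": pvals,
            "n": ns,
        },
        columns=CANONICAL_FIELDS,
    )


def _draw_alleles(rng: np.random.Generator, J: int, palindromic_rate: float):
    eas, oas = [], []
    pal = rng.random(J) < palindromic_rate
    for j in range(J):
        pairs = PALINDROMIC_PAIRS if pal[j] else NON_PALINDROMIC_PAIRS
        ea, oa = pairs[rng.integers(len(pairs))]
        eas.append(ea)
        oas.append(oa)
    return eas, oas


def _draw_pleiotropy(
    rng: np.random.Generator, gamma: np.ndarray, cfg: Pleiotropy
) -> tuple[np.ndarray, np.ndarray]:
    J = len(gamma)
    alpha = np.zeros(J)
    n_invalid = math.ceil(cfg.fraction_invalid * J)
    invalid = np.zeros(J, dtype=bool)
    if n_invalid:
        idx = rng.choice(J, size=n_invalid, replace=False)
        invalid[idx] = True
        alpha[idx] = cfg.mean + cfg.sd * rng.standard_normal(n_invalid)
        if cfg.inside_lambda != 0.0:
            alpha[idx] += cfg.inside_lambda * gamma[idx]
    return alpha, invalid


def simulate_two_sample(config: SynthConfig):
    """Generate (exposure panel, outcome panel, truth record).

    Deterministic given ``config.seed``; the truth record carries the
    per-variant true effects, pleiotropy assignment and any corruption
    actions needed by recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_variants
    maf = rng.uniform(*config.maf_range, size=J)
    het = 2.0 * maf * (1.0 - maf)  # genotype variance under Hardy-Weinberg
    # exposure-increasing orientation: positive raw effects
    gamma_raw = np.abs(rng.standard_normal(J))
    scale = math.sqrt(config.target_r2 / float(np.sum(het * gamma_raw**2)))
    gamma = gamma_raw * scale
    se_exp = 1.0 / np.sqrt(config.n_exposure * het)
    k = config.case_fraction
    se_out = 1.0 / np.sqrt(config.n_outcome * k * (1.0 - k) * het)
    alpha, invalid = _draw_pleiotropy(rng, gamma, config.pleiotropy)
    gamma_true_out = config.true_beta * gamma + alpha

    beta_exp_obs = gamma + se_exp * rng.standard_normal(J)
    beta_out_obs = gamma_true_out + se_out * rng.standard_normal(J)

    ids = [f"rs{1000 + j}" for j in range(J)]
    chroms, poss = zip(*(_positions(j) for j in range(J)))
    corruption = config.corruption or Corruption()
    eas, oas = _draw_alleles(rng, J, corruption.palindromic_rate)

    exposure = TraitPanel(
        trait_name=config.exposure_name,
        data=_panel_frame(
            ids, chroms, poss, eas, oas, maf, beta_exp_obs, se_exp,
            np.full(J, float(config.n_exposure)),
        ),
        trait_type="continuous",
    )

    out_eas, out_oas = list(eas), list(oas)
    out_beta = beta_out_obs.copy()
    out_eaf = maf.copy()
    swapped = rng.random(J) < corruption.allele_swap_rate
    flipped = rng.random(J) < corruption.strand_flip_rate
    for j in range(J):
        if swapped[j]:
            out_eas[j], out_oas[j] = out_oas[j], out_eas[j]
            out_beta[j] = -out_beta[j]
            out_eaf[j] = 1.0 - out_eaf[j]
        if flipped[j]:
            out_eas[j] = COMPLEMENT[out_eas[j]]
            out_oas[j] = COMPLEMENT[out_oas[j]]
    outcome = TraitPanel(
        trait_name=config.outcome_name,
        data=_panel_frame(
            ids, chroms, poss, out_eas, out_oas, out_eaf, out_beta, se_out,
            np.full(J, float(config.n_outcome)),
        ),
        trait_type="binary",
    )
    truth = {
        "config": config,
        "variant_ids": ids,
        "maf": maf,
        "gamma": gamma,
        "alpha": alpha,
        "invalid": invalid,
        "Gamma": gamma_true_out,
        "se_exp": se_exp,
        "se_out": se_out,
        "beta_exp_obs": beta_exp_obs,
        "beta_out_obs": beta_out_obs,
        "allele_swapped": swapped,
        "strand_flipped": flipped,
    }
    return exposure, outcome, truth


def simulate_mv(config: SynthConfig):
    """Generate (list of exposure panels, outcome panel, truth record).

    Per-variant exposure-effect vectors are multivariate normal with
    equicorrelation ρ across exposures (magnitudes oriented positive on
    the first exposure), each column rescaled to ``target_r2``; outcome
    effects are Γ_j = Σ_k δ_k γ_jk plus any pleiotropy.
    """
    if config.mv is None:
        raise ValueError("config.mv must be set for simulate_mv")
    mv = config.mv
    K = mv.k_exposures
    rng = np.random.default_rng(config.seed)
    J = config.n_variants
    maf = rng.uniform(*config.maf_range, size=J)
    het = 2.0 * maf * (1.0 - maf)
    rho = mv.exposure_correlation
    cov = np.full((K, K), rho) + (1.0 - rho) * np.eye(K)
    L = np.linalg.cholesky(cov)
    raw = rng.standard_normal((J, K)) @ L.T
    # orient each variant to increase the first exposure
    sign = np.where(raw[:, 0] < 0, -1.0, 1.0)
    raw = raw * sign[:, None]
    gamma = np.empty_like(raw)
    for kk in range(K):
        scale = math.sqrt(config.target_r2 / float(np.sum(het * raw[:, kk] ** 2)))
        gamma[:, kk] = raw[:, kk] * scale
    se_exp = 1.0 / np.sqrt(config.n_exposure * het)
    kf = config.case_fraction
    se_out = 1.0 / np.sqrt(config.n_outcome * kf * (1.0 - kf) * het)
    delta = np.asarray(mv.true_direct_effects, float)
    alpha, invalid = _draw_pleiotropy(rng, gamma[:, 0], config.pleiotropy)
    Gamma = gamma @ delta + alpha

    ids = [f"rs{1000 + j}" for j in range(J)]
    chroms, poss = zip(*(_positions(j) for j in range(J)))
    eas, oas = _draw_alleles(rng, J, (config.corruption or Corruption()).palindromic_rate)

    panels = []
    obs_cols = []
    for kk in range(K):
        obs = gamma[:, kk] + se_exp * rng.standard_normal(J)
        obs_cols.append(obs)
        panels.append(
            TraitPanel(
                trait_name=f"{config.exposure_name}_{kk + 1}",
                data=_panel_frame(
                    ids, chroms, poss, eas, oas, maf, obs, se_exp,
                    np.full(J, float(config.n_exposure)),
                ),
                trait_type="continuous",
            )
        )
    beta_out_obs = Gamma + se_out * rng.standard_normal(J)
    outcome = TraitPanel(
        trait_name=config.outcome_name,
        data=_panel_frame(
            ids, chroms, poss, eas, oas, maf, beta_out_obs, se_out,
            np.full(J, float(config.n_outcome)),
        ),
        trait_type="binary",
    )
    truth = {
        "config": config,
        "variant_ids": ids,
        "maf": maf,
        "gamma": gamma,
        "alpha": alpha,
        "invalid": invalid,
        "Gamma": Gamma,
        "se_exp": se_exp,
        "se_out": se_out,
        "beta_exp_obs": np.column_stack(obs_cols),
        "beta_out_obs": beta_out_obs,
    }
    return panels, outcome, truth


#: named study-condition presets
PRESETS: dict[str, SynthConfig] = {
    # LDL -> aortic stenosis scale: 57 instruments, OR 1.5 per SD
    "ldl_as_like": SynthConfig(true_beta=math.log(1.5), seed=20_02),
    # same scale, no causal effect
    "null": SynthConfig(true_beta=0.0, seed=20_03),
    # 40% invalid instruments with strong positive-mean pleiotropy (InSIDE
    # holds): pleiotropic outcome effects ~7x the outcome-panel SE, the
    # regime where directional pleiotropy is unambiguous
    "directional_pleiotropy": SynthConfig(
        n_variants=100,
        true_beta=math.log(1.5),
        pleiotropy=Pleiotropy(fraction_invalid=0.4, mean=0.3, sd=0.05),
        seed=20_04,
    ),
    # three correlated lipid-like exposures, only the first causal
    "mv_lipids": SynthConfig(
        n_variants=100,
        true_beta=math.log(1.5),
        mv=MVSettings(
            k_exposures=3,
            exposure_correlation=0.5,
            true_direct_effects=(math.log(1.5), 0.0, 0.0),
        ),
        seed=20_05,
    ),
}


def preset(name: str, **overrides) -> SynthConfig:
    """A named preset config, optionally with field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg
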