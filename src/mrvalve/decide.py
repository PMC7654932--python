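"""Method selection, causal calls and power for two-sample MR.

The study design fits four estimators per exposure–outcome pair and then
(1) picks a single "best" estimate from the diagnostic pattern —
directional pleiotropy favours MR-Egger, strong heterogeneity with
detected outliers favours the PRESSO-corrected estimate, moderate
heterogeneity favours the weighted median, and a clean set favours IVW —
and (2) declares the association causal only when at least three
applicable methods agree.  The selection thresholds are a documented
reconstruction of the study's predefined flowchart and are configurable.

The minimum detectable odds ratio follows the asymptotic binary-outcome
MR power approximation: for outcome sample size n, case fraction K, and
instrument variance explained R², the detectable log-odds effect at
significance α and target power is

    β_min = (z_{1−α/2} + z_{power}) / sqrt(n · R² · K(1−K)).

A logistic simulation oracle (score test of outcome on the genetic score)
is provided to validate the approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .estimators import EGGER, IVW_RE, PRESSO_CORRECTED, WEIGHTED_MEDIAN, MRFitResult

__all__ = [
    "DecisionThresholds",
    "DecisionReport",
    "PowerSpec",
    "select_best",
    "causal_call",
    "min_detectable_or",
    "simulate_power",
]


@dataclass(frozen=True)
class DecisionThresholds:
    """Configurable thresholds of the method-selection rule.

    Defaults reconstruct the study flowchart: pleiotropy gate at
    p < 0.05 on the Egger intercept; a strong-heterogeneity gate at
    Q_p < 0.001 that hands over to the PRESSO-corrected estimate when
    outliers were found; a moderate-heterogeneity gate at Q_p <= 0.05
    (inclusive boundary) selecting the weighted median; IVW otherwise.
    """

    pleiotropy_p: float = 0.05
    strong_heterogeneity_p: float = 0.001
    heterogeneity_p: float = 0.05


@dataclass
class DecisionReport:
    """Best-method selection plus the >= 3-method causal call for a pair."""

    exposure: str
    outcome: str
    q_p: float
    intercept_p: float
    outliers_found: bool
    selected_method: str
    causal: Optional[bool]
    agreement: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "inputs": {
                "Q_p": self.q_p,
                "egger_intercept_p": self.intercept_p,
                "presso_outliers_found": self.outliers_found,
            },
            "selected_method": self.selected_method,
            "causal_call": (
                "indeterminate" if self.causal is None
                else ("causal" if self.causal else "not_causal")
            ),
            "method_agreement": self.agreement,
        }


def select_best(
    q_p: float,
    intercept_p: float,
    outliers_found: bool,
    thresholds: DecisionThresholds = DecisionThresholds(),
) -> str:
    """Select the best estimator from the diagnostic triple.

    Order of the rule: pleiotropy first (MR-Egger is the only estimator
    consistent under directional pleiotropy), then outlier-driven strong
    heterogeneity (PRESSO-corrected), then moderate heterogeneity
    (weighted median, robust to a minority of invalid instruments), else
    IVW, the most efficient estimator when its assumptions hold.
    """
    for name, value in (("Q_p", q_p), ("intercept_p", intercept_p)):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"missing diagnostic: {name}")
    t = thresholds
    if intercept_p < t.pleiotropy_p:
        return EGGER
    if q_p < t.strong_heterogeneity_p and outliers_found:
        return PRESSO_CORRECTED
    if q_p <= t.heterogeneity_p:
        return WEIGHTED_MEDIAN
    return IVW_RE


def causal_call(
    fits: Sequence[MRFitResult],
    alpha: float = 0.05,
    require_significance: bool = True,
) -> tuple[Optional[bool], dict]:
    """Call an association causal when >= 3 methods give consistent results.

    "Consistent" is operationalized as agreement in effect direction
    with, by default, each agreeing method also significant at ``alpha``.
    ``require_significance=False`` relaxes to direction-only agreement.
    Returns (verdict, agreement detail); the verdict is ``None``
    (indeterminate) when fewer than 3 methods are applicable.
    """
    detail: dict = {"alpha": alpha, "require_significance": require_significance, "methods": {}}
    applicable = [f for f in fits if f.applicable]
    for f in fits:
        entry = {"applicable": f.applicable}
        if f.applicable:
            entry.update(
                direction="positive" if f.beta > 0 else "negative",
                pval=f.pval,
                significant=bool(f.pval < alpha),
            )
        detail["methods"][f.method] = entry
    if len(applicable) < 3:
        detail["reason"] = "fewer than 3 applicable methods"
        return None, detail
    for sign in (1.0, -1.0):
        agreeing = [
            f
            for f in applicable
            if f.beta * sign > 0 and (not require_significance or f.pval < alpha)
        ]
        if len(agreeing) >= 3:
            detail["agreeing_methods"] = [f.method for f in agreeing]
            detail["direction"] = "positive" if sign > 0 else "negative"
            return True, detail
    detail["agreeing_methods"] = []
    return False, detail


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the binary-outcome MR power calculation.

    n: total outcome sample size; case_fraction: cases/n; r2: variance
    of the exposure explained by the instruments; alpha: two-sided test
    size; power: target power.
    """

    n: float
    case_fraction: float
    r2: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError("n must be > 0")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError("r2 must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must be in (0, 1)")


def min_detectable_or(spec: PowerSpec) -> float:
    """Minimum detectable odds ratio per 1 SD of exposure.

    Strictly decreasing in n, r2 and K(1−K): more outcome information or
    stronger instruments let smaller effects be detected.
    """
    k = spec.case_fraction
    ncp_unit = spec.n * spec.r2 * k * (1.0 - k)
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_p = stats.norm.ppf(spec.power)
    beta_min = (z_a + z_p) / math.sqrt(ncp_unit)
    return math.exp(beta_min)


def _logit_intercept_for_prevalence(beta: float, k: float) -> float:
    """Intercept a0 with E[expit(a0 + beta·x)] = k for x ~ N(0, 1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / weights.sum()

    def prevalence(a0: float) -> float:
        return float(np.sum(weights * special.expit(a0 + beta * nodes))) - k

    lo, hi = -40.0, 40.0
    return float(optimize.brentq(prevalence, lo, hi, xtol=1e-12))


def simulate_power(
    spec: PowerSpec,
    or_value: float,
    n_reps: int = 1000,
    seed: Optional[int] = None,
    chunk: int = 100,
) -> float:
    """Simulation oracle: empirical power to detect ``or_value``.

    Per replicate, a genetic score g ~ N(0, r2) determines the exposure
    x = g + e with Var(x) = 1; the binary outcome is logistic in x with
    log-odds slope log(or_value) and intercept matched to the case
    fraction; the instrument–outcome association is tested with the
    logistic score test of y on g at level ``alpha``.  Returns the
    rejection fraction over ``n_reps`` replicates.
    """
    beta = math.log(or_value)
    n = int(spec.n)
    a0 = _logit_intercept_for_prevalence(beta, spec.case_fraction)
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    rng = np.random.default_rng(seed)
    sd_g = math.sqrt(spec.r2)
    sd_e = math.sqrt(1.0 - spec.r2)
    rejected = 0
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        g = sd_g * rng.standard_normal((b, n))
        x = g + sd_e * rng.standard_normal((b, n))
        p = special.expit(a0 + beta * x)
        y = (rng.random((b, n)) < p).astype(float)
        ybar = y.mean(axis=1, keepdims=True)
        gc = g - g.mean(axis=1, keepdims=True)
        u = np.sum(gc * (y - ybar), axis=1)
        v = (ybar[:, 0] * (1.0 - ybar[:, 0])) * np.sum(gc**2, axis=1)
        z = u / np.sqrt(v)
        rejected += int(np.sum(np.abs(z) > z_crit))
        done += b
    return rejected / n_reps
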