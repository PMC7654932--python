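"""End-to-end study workflow over an exposure × outcome grid.

For each pair: harmonize → four estimators (IVW random-effects, MR-Egger,
weighted median, MR-PRESSO) → heterogeneity/pleiotropy diagnostics →
leave-one-out and funnel tables → best-method selection and the
three-method causal call.  Emits per-pair JSON, one rendered TSV table
per outcome in the conventional layout (four method rows plus an Egger
intercept row per exposure, "NA" where PRESSO found no outliers, best
method flagged), a grid summary of best estimates, and a run manifest
with seeds, versions and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decide import DecisionReport, DecisionThresholds, causal_call, select_best
from .estimators import (
    EGGER,
    IVW_RE,
    PRESSO_CORRECTED,
    WEIGHTED_MEDIAN,
    MRFitResult,
    funnel_data,
    ivw_random_effects,
    leave_one_out,
    mr_egger,
    weighted_median,
)
from .harmonize import HarmonizedSet, harmonize, orient_positive_exposure
from .presso import PressoReport, presso
from .sumstats import TraitPanel, read_panel

__all__ = [
    "RunConfig",
    "PairResult",
    "RunBundle",
    "analyze_pair",
    "run",
    "exclusion_rerun",
    "render_outcome_table",
]

METHOD_LABELS = {
    IVW_RE: "Inverse-variance weighted",
    EGGER: "MR-Egger",
    WEIGHTED_MEDIAN: "Weighted median",
    PRESSO_CORRECTED: "MR-PRESSO",
}


@dataclass
class RunConfig:
    """Declarative description of a full analysis run."""

    exposures: list[dict]  # name, path, optionally sd_mmol_per_l
    outcomes: list[dict]  # name, path, optionally trait_type/case_count/total_n
    output_dir: Optional[str] = None
    methods: tuple = (IVW_RE, EGGER, WEIGHTED_MEDIAN, PRESSO_CORRECTED)
    palindrome_policy: str = "infer_by_frequency"
    ambiguity_band: float = 0.08
    thresholds: DecisionThresholds = field(default_factory=DecisionThresholds)
    alpha: float = 0.05
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seeds: dict = field(default_factory=lambda: {"weighted_median": 1, "presso": 2})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not raw.get("exposures") or not raw.get("outcomes"):
            raise ValueError("config must list at least one exposure and one outcome")
        thr = raw.pop("thresholds", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if thr:
            cfg.thresholds = DecisionThresholds(**thr)
        cfg.methods = tuple(cfg.methods)
        return cfg

    def digest(self) -> str:
        payload = {
            "exposures": self.exposures,
            "outcomes": self.outcomes,
            "methods": list(self.methods),
            "palindrome_policy": self.palindrome_policy,
            "ambiguity_band": self.ambiguity_band,
            "thresholds": vars(self.thresholds),
            "alpha": self.alpha,
            "n_boot": self.n_boot,
            "presso_n_sim": self.presso_n_sim,
            "seeds": self.seeds,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class PairResult:
    """Everything computed for one exposure–outcome pair."""

    exposure: str
    outcome: str
    hset: HarmonizedSet
    fits: dict[str, MRFitResult]
    presso_report: PressoReport
    loo: list
    funnel: pd.DataFrame
    decision: DecisionReport

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "n_variants": len(self.hset),
            "harmonization_audit": dict(self.hset.audit),
            "fits": {m: f.to_dict() for m, f in self.fits.items()},
            "presso": self.presso_report.to_dict(),
            "leave_one_out": [
                {"excluded": vid, "beta": fit.beta, "se": fit.se} for vid, fit in self.loo
            ],
            "decision": self.decision.to_dict(),
        }


@dataclass
class RunBundle:
    pairs: list[PairResult]
    tables: dict[str, pd.DataFrame]  # per outcome
    summary: pd.DataFrame
    manifest: dict
    failures: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def analyze_pair(
    exposure: TraitPanel,
    outcome: TraitPanel,
    palindrome_policy: str = "infer_by_frequency",
    ambiguity_band: float = 0.08,
    thresholds: DecisionThresholds = DecisionThresholds(),
    alpha: float = 0.05,
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
    wm_seed: int = 1,
    presso_seed: int = 2,
) -> PairResult:
    """Run the full univariable analysis for one exposure–outcome pair."""
    import warnings

    hset = harmonize(
        exposure, outcome, palindrome_policy=palindrome_policy, ambiguity_band=ambiguity_band
    )
    hset = orient_positive_exposure(hset)
    if len(hset) < 10:
        warnings.warn(
            f"{exposure.trait_name}->{outcome.trait_name}: only {len(hset)} instruments; "
            "estimates may be unstable",
            stacklevel=2,
        )
    ivw = ivw_random_effects(hset)
    egger = mr_egger(hset)
    wm = weighted_median(hset, n_boot=n_boot, seed=wm_seed)
    rep = presso(hset, n_sim=presso_n_sim, seed=presso_seed)
    if rep.applicable and rep.corrected is not None:
        presso_fit = rep.corrected
    else:
        presso_fit = MRFitResult(
            method=PRESSO_CORRECTED,
            n_variants=len(hset),
            applicable=False,
            extras={"reason": rep.reason or "no significant outliers"},
        )
    fits = {IVW_RE: ivw, EGGER: egger, WEIGHTED_MEDIAN: wm, PRESSO_CORRECTED: presso_fit}
    loo = leave_one_out(hset) if len(hset) >= 3 else []
    funnel = funnel_data(hset)
    q_p = ivw.extras.get("Q_p", math.nan)
    icp = egger.extras.get("intercept_p", math.nan)
    selected = select_best(q_p, icp, rep.outliers_found, thresholds)
    if not fits[selected].applicable:  # e.g. too few variants for the selected method
        selected = IVW_RE
    verdict, agreement = causal_call(list(fits.values()), alpha=alpha)
    decision = DecisionReport(
        exposure=exposure.trait_name,
        outcome=outcome.trait_name,
        q_p=q_p,
        intercept_p=icp,
        outliers_found=rep.outliers_found,
        selected_method=selected,
        causal=verdict,
        agreement=agreement,
    )
    return PairResult(
        exposure=exposure.trait_name,
        outcome=outcome.trait_name,
        hset=hset,
        fits=fits,
        presso_report=rep,
        loo=loo,
        funnel=funnel,
        decision=decision,
    )


def _fmt_p(p: float, digits: int = 2) -> str:
    if isinstance(p, float) and math.isnan(p):
        return "NA"
    if p < 0.001:
        return "<0.001"
    return f"{p:.{digits}g}"


def render_outcome_table(pairs: Sequence[PairResult]) -> pd.DataFrame:
    """Rendered per-outcome table: 4 method rows + intercept row per exposure.

    ORs to 2 decimals; p below 0.001 printed "<0.001"; PRESSO row "NA"
    when no outliers were flagged; the selected best method marked.
    """
    rows = []
    for pr in pairs:
        ivw = pr.fits[IVW_RE]
        for method in (IVW_RE, EGGER, WEIGHTED_MEDIAN, PRESSO_CORRECTED):
            fit = pr.fits[method]
            first = method == IVW_RE
            if fit.applicable:
                cells = {
                    "odds_ratio": f"{fit.or_:.2f}",
                    "ci_low": f"{fit.or_low:.2f}",
                    "ci_high": f"{fit.or_high:.2f}",
                    "p_value": _fmt_p(fit.pval),
                }
            else:
                cells = {k: "NA" for k in ("odds_ratio", "ci_low", "ci_high", "p_value")}
            rows.append(
                {
                    "method": METHOD_LABELS[method],
                    "exposure": pr.exposure,
                    **cells,
                    "p_heterogeneity": _fmt_p(ivw.extras.get("Q_p", math.nan)) if first else "",
                    "q_statistic": f"{ivw.extras.get('Q', math.nan):.1f}" if first else "",
                    "best": "*" if method == pr.decision.selected_method else "",
                }
            )
        egger = pr.fits[EGGER]
        if egger.applicable:
            rows.append(
                {
                    "method": "MR-Egger intercept",
                    "exposure": pr.exposure,
                    "odds_ratio": f"{egger.extras['intercept']:.3f}",
                    "ci_low": f"{egger.extras['intercept_ci_low']:.3f}",
                    "ci_high": f"{egger.extras['intercept_ci_high']:.3f}",
                    "p_value": _fmt_p(egger.extras["intercept_p"]),
                    "p_heterogeneity": "",
                    "q_statistic": "",
                    "best": "",
                }
            )
    return pd.DataFrame(rows)


def _summary_frame(pairs: Sequence[PairResult]) -> pd.DataFrame:
    rows = []
    for pr in pairs:
        fit = pr.fits[pr.decision.selected_method]
        rows.append(
            {
                "exposure": pr.exposure,
                "outcome": pr.outcome,
                "best_method": pr.decision.selected_method,
                "odds_ratio": fit.or_ if fit.applicable else math.nan,
                "or_low": fit.or_low if fit.applicable else math.nan,
                "or_high": fit.or_high if fit.applicable else math.nan,
                "p_value": fit.pval,
                "causal_call": pr.decision.to_dict()["causal_call"],
            }
        )
    return pd.DataFrame(rows)


def _load_panels(entries: Sequence[dict], kind: str) -> list[TraitPanel]:
    panels = []
    for e in entries:
        path = Path(e["path"])
        if not path.exists():
            raise FileNotFoundError(f"{kind} file not found: {path}")
        panels.append(
            read_panel(
                path,
                trait_name=e.get("name", path.stem),
                trait_type=e.get("trait_type", "continuous" if kind == "exposure" else "binary"),
                sd_mmol_per_l=e.get("sd_mmol_per_l"),
            )
        )
    return panels


def run(
    config: RunConfig,
    exposure_panels: Optional[Sequence[TraitPanel]] = None,
    outcome_panels: Optional[Sequence[TraitPanel]] = None,
) -> RunBundle:
    """Execute the whole grid; per-pair failures are isolated and reported.

    Panels may be passed in memory (overriding the config paths), which
    is how the simulated-data workflow and the sensitivity re-runs use
    this entry point.
    """
    exposures = list(exposure_panels) if exposure_panels is not None else _load_panels(
        config.exposures, "exposure"
    )
    outcomes = list(outcome_panels) if outcome_panels is not None else _load_panels(
        config.outcomes, "outcome"
    )
    pairs: list[PairResult] = []
    failures: list[dict] = []
    for out_panel in outcomes:
        for exp_panel in exposures:
            try:
                pairs.append(
                    analyze_pair(
                        exp_panel,
                        out_panel,
                        palindrome_policy=config.palindrome_policy,
                        ambiguity_band=config.ambiguity_band,
                        thresholds=config.thresholds,
                        alpha=config.alpha,
                        n_boot=config.n_boot,
                        presso_n_sim=config.presso_n_sim,
                        wm_seed=config.seeds.get("weighted_median", 1),
                        presso_seed=config.seeds.get("presso", 2),
                    )
                )
            except Exception as exc:  # isolate per-pair failures
                failures.append(
                    {
                        "exposure": exp_panel.trait_name,
                        "outcome": out_panel.trait_name,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                )
    tables = {}
    for out_panel in outcomes:
        sub = [p for p in pairs if p.outcome == out_panel.trait_name]
        if sub:
            tables[out_panel.trait_name] = render_outcome_table(sub)
    summary = _summary_frame(pairs)
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_hash": config.digest(),
        "seeds": dict(config.seeds),
        "n_pairs": len(pairs),
        "n_failures": len(failures),
        "pair_variant_counts": {f"{p.exposure}|{p.outcome}": len(p.hset) for p in pairs},
    }
    bundle = RunBundle(
        pairs=pairs, tables=tables, summary=summary, manifest=manifest, failures=failures
    )
    if config.output_dir:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _write_bundle(bundle: RunBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for pr in bundle.pairs:
        stem = f"{pr.exposure}__{pr.outcome}"
        with open(outdir / f"{stem}.json", "w") as fh:
            json.dump(pr.to_dict(), fh, indent=2, default=_json_default)
        pr.hset.to_frame().to_csv(outdir / f"{stem}.harmonized.tsv", sep="\t", index=False)
        pr.funnel.to_csv(outdir / f"{stem}.funnel.tsv", sep="\t", index=False)
    for outcome, table in bundle.tables.items():
        table.to_csv(outdir / f"table_{outcome}.tsv", sep="\t", index=False)
    bundle.summary.to_csv(outdir / "summary_best_estimates.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)
    if bundle.failures:
        with open(outdir / "failures.json", "w") as fh:
            json.dump(bundle.failures, fh, indent=2)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def exclusion_rerun(
    config: RunConfig,
    excluded_outcome_panel: TraitPanel,
    exposure_panels: Optional[Sequence[TraitPanel]] = None,
    outcome_panels: Optional[Sequence[TraitPanel]] = None,
) -> tuple[RunBundle, pd.DataFrame]:
    """Sensitivity re-run on a substituted outcome panel, diffed per method.

    The paper-style exclusions (e.g. removing participants with
    myocardial infarction / heart failure, or restricting cases) are the
    same computation on a re-estimated outcome panel; the diff reports
    the per-method change in the causal estimate for the matching
    outcome name.
    """
    primary = run(config, exposure_panels=exposure_panels, outcome_panels=outcome_panels)
    substituted = run(
        config,
        exposure_panels=exposure_panels,
        outcome_panels=[excluded_outcome_panel],
    )
    rows = []
    for sub_pr in substituted.pairs:
        base = [
            p
            for p in primary.pairs
            if p.exposure == sub_pr.exposure and p.outcome == excluded_outcome_panel.trait_name
        ]
        if not base:
            continue
        base_pr = base[0]
        for method, fit in sub_pr.fits.items():
            bfit = base_pr.fits[method]
            if fit.applicable and bfit.applicable:
                rows.append(
                    {
                        "exposure": sub_pr.exposure,
                        "method": method,
                        "beta_primary": bfit.beta,
                        "beta_substituted": fit.beta,
                        "delta_beta": fit.beta - bfit.beta,
                        "se_primary": bfit.se,
                    }
                )
    return substituted, pd.DataFrame(rows)
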