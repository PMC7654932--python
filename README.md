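# mrvalve

Two-sample Mendelian randomization (MR) from GWAS summary statistics, built
for lipid → valvular-heart-disease analyses: harmonization of exposure and
outcome panels, four causal estimators with heterogeneity and pleiotropy
diagnostics, multivariable MR for mutually-adjusted direct effects,
evidence-synthesis rules (best-method selection and a three-method causal
call), binary-outcome power calculation, and a ground-truth simulator of
two-sample summary panels.

## Who this is for

Genetic epidemiologists who have per-variant association estimates for one
or more exposures (e.g. LDL-cholesterol in SD units from a lipid
consortium) and a binary outcome (e.g. aortic stenosis log-odds from a
biobank GWAS), in non-overlapping samples, and want the full
estimate–diagnose–decide workflow those studies report.

## The model

Each instrument j gives a Wald ratio r_j = Γ̂_j/γ̂_j (outcome log-odds per
1 SD exposure). The package fits:

- **IVW** (multiplicative random effects): β̂ = Σw_j r_j/Σw_j with
  w_j = γ̂_j²/σ_Γj²; SE inflated by max(1, √(Q/(J−1))) with Cochran's Q;
- **MR-Egger**: weighted regression of Γ̂ on γ̂ with intercept (the mean
  directional-pleiotropy estimate), t-based inference on J−2 df;
- **Weighted median**: the 50%-cumulative-weight quantile of ordered
  ratios, parametric-bootstrap SE; consistent while ≥ 50% of weight is
  valid;
- **MR-PRESSO**: simulation-based global heterogeneity test, per-variant
  outlier test (Bonferroni), outlier-corrected IVW and distortion test;
- **Multivariable IVW**: no-intercept weighted multiple regression of Γ̂ on
  the J×K exposure-effect matrix, giving direct effects per exposure.

A configurable decision rule then selects the best estimate from the
diagnostic pattern (pleiotropy → Egger; strong heterogeneity with outliers
→ PRESSO-corrected; moderate heterogeneity → weighted median; else IVW) and
an association is called causal when ≥ 3 methods agree in direction with
p < 0.05. Details, defaults and limitations: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a study-scale dataset (57 instruments explaining 12% of exposure
variance, true OR 1.5 per SD, biobank-scale binary outcome) and run the
full analysis:

```python
import mrvalve as mv

exposure, outcome, truth = mv.simulate_two_sample(mv.preset("ldl_as_like"))
pair = mv.analyze_pair(exposure, outcome, wm_seed=1, presso_seed=2)

ivw = pair.fits["IVW_RE"]
print(f"IVW OR {ivw.or_:.2f} (95% CI {ivw.or_low:.2f}-{ivw.or_high:.2f}), "
      f"p={ivw.pval:.2g}, Q_p={ivw.extras['Q_p']:.2f}")
print(f"Egger intercept {pair.fits['EGGER'].extras['intercept']:.4f} "
      f"(p={pair.fits['EGGER'].extras['intercept_p']:.2f})")
print("best method:", pair.decision.selected_method,
      "| causal call:", pair.decision.to_dict()["causal_call"])
```

prints

```
IVW OR 1.36 (95% CI 1.19-1.56), p=6.2e-06, Q_p=0.22
Egger intercept 0.0017 (p=0.86)
best method: IVW_RE | causal call: causal
```

i.e. the estimated odds ratio per 1 SD of exposure is 1.36 (truth 1.5, well
inside the CI), there is no excess heterogeneity (Q_p = 0.22) and no
directional pleiotropy (intercept ≈ 0), so the rule keeps the efficient IVW
estimate, and all methods agree the effect is causal.

The same workflow runs from the shell over an exposure × outcome grid:

```bash
mrvalve simulate --preset ldl_as_like --out-dir data/
mrvalve run --config run.yaml        # per-pair JSON + publication-layout TSV tables
mrvalve fit --exposure data/exposure.tsv --outcome data/outcome.tsv \
            --methods ivw,egger,median --seed 1
```

Power for a design: `min_detectable_or(PowerSpec(n=432_173,
case_fraction=1961/432_173, r2=0.12))` → **1.20**, the smallest odds ratio
detectable at 80% power and α = 0.05 at that outcome scale.

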