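# Methods

## Setting

`mrvalve` implements a complete two-sample Mendelian randomization (MR)
workflow for summary statistics, built around the design used in studies of
plasma lipids and valvular heart disease: exposure effects estimated in a
lipid-genetics consortium (continuous traits, SD units) and outcome effects
estimated in a large biobank (binary disease status, log-odds), in
non-overlapping samples. Per variant j the inputs are the exposure effect
γ̂_j with standard error σ_γj and the outcome effect Γ̂_j with standard error
σ_Γj. The target is the causal log-odds effect β of a 1 SD exposure change.

## Instrument selection and harmonization

Instruments are filtered at genome-wide significance (default p < 5×10⁻⁸)
and then greedily distance-pruned per chromosome: the smallest-p variant is
kept and every variant strictly closer than the window (default 1 Mb) is
discarded, repeating until exhaustion. Ties on p break by (chromosome,
position, id) so the result is independent of row order. LD-based pruning
against a genotype reference panel is deliberately out of scope — consortium
instrument lists are published pre-pruned — so the distance rule is a
convenience, not a replacement.

Harmonization matches variants by id and aligns the outcome effect to the
exposure's effect allele: swapped allele labels negate the outcome beta and
complement the frequency; strand-complement codings are resolved first when
the allele pair is unambiguous. Palindromic variants (A/T, C/G) cannot be
strand-resolved from labels. Under the default `infer_by_frequency` policy a
palindromic variant is kept when both panels report an effect-allele
frequency outside 0.5 ± 0.08 (the conventional ambiguity band), with
orientation inferred from whether the frequencies fall on the same side of
0.5; otherwise (or when frequency is missing) it is dropped. Every input
variant receives an audit action, so attrition is fully observable.

MR-Egger's estimate depends on allele orientation, so the pipeline orients
every variant to its exposure-increasing allele (negating both betas, which
leaves all Wald ratios unchanged) before estimation. Variants with exactly
zero exposure effect have undefined ratios and are excluded with a warning.

## Estimators

*IVW (multiplicative random effects).* With weights w_j = γ̂_j²/σ_Γj² the
estimate is β̂ = Σw_j r_j / Σw_j for Wald ratios r_j = Γ̂_j/γ̂_j —
equivalently the 1/σ_Γ²-weighted regression of Γ̂ on γ̂ through the origin.
Cochran's Q = Σw_j(r_j − β̂)² on J−1 df measures heterogeneity, and the
fixed-effect SE (Σw)^(−1/2) is inflated by max(1, √(Q/(J−1))). The
multiplicative (rather than additive) random-effects flavour was chosen
because it is the convention of the standard MR analysis platforms; it never
deflates the SE below the fixed-effect value. A single variant reduces to
its Wald ratio. p-values are normal-based.

*MR-Egger.* The same weighted regression with a free intercept, after
positive-exposure orientation. The slope is the causal estimate (consistent
under InSIDE — instrument strength independent of direct effects) and the
intercept estimates mean directional pleiotropy. Both SEs carry the
max(1, √(RSS_w/(J−2))) inflation; tests and confidence intervals use t with
J−2 df rather than normal quantiles, because Egger's effective sample size
is the instrument count and J is often a few dozen.

*Weighted median.* Ratios are sorted, weights (the IVW weights) normalized,
and the estimate interpolates ratio against the cumulative-midpoint weight
s_j = Σ_{k≤j}w'_k − w'_j/2 at s = 0.5. It is consistent when at least half
the total weight comes from valid instruments. The SE is the standard
deviation over parametric-bootstrap replicates (default 1000) that perturb
each observed (γ̂_j, Γ̂_j) by its Gaussian SEs; the CLI requires an explicit
seed so results are reproducible.

*MR-PRESSO.* The observed residual sum of squares RSS = Σ_j(Γ̂_j −
β̂_{−j}γ̂_j)²/σ_Γj², with β̂_{−j} the leave-one-out IVW slope, is compared
against a parametric null: γ*_j ~ N(γ̂_j, σ_γj²), Γ*_j ~ N(β̂_{−j}γ̂_j,
σ_Γj²), recomputing the leave-one-out slopes on each simulated panel
(default 1000 simulations). Empirical p-values use the add-one estimator
(1 + #{sim ≥ obs})/(n_sim + 1), so they are never zero. Per-variant residual
contributions are tested against their own simulated distributions with a
Bonferroni threshold α/J (α = 0.05 default); flagged outliers are removed
and IVW re-estimated, and a distortion test compares the observed relative
shift of the estimate against shifts from removing random subsets of the
same size (an independent child seed stream, so each component reproduces
separately). With no outliers the corrected estimate and distortion p are
absent and render as "NA (no significant outliers)", matching the reporting
convention of the study tables. The procedure needs ≥ 4 variants and
returns a distinguishable not-applicable result below that.

*Diagnostics.* Leave-one-out IVW re-estimation flags influential variants;
the funnel table (ratio against precision |γ̂_j|/σ_Γj) is exported plot-ready
rather than rendered.

## Multivariable MR

With K exposures the union of instruments (restricted to variants present
in every panel and the outcome, each drop audited) forms a J×K effect
matrix, aligned to the first panel's allele coding. Direct effects come
from the no-intercept weighted (1/σ_Γ²) multiple regression of Γ̂ on the K
columns, with SEs inflated by max(1, √(Q_mv/(J−K))). K = 1 reproduces
univariable IVW exactly. A rank-deficient matrix raises a collinearity
error naming the offending exposures; conditionally weak instruments
(approximate conditional F < 10) produce a warning only, never a hard
filter. Union rather than intersection instruments is standard multivariable
MR practice and keeps the instrument count well above K.

## Method selection and the causal call

Studies of this design pick one "best" estimate per exposure–outcome pair
from the diagnostic pattern. The default rule is a reconstruction, encoded
as configuration so alternative readings can be swapped in without code
changes:

1. Egger intercept p < 0.05 (directional pleiotropy) → MR-Egger;
2. else heterogeneity p < 0.001 with PRESSO outliers → PRESSO-corrected;
3. else heterogeneity p ≤ 0.05 (inclusive boundary) → weighted median;
4. else → IVW.

These thresholds reproduce all 12 published method selections implied by
the printed heterogeneity p, intercept p and PRESSO-NA fields of the
lipid–valve-disease tables (4 exposures × 3 outcomes); the inclusive ≤ on
the 0.05 boundary is forced by a printed p of exactly 0.05 selecting the
weighted median. An association is called causal when at least three
applicable methods agree in direction and each is significant at α = 0.05;
a direction-only mode is provided because the source wording ("consistent
results") is looser than any single operationalization.

## Power

The minimum detectable odds ratio for a binary outcome uses the asymptotic
noncentrality approximation: β_min = (z_{1−α/2} + z_{power})/√(n·R²·K(1−K))
with n the outcome sample size, K the case fraction and R² the variance of
the exposure explained by the instruments; the returned OR is exp(β_min).
A simulation oracle validates it: the genetic score g ~ N(0, R²) drives the
exposure x = g + e (Var x = 1), the outcome is logistic in x with the
intercept solved (Gauss–Hermite quadrature + Brent root-finding) to match
K, and the score test of outcome on g measures empirical power. Across case
fractions 0.004–0.05 the approximation and oracle agree within 3 percentage
points; the mild rare-disease approximation error grows with large effects
and common outcomes. At the study's outcome scale (432 173 participants,
1961 cases, R² = 0.12) the formula gives a minimum detectable OR of 1.20 at
80% power, pinned as a regression value after oracle validation.

## Synthetic data generator

The generator emulates summary statistics, not individual-level data: MAFs
are uniform on (0.05, 0.5]; exposure effects are half-normal (every effect
allele is exposure-increasing) and deterministically rescaled so
Σ2p_j(1−p_j)γ_j² equals the target R² (default 0.12, the order of variance
explained by published lipid instrument panels); SEs follow the standard
GWAS scalings σ_γj = (n_exp·2p_j(1−p_j))^(−1/2) and, for the binary
outcome, the score-test approximation σ_Γj = (n_out·K(1−K)·2p_j(1−p_j))^(−1/2).
Outcome effects are Γ_j = βγ_j + α_j with α_j = 0 for valid instruments and
α_j ~ N(μ_α, σ_α²) for the invalid fraction; setting the InSIDE-violation
weight λ adds λγ_j to α_j so Egger's failure mode can be exercised. Observed
effects are drawn independently per panel (two-sample independence). Optional
corruption swaps allele labels (negating beta, complementing the frequency)
or flips strands in the outcome panel, both exactly invertible by
harmonization for non-palindromic variants, with ground-truth annotations.

Defaults mirror the motivating study's scale: 57 instruments, exposure GWAS
of 83 198, outcome panel of 432 173 with case fraction 1961/432 173.
Presets: `ldl_as_like` (true OR 1.5 per SD), `null` (true OR 1),
`directional_pleiotropy`, and `mv_lipids` (three exposures, equicorrelation
0.5, only the first causal). The directional-pleiotropy preset is a stress
regime chosen by a design power analysis: 100 instruments, 40% invalid with
α_j ~ N(0.3, 0.05²) — pleiotropic outcome effects roughly seven times the
outcome-panel SE — the scale at which directional pleiotropy is unambiguous
(Egger intercept power ≈ 0.9) and the weighted median's robustness
advantage over IVW is clear. With weaker pleiotropy both effects shade
toward the null gradually; the preset is not meant to represent typical
real-trait pleiotropy.

What the generator does not emulate: LD between instruments (independence
matches r² < 0.01 selection), covariate-adjusted logistic GWAS machinery
(population structure, relatedness), allele-frequency differences between
panels, winner's-curse in instrument discovery, and sample overlap. Passing
recovery tests therefore demonstrates correctness of the estimators under
the two-sample summary-data model, not robustness to those real-data
complications.

## Numerical choices and edge cases

- Normal-based CIs use the exact 0.975 quantile (1.95996…); Egger uses t.
- Weighted regressions are solved in closed form (weighted normal
  equations); an independent generic WLS implementation is used as the
  oracle in tests, to 1e-10 relative agreement.
- p-values are floored at the smallest positive double to keep them in
  (0, 1]; rendered tables truncate below 0.001 to "<0.001".
- Q = 0 (all ratios equal) gives no inflation; J = 1 IVW is the Wald ratio;
  J < 3 (Egger, median) and J < 4 (PRESSO) return explicit not-applicable
  results rather than raising.
- Bootstrap replicates that hit an exactly-zero perturbed exposure effect
  replace it with the smallest positive double (probability-zero event,
  keeps ratios finite).
- Empirical p-values are add-one, hence bounded below by 1/(n_sim+1).
- Seeds: all stochastic components take explicit seeds; PRESSO splits its
  seed into independent child streams for the global/outlier simulation and
  the distortion test.

## Known limitations

- The method-selection rule is a reconstruction from printed results, not a
  transcription of the original flowchart; the rule engine is configurable
  for that reason.
- Wald-ratio SEs are first-order only (no second-order delta term), chosen
  to match the weights under which IVW equals weighted regression.
- No LD-aware (correlated-instrument) IVW, no mode-based or robust/penalized
  estimators, no MVMR-Egger/median, no multi-exposure PRESSO variant.
- Distance pruning is not LD pruning; inputs are assumed pre-pruned.
- Positions are treated as opaque coordinates; no genome-build handling.
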