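# Methods

`lpamr` implements two complementary analyses of the relationship between
PCSK9 and lipoprotein(a): aggregate association statistics for a biallelic
*PCSK9* variant (E670G, rs505151) against a three-category Lp(a) risk
outcome, and a two-sample Mendelian randomization (MR) of plasma PCSK9
levels on inverse-rank-normalised Lp(a) using six *PCSK9*-locus variants as
instruments. This note records the models, the conventions they depend on,
the synthetic-data design, and the choices made where the design was
genuinely open.

## Two-sample MR model

Let β̂X_j ± σX_j and β̂Y_j ± σY_j be the per-allele associations of
instrument j with the exposure (plasma PCSK9, arbitrary GWAS units) and the
outcome (irnt Lp(a), SD units), estimated in non-overlapping samples. Each
instrument's Wald ratio is r_j = β̂Y_j / β̂X_j with first-order
delta-method standard error s_j = σY_j / |β̂X_j| (the second-order term is
deliberately omitted — the per-SNP SEs then agree with standard two-sample
IV output) and inverse-variance weight w_j = s_j⁻².

**Harmonization.** Panels are joined on rsID after expressing both on a
common effect allele: swapped allele labels negate the outcome beta;
strand-complement relabelling (A↔T, C↔G) is resolved before comparison.
Strand-ambiguous (A/T, C/G) variants are dropped by default; they can be
kept as-is, or resolved by comparing effect-allele frequencies against 0.5
when frequencies are available. Incompatible variants are excluded and
logged rather than silently altered.

**IVW.** β̂ = Σ w_j r_j / Σ w_j, identical to weighted regression of β̂Y on
β̂X through the origin with weights σY⁻². The fixed-effect SE is
(Σ w_j)^−1/2; the default multiplicative random-effects convention scales
it by max(1, √(Q/(L−1))) where Q is Cochran's Q, so the SE is never
deflated below the fixed-effect value when the instruments are
under-dispersed. Inference is on the standard normal.

**MR-Egger.** Instruments are oriented so β̂X_j ≥ 0 (the intercept is
orientation-dependent; this is the established convention), then weighted
least squares of β̂Y on β̂X with intercept and weights σY⁻². The intercept
estimates the mean direct (pleiotropic) effect per instrument; the slope is
a consistent causal estimate under the InSIDE assumption. Coefficient SEs
use the same multiplicative floor (residual scale never below 1), and
inference uses t on L−2 degrees of freedom. These two conventions — normal
for IVW, t(L−2) with an SE floor for Egger — are exactly what is needed to
reconcile a published β/SE pair with its p-value on the platform this
analysis style comes from.

**Weighted median.** Order the ratios ascending, normalise the weights,
and form standardised mid-cumulative weights p_j = (S_j − w_j/2)/S_L; the
estimate interpolates the ratio linearly at p = 0.5. It is consistent when
instruments carrying ≥ 50% of the weight are valid. Its SE is a parametric
bootstrap: β̂X_j and β̂Y_j are resampled from normal distributions with
their reported SEs (default 1000 replicates; the seed is a required
argument and is echoed into provenance output).

**Heterogeneity.** Cochran's Q = Σ w_j (r_j − β̂_IVW)² on L−1 df; Rücker's
Q′ is the weighted residual sum of squares of the Egger fit on L−2 df.
I² = max(0, (Q−df)/Q).

**Instrument selection.** Candidates must pass a p-value threshold
(default 5 × 10⁻⁷) and optionally a replication list; LD pruning is greedy
by ascending p-value (ties broken lexicographically by rsID), keeping a
variant only if its r² with every already-kept variant is below the
threshold (default 0.5) in a user-supplied LD matrix. The variance
explained by a panel is approximated as Σ 2f_j(1−f_j)β_j² over the
phenotype variance, ignoring LD.

### Numerical notes and known limitations

* With L = 6 instruments the Egger t(4) intervals are wide; this is
  inherent to the method, not a numerical issue.
* Recomputing published tables from their own printed coefficients (2–3
  significant figures) moves third-digit results; comparisons therefore use
  2% relative tolerance, and the weighted-median point estimate — which
  sits near an interpolation boundary between adjacent ratios — is held to
  the interval [0.060, 0.070] rather than the printed 0.06628.
* The published Egger intercept of −0.034 is inconsistent with the
  published per-SNP coefficients, which yield −0.0034 (p ≈ 0.30, matching
  the published p of 0.299); the package reports the computed value.
* All ratio-based estimators carry finite-sample attenuation from
  estimation error in β̂X ("weak-instrument" or NOME bias). For IVW and the
  weighted median this is ≈ Σσ²X/Σβ²X (a fraction of a percent at
  genome-wide-significant instrument strength); for the Egger slope it is
  ≈ θ(1 − I²_GX) with I²_GX = Var(βX)/(Var(βX) + mean σ²X), about 7% of θ
  under the default simulation conditions. The estimator-recovery test
  suite makes this visible: the Egger mean check at the 2-MC-SE resolution
  documents the attenuation rather than ideal unbiasedness.

## Association model

Lp(a) risk strata follow the clinical convention: low < 9.4 mg/dL, average
9.4–30 mg/dL (closed interval), high > 30 mg/dL (hyperlipoproteinemia(a)).
Boundary values are vanishingly rare in continuous data, so the closure
convention is immaterial in practice.

* **Allele statistics** per stratum: G count = AG + 2·GG, frequency over
  2n. Carrier analyses pool AG with GG (a single GG subject in the
  motivating cohort); the 3×3 genotype test keeps GG separate.
* **Hardy–Weinberg**: 1-df Pearson goodness of fit against p², 2pq, q²
  expectations without continuity correction, or an exact test that
  enumerates all heterozygote counts compatible with the observed allele
  counts and sums the probabilities of outcomes no more probable than the
  observed one.
* **Independence tests**: Pearson chi-square without Yates correction (the
  correction is deliberately off by default — it is what reproduces the
  published 0.011/0.010/0.044 p-values from the count table).
* **Crude odds ratios**: 2×2 cross-products with Woolf log-scale Wald 95%
  CIs; an optional Haldane +0.5 handles empty cells and is required
  explicitly rather than applied silently.
* **Multinomial logit**: baseline-category model with K−1 coefficient
  blocks, maximised by Newton–Raphson on the exact stacked score and
  Fisher information with step-halving (the log-likelihood is
  non-decreasing by construction), a small ridge on a singular information
  matrix (logged), divergence detection for separation (|coef| > 30 on the
  log-odds scale), and Wald ORs/CIs. On aggregate one-binary-covariate
  data the fit is saturated and reproduces the contingency cross-products
  exactly, which the tests exploit as an oracle; an independent
  implementation (statsmodels MNLogit) is used as a cross-check only.
* **Summary ANOVA / t-tests**: computed from (n, mean, SD) triplets, equal
  to the textbook statistics on any raw data with those moments.
  Triglycerides are log-transformed (natural log) before parametric
  modelling; reported means stay on the raw scale.
* **Friedewald LDL**: TC − HDL − TG/5 (mg/dL), flagged invalid above
  TG = 400 mg/dL (standard clinical bound).
* **Power**: Monte-Carlo rejection rate of the two-sided Wald test on the
  carrier log-odds coefficient in a binary logit of category membership on
  carrier status. With one binary covariate the model is saturated, so the
  Wald statistic is the 2×2 log cross-product OR over its Woolf SE, which
  makes 10⁴ replicates essentially instant. The non-carrier outcome
  probability is solved (Brent) so the requested marginal prevalence and
  carrier OR hold simultaneously. The reference scenario (n = 614, carrier
  frequency 11.9%, prevalence 38%, OR 0.5, α = 0.05) lands in the broad
  vicinity of the published 68%; exact reproduction of the G*Power
  algorithm is out of scope.

## Synthetic data

**Cohort generator.** Genotypes are Hardy–Weinberg at a configurable
G-allele frequency (default 0.06). The risk category comes from a
three-category logit: non-carrier probabilities default to
(0.405, 0.392, 0.203) — the AA column of the observed genotype table — and
carriers' average/high odds are multiplied by the carrier ORs (default
0.5, 0.4), which together reproduce the observed 262/233/119 marginal
split at n = 614. Lp(a) is drawn from category-conditional log-normals
restricted to the category bounds by rejection (defaults: meanlog/sdlog of
1.60/0.55, 2.80/0.35 and 3.74/0.40 mg/dL for low/average/high), so the
classifier round-trips exactly; the marginal Lp(a) distribution is a
mixture calibrated to the category counts only, since no distributional
parameters beyond the counts are available. Covariates are independent
given the category (no between-category differences were observed for
them): age N(46, 10²), BMI N(24.3, 3.4²), male/smoker/
hypertension/diabetes Bernoulli(0.535/0.25/0.12/0.025), HDL N(55, 15²);
total cholesterol is category-conditional normal and triglycerides
category-conditional log-normal with moment-matched means/SDs; LDL derives
from Friedewald. All draws flow through one seeded generator, so a run is
bit-reproducible from its seed.

**Two-sample GWAS generator.** L instruments (default 6) with MAF uniform
on (0.2, 0.5) and true exposure effects uniform on (0.16, 0.5) expressed
on the canonical exposure-increasing allele. Estimated betas add normal
noise with SE = (2·maf·(1−maf)·n)^−1/2 at n_exp = 3290 and n_out = 27,386
(the two panels' sample sizes in the motivating design). The effect-size
range is calibrated so simulated instruments have z ≈ 5–16 — the strength
of a genome-wide-significant panel (p ≤ 5 × 10⁻⁷) under this SE formula;
note the formula assumes a unit-variance phenotype, so published SEs from
differently-scaled GWAS cannot be matched simultaneously with published
effect sizes. True outcome effects are θ·βX plus a per-SNP direct effect:
zero, N(0, sd) (balanced), or N(mean, sd) (directional, default mean 0.01,
sd 0.005), drawn independently of the instrument strength (InSIDE holds).
Directionality is defined relative to the exposure-increasing allele — the
orientation under which the Egger intercept estimates the mean direct
effect. Orientation randomness lives entirely in allele presentation
(either allele reported as the effect allele; outcome panels disagree with
the exposure presentation with probability 0.3 by default) so that
harmonization is exercised without changing any effect. Instruments are
independent by construction, matching the post-pruning setting; no LD,
winner's-curse selection, or sample overlap is simulated, so passing
recovery tests demonstrate estimator correctness under the stated model,
not robustness to those real-data complications.

**irnt.** The rank-based inverse-normal transform uses the Blom offset:
Φ⁻¹((r − 0.375)/(n + 0.25)) with average ranks for ties (the UK Biobank
convention; the source names the transform but not the offset).

## Problem sizes in the test suite

Estimator-recovery experiments use 500 replicates for mean-bias checks at
the 2-Monte-Carlo-SE resolution and 2000 replicates for the fixed-band CI
coverage proportion; multinomial OR recovery uses one n = 50,000 cohort;
power calibration uses 10⁴ replicates. These sizes make the stochastic
checks sharp enough to detect the failure modes they target while keeping
the default suite fast.
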