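# Methods

## Model

For a two-group comparison of log-scale expression values (log2 is
assumed throughout, so a log fold change of 1 is a two-fold expression
change; the scale is documented, not enforced), gene *j* is modelled by
the linear design (intercept, group-2 indicator). The coefficient of
interest is the log fold change β̂ⱼ = mean(group 2) − mean(group 1),
with design factor √(1/n₁ + 1/n₂) and pooled within-group residual
variance s²ⱼ on d = n₁ + n₂ − 2 degrees of freedom. Only this two-group
design is supported; general design matrices, array weights,
normalisation and trend/robust prior variants are out of scope.

### Variance prior

Gene variances share a conjugate scaled inverse-chi-square prior with
hyperparameters (d₀, s₀²); marginally s²ⱼ ~ s₀²·F(d, d₀). The
hyperparameters are estimated by moment matching on the log variances:
with eⱼ = log s²ⱼ − ψ(d/2) + log(d/2),

- excess dispersion v = var(e) − ψ′(d/2) > 0: d₀ = 2·ψ′⁻¹(v) and
  s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2));
- v ≤ 0: the variances are indistinguishable from a single common value,
  d₀ = ∞ and s₀² = mean(s²) (point-mass prior).

ψ′⁻¹ is computed by Newton iteration started at the asymptotic inverse
0.5 + 1/v, with the expansions 1/√v (v > 10⁷) and 1/v (v < 10⁻⁶) at the
extremes; convergence tolerance 1e-8 on the relative step. ψ′ is
strictly decreasing and convex on (0, ∞), so the iteration is monotone
and needs no bracketing.

Genes with s²ⱼ = 0 carry no log-variance information and are excluded
from the moment matching but retained in the analysis — shrinkage gives
them a positive posterior variance. If shrinkage is disabled (d₀ = 0)
a zero-variance gene has an undefined standard error and is rejected
with a diagnostic naming it. Non-finite input values are always an
error; nothing is imputed.

### Moderated statistics

The posterior variance is the convex combination
s²post,j = (d₀s₀² + d·s²ⱼ)/(d₀ + d) (the limit s₀² when d₀ = ∞), the
shrunken standard error s̃ⱼ = √s²post,j·√(1/n₁+1/n₂), and the moderated
tⱼ = β̂ⱼ/s̃ⱼ follows a t-distribution with f\* = d₀ + d degrees of
freedom under the null (standard normal when f\* = ∞). `prior_df`
overrides d₀; `prior_df=0` reproduces the classical pooled two-sample
t-test exactly, which the tests use as an oracle.

## Step-up adjustment and adjusted confidence levels

BH adjusted p-values are p̃₍ⱼ₎ = min_{k≥j} min(m·p₍ₖ₎/k, 1); BY
multiplies by C(m) = Σ 1/i and caps at 1. The cumulative-minimum
formulation automatically gives tied raw p-values identical adjusted
values (stable sort). Selection takes the largest k with
p₍ₖ₎ ≤ k·α/m (BH) or p₍ₖ₎ ≤ k·α/(m·C(m)) (BY), using ≤ at the
boundary, and sets α_adj = k·α/m resp. k·α/(m·C(m)); with no passing
index, k = 0 and α_adj = 0.

Intervals are β̂ⱼ ± t(1 − level/2, f\*)·s̃ⱼ at level α (unadjusted) or
α_adj (adjusted), built for **all** genes, not only selected ones — the
FCR guarantee concerns the selected subset, but the non-selected
intervals are informative and mirror typical interval-vs-rank displays.
Because |tⱼ| > t(1 − α_adj/2, f\*) iff p_raw,j < α_adj, an adjusted
interval excludes zero exactly when the gene is selected; at the
probability-zero boundary p_raw = α_adj the interval's significance
flag follows the p-value side (selected ⇒ excludes zero), one
consistent documented rule. When k = 0 no adjusted level exists; the
library returns a typed no-selection outcome rather than inventing a
fallback level, and the CLI emits the unadjusted-interval columns empty
with a logged warning.

## Relevance categories

Significance for categorisation is taken from the interval's
excludes-zero flag. Under adjusted intervals this coincides with the
adjusted p-value decision; under unadjusted intervals it deliberately
reproduces the mismatch between unadjusted intervals and adjusted
p-values that motivates the adjustment. Boundary ties at ρ (continuous
data: measure zero) use ≥ ρ for "exceeds" on the estimate and the upper
limit, and strictly > ρ for the lower limit in category D. The default
profile grid is ρ = 0.05 … 2.00 in steps of 0.05, covering the usual
working range for log2 fold changes (ρ = 0.5 and ρ = 1 being common
working thresholds). The "probably" wording of categories B/C is only
meaningful for symmetric estimator distributions; no symmetry
diagnostic is performed — a documented caveat.

Because an adjusted interval contains its unadjusted counterpart and
adjusted significance implies unadjusted zero-exclusion, the set of
category-D genes under adjusted intervals is a subset of that under
unadjusted intervals, for any dataset and any ρ.

## FCR and CCP

For known truth, FCR = #{selected genes whose interval misses the true
log fold change}/R and CCP = 1 − FCR, with R the number of selected
genes; both are defined as 0 when R = 0. Containment uses closed
intervals (an endpoint hit counts as covered). Estimating the FCR from
real data without known truth is out of scope.

## Simulation design

The generator emulates a typical two-group microarray comparison and is
fixed by design, not tuned: m = 200 genes, n₁ = n₂ = 10 samples per
group, drawn from N(μᵢ, Σ). Group 1 has mean zero; in group 2 a
uniformly re-drawn random 25% of genes (τ = 0.25) are all shifted by
the same log fold change β ∈ {0, 1, 2, 3, 4} (positive shifts only — a
single common β, no sign mixture). Σ is block-diagonal from the
Kronecker product of diag(0, 0.2, 0.4, 0.6, 0.8) with the all-ones
40×40 block, its diagonal then replaced by variances evenly spaced from
1 to 2 in gene order (the fixed-vector formulation implies gene order;
the assignment is not randomised). Each block c·J + diag(v − c) with
v ≥ 1 > c is positive definite; a config with a block covariance ≥ the
smallest variance is rejected. 1000 replicates per β at α = 0.05.
Replicates with an empty selection contribute FCR = CCP = 0 to the
means, per the definitions, and are not dropped.

Randomness derives from one root seed; each (effect size, replicate)
pair gets a deterministic child stream (the indices are mixed into the
seed sequence), so any replicate is reproducible in isolation and the
whole run is bitwise reproducible.

What the generator does *not* emulate: heavy-tailed or non-normal
expression noise, missing values, gene-specific sample sizes,
mixed-sign or heterogeneous effect sizes, and realistic gene-network
correlation beyond equicorrelated blocks. Passing simulation tests
therefore demonstrate the operating characteristics under the stated
multivariate-normal design, not performance guarantees on arbitrary
real data.

### Observed operating characteristics

The tests and `scripts/acceptance.py` compute, at the design above:
the mean FCR of BH-adjusted intervals under BH selection near the
nominal 5% (slightly conservative at β = 1, where selection is weak and
empty selections contribute zeros) and approximately flat in β; CCP
exactly 0 at β = 0 (duality forces every selected interval to exclude
the true value 0) and rising towards 1 − α as β grows; and the BY rate
well below both the nominal level and the paired BH rate. A reduced
robustness check (m = 1000, τ ∈ {0.10, 0.50}, 200 replicates) keeps the
BH FCR in [0.02, 0.07]. Per-replicate FCR(BY) ≤ FCR(BH) does **not**
hold pointwise — BY selects a subset of the BH genes, so its miss
fraction has a smaller denominator and is noisier — only the means are
ordered.

## Numerical and interface choices

- Interval and quantile arithmetic uses scipy's t and normal
  distributions; f\* = ∞ switches to the normal explicitly.
- Results tables are written with 12 significant digits, enough to
  round-trip the statistics through delimited text.
- Group labels map to groups 1/2 lexicographically unless a reference
  label is named, making CLI runs deterministic across label spellings.
- Problem sizes in the test suite (replicate counts, fuzz counts,
  matrix sizes) are chosen so the whole suite runs in well under a
  minute on one CPU while keeping Monte-Carlo standard errors far below
  the asserted tolerances; the full 1000-replicate grid is retained
  where the operating characteristics themselves are asserted.

## Known limitations

Two-group designs only; no normalisation or preprocessing; no
enrichment analysis downstream of the categories; no selective-inference
constructions shorter than the common-level adjusted intervals; FCR
control is demonstrated by simulation for the implemented design, and
the BY variant is the one with a dependence-robust theoretical
guarantee.
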