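# Methods

## Model and estimators

The package analyses two-sample summary-level MR: exposure and outcome
associations come from non-overlapping GWAS cohorts, and only per-SNP
effects, standard errors, allele identities, frequencies and sample sizes
are available. Writing γ<sub>j</sub> for SNP j's true effect on the
exposure, α<sub>j</sub> for any direct (pleiotropic) effect on the outcome,
and θ for the causal effect of interest, the working model is
β<sub>Yj</sub> = θγ<sub>j</sub> + α<sub>j</sub>, with β<sub>Xj</sub> and
β<sub>Yj</sub> observed with known sampling SEs. Outcomes are binary and
kept on the log-odds scale throughout; odds ratios and CIs are derived at
reporting time as exp(b) and exp(b ± 1.96·SE).

The five estimators and their validity conditions:

| estimator | assumption on invalid instruments |
|---|---|
| IVW (fixed-effect) | none invalid (all α = 0) |
| MR-Egger slope | InSIDE: α independent of γ; directional α allowed |
| weighted median | < 50% of weight on invalid instruments |
| simple / weighted mode | largest homogeneous group valid |

IVW is fixed-effect, matching its role as the primary test; a
multiplicative random-effects variant exists behind a flag but defaults
off. The Egger regression is weighted least squares with weights
1/σ<sub>Yj</sub>², after orienting every pair so β<sub>Xj</sub> ≥ 0 (the
standard identification convention; the orientation is a reporting choice,
not a data change). Egger SEs are inflated by the residual scale floored at
1 — i.e. SE = (X'WX)⁻¹<sup>½</sup> · max(σ̂, 1) — so underdispersed sets are
not rewarded.

p-value reference distributions follow the conventions of the reference
two-sample-MR implementations: standard normal for IVW, Wald ratios and the
weighted median; Student t with nSNP−2 df for the Egger slope and
intercept; t with nSNP−1 df for both mode estimators. (The published
summary table this package's acceptance checks recompute is only internally
consistent under exactly these conventions, which is how they were
confirmed.)

The weighted median interpolates the weighted empirical quantile function
(cumulative weight minus half of each SNP's own weight) at 0.5. Exactly
tied ratios are merged, weights summed, before interpolation; this makes
the estimate independent of tie ordering and exactly sign-equivariant, and
changes nothing for distinct ratios. The mode estimators maximize a
Gaussian kernel density over the ratios with bandwidth
φ·0.9·min(sd, MAD/0.6745)·n<sup>−1/5</sup> (φ = 1 by default; MAD scaled to
be sd-consistent). When the MAD is zero but the ratios are not all
identical — more than half the ratios tied — the sd alone sets the
bandwidth; fully identical ratios return the common value. The maximizer is
located from a 2048-point grid augmented with the ratio locations
themselves (kernels can be narrower than any fixed grid), then refined by
bounded scalar optimization.

Median and mode SEs come from a parametric bootstrap: β<sub>Xj</sub> and
β<sub>Yj</sub> are redrawn from normal distributions centred on the
observed effects with their reported SEs, ratios and weights are recomputed
each replicate, and the SE is the sd over replicates (default 1,000; the
seed is mandatory in the pipeline so no run is silently nondeterministic).

## Instrument selection

Defaults are the conventional suggestive-threshold settings for
low-heritability microbiome/metabolite exposures: p < 1×10⁻⁵ (strict
inequality at the boundary), MAF ≥ 0.01, greedy LD clumping at r² > 0.001
within 10,000 kb, and weak-instrument exclusion at F < 10 (F ≥ 10 kept).
Explained variance uses R² = 2·EAF·(1−EAF)·β² for sets of fewer than 10
instruments and β²/(β² + N·SE²) — the algebraic reduction of the
frequency-weighted ratio — otherwise. The small-set formula assumes
standardized traits and can exceed 1 for extreme β; inputs of that
magnitude indicate unstandardized effects and are the user's
responsibility. Set-level strength sums per-SNP R² (additive under the
independence clumping enforces) into F = [R²/(1−R²)]·[(N−1−i)/i]; the
per-IV exclusion uses the univariate F (i = 1) on each SNP's own R².

Clumping without a genotype reference panel: a precomputed pairwise r²
table (TSV) can be supplied; pairs absent from the table are treated as
unlinked. With no table at all, distance-only mode removes every
same-chromosome neighbour inside the window — a strictly more aggressive
approximation that never under-prunes. Confounder screening is file-based:
a TSV of SNP → trait annotations (e.g. HDL cholesterol, smoking, BMI, body
fat) exported from any variant-annotation service; annotated instruments
are dropped with the trait logged.

## Harmonization

Effects are expressed on the exposure's effect allele. Swapped alleles
negate the outcome beta and reflect its EAF; strand flips are resolved by
complementing before matching. Palindromic SNPs (A/T, C/G) carry no strand
information in their allele letters, so strand is inferred from frequency:
kept only when both traits' EAFs fall on the same side of 0.5 and both MAFs
are below 0.42 (configurable); dropped as ambiguous otherwise, and dropped
unconditionally when the outcome EAF is missing. Duplicate SNP ids within
one trait keep the smallest-p record. Every drop is recorded with a reason
code. Positions are 1-based, as in conventional GWAS exports.

## Sensitivity panel

Cochran's Q is Σ(β<sub>Yj</sub> − a − b·β<sub>Xj</sub>)²/σ<sub>Yj</sub>²
with first-order weights (identical to Σw<sub>j</sub>(ratio<sub>j</sub> − b)²
when a = 0), on nSNP−1 df about the IVW fit and nSNP−2 about the Egger fit;
heterogeneity is flagged at Q-test p < 0.05. The Steiger directionality
test sums instrument-explained variance: frequency-based
2·EAF·(1−EAF)·β<sub>X</sub>² on the exposure side, and z-recovered
r = z/√(z²+N) on the outcome side — binary outcomes on the observed scale.
Its p-value compares the Fisher-z-transformed multiple correlations across
the two independent samples. Bonferroni correction is per exposure
category with divisors 1 (order), 3 (family), 15 (genus), 9 (metabolite)
and 20 (pathway) by default — these are post-hoc counts of initially
significant exposures and therefore config-supplied, not hard-coded —
with strict inequality at the threshold.

## Synthetic data

The generator is summary-level: no individual genotypes and no LD between
SNPs (the pipeline assumes post-clumping independence). Per instrument,
EAF ~ Uniform(0.1, 0.9), γ ~ N(0, 0.1²) (a realistic effect scale for
suggestive-threshold microbiome GWAS hits at N ≈ 18,000, where detectable
effects start near |β| ≈ 0.05), SEs follow the analytic forms
1/√(2p(1−p)N) and, for binary outcomes, 1/√(2p(1−p)·N·cf(1−cf)). Observed
effects add N(0, SE²) noise; pleiotropy enters as
α ~ N(μ<sub>α</sub>, σ<sub>α</sub>²), optionally correlated with γ to
violate InSIDE; reverse designs swap the generative roles of exposure and
outcome. The global seed expands into per-component substreams, so adding
null SNPs never shifts the instruments' draws and equal seeds give
byte-identical output tables. Preset scenarios carry the real cohort sizes
(exposure 18,340; outcomes 218,792 at 16.4% cases and 463,010 at 0.68%
cases).

What the generator does not emulate — and hence what passing tests do not
establish about real data: LD structure and imperfect clumping,
compositional taxon-abundance artefacts, population stratification, sample
overlap between exposure and outcome cohorts, and liability-scale effects
for binary traits.

Two designed-in consequences of the observed-scale binary convention are
worth noting. First, with the rare-outcome cohort (0.68% cases) the
Steiger outcome-r² is attenuated by cf(1−cf) ≈ 0.0067, which makes reverse
causation essentially undetectable on the observed scale; the `reverse`
preset therefore uses the common-outcome cohort scale (16.4% cases) with
θ = 0.2, where the direction flag is informative. Second, the Egger
intercept is only unbiased for μ<sub>α</sub> once near-zero-γ instruments
are removed — the β<sub>X</sub> ≥ 0 orientation flips the sign of their
pleiotropy contribution — and the p < 1×10⁻⁵ selection step that the
pipeline always applies removes exactly those SNPs, so intercept
calibration is assessed downstream of selection, as in the real workflow.

## Numerical choices and problem sizes

χ² and normal/t tails come from scipy; p-values are clipped to the smallest
positive double rather than underflowing to 0. Odds-ratio transforms
saturate to inf rather than raising on absurd log-odds. Degenerate inputs
raise typed errors (EAF ∈ {0,1}, N ≤ i+1, β<sub>X</sub> = 0, too few
instruments); the pipeline isolates failures per exposure-outcome pair and
emits a status row, because a sweep across hundreds of taxa must not abort
on one degenerate exposure.

Replicate studies in the test suite and the acceptance script use 100–200
instruments with 200–2,000 replicates, and estimator-calibration checks use
cohort sizes of 4×10⁵ so that weak-instrument regression dilution
(≈ 1–2% of θ at N ≈ 18,000 with γ-sd 0.1 — an intrinsic property of
two-sample MR, not an implementation artefact) does not dominate the
Monte-Carlo error of the mean. Calibration targets: every estimator's mean
within 3 MC SEs of θ = 0.1; IVW type-I error within [0.03, 0.07] at
α = 0.05; Steiger direction correct in ≥ 95% of forward and reverse
replicates.

## Known limitations

Single-exposure models only (no multivariable MR, MR-PRESSO or
contamination mixtures); no genotype-panel clumping or liftover; no
liability-scale conversion for binary traits; the confounder screen is as
good as the annotation file supplied to it.
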