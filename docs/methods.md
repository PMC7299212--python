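# Methods

## Problem and model

`cismr` implements cis drug-target Mendelian randomization (MR): the causal
effect of pharmacologically modulating a protein target is proxied by genetic
variants near the target's gene that shift a downstream biomarker of the
target's activity. The motivating design is IL-6R inhibition proxied by
CRP-lowering variants in the IL6R cis region, with effects on stroke and
other cardiovascular outcomes estimated by two-sample MR from GWAS summary
statistics.

For variant *j*, let β̂_exp,j (SE σ_exp,j) be its effect on the exposure
biomarker (SD units per allele) and β̂_out,j (SE σ_out,j) its effect on the
outcome (log-odds per allele for binary outcomes). The single-variant Wald
ratio is θ̂_j = β̂_out,j / β̂_exp,j with first-order delta-method standard
error σ_j = σ_out,j / |β̂_exp,j|. The inverse-variance weighted (IVW)
estimate pools ratios with weights w_j = σ_j⁻²:

θ̂ = Σ w_j θ̂_j / Σ w_j,  SE_fixed = (Σ w_j)^(−1/2),

which is algebraically identical to weighted least squares of β̂_out on
β̂_exp through the origin with weights σ_out⁻². Heterogeneity is measured by
Cochran's Q = Σ w_j (θ̂_j − θ̂)² on J−1 degrees of freedom.

### Sign convention

The exposure axis is **one SD of biomarker decrease**. Exposure records are
first oriented so every β̂_exp ≥ 0 (negative-beta records have alleles
swapped, eaf complemented, beta negated); the synthetic generator produces
effects directly on the decrease scale (a positive beta means the effect
allele lowers the biomarker). A protective causal effect of target
inhibition therefore appears as a negative θ (odds ratio < 1), matching the
convention of drug-target MR forest plots. Orientation never changes |β|,
SEs or p-values, and the Wald ratio is invariant to which allele is labeled
"effect", so the convention is purely presentational — but it is applied in
exactly one place to avoid double sign flips.

## Instrument selection

1. **Cis window.** Variants with position in
   [gene_start − flank, gene_end + flank], both ends inclusive, 1-based
   coordinates; flank defaults to 300 kb.
2. **Significance.** p < 5×10⁻⁸, strict.
3. **Greedy LD clumping** at r² < 0.1: repeatedly retain the smallest-p
   unretired variant and retire everything with r² ≥ 0.1 against it. Ties on
   p are broken by smaller base-pair position, then lexicographic rsid, so
   output is independent of input row order. The LD matrix is an explicit
   input: a square tab-delimited text matrix of correlations **r** (not r²)
   with variant IDs as first row and column. No remote LD panels are
   queried.
4. **Approximate conditional analysis** of each retained variant against the
   lead (smallest-p) variant, a two-variant joint model on standardized
   effects: with z_j = β̂_j/σ_j and r the LD correlation with the lead,
   z_cond = (z_j − r·z_lead)/√(1 − r²), two-sided normal p-value, and
   conditional beta/SE recovered by multiplying by σ_j. Conditioning on the
   lead only (rather than full stepwise joint modeling) matches how a single
   dominant cis signal is handled in practice, and converting through
   z-scores avoids needing reference allele frequencies. Variants failing
   the conditional threshold (0.05; Bonferroni-corrected 0.05/m for
   variants inside the gene body, with m defaulting to the number of
   non-lead instruments tested) are flagged, never silently removed.
   With 7 instruments the default in-gene threshold is 0.05/6 ≈ 0.0083.
5. **Instrument strength**: single-variant F = (β̂/σ)², the squared z-score;
   F > 10 is the conventional weak-instrument bound, and the designs
   emulated here sit in the high tens to hundreds.

## Estimators

* **IVW** defaults to multiplicative random effects: SE_fixed is inflated by
  √max(1, Q/(J−1)), so the SE never drops below the fixed-effect SE. This
  makes the test mildly conservative under homogeneity (simulated type-I
  error ≈ 0.03–0.04 at α = 0.05) and robust to overdispersion.
* **Weighted median**: ratios ordered, estimate taken where the cumulative
  normalized weight (midpoint convention) crosses ½, interpolating linearly
  between bracketing ratios. SE by parametric bootstrap: β̂_exp and β̂_out
  resampled from their normal sampling distributions (default 5 000 draws),
  SE = SD of bootstrap medians. Consistent while valid instruments carry
  more than half of the weight; with fewer it breaks down, which the test
  suite demonstrates rather than hides.
* **Contamination mixture**: each ratio contributes
  max{log N(θ̂_j; θ, σ_j²), log N(θ̂_j; 0, σ_j² + ψ²)} to a profile
  log-likelihood evaluated on a grid (default 5 000 points spanning
  [min θ̂_j − 3 max σ_j, max θ̂_j + 3 max σ_j]); θ̂ is the grid argmax and
  the 95% CI is the set of grid points within χ²₁(0.95)/2 ≈ 1.92 units of
  the maximum (enclosing hull reported, disjoint regions flagged). ψ
  defaults to the SD of the ratio estimates — the original method leaves ψ
  to the analyst, and this data-driven scale keeps the invalid component
  wide relative to the spread actually observed.
* **MR-PRESSO**: observed RSS = Σ w_j (β̂_out,j − θ̂₍₋ⱼ₎ β̂_exp,j)² with
  leave-one-out IVW slopes and w_j = σ_out,j⁻²; the null RSS distribution is
  simulated parametrically (β*_exp ~ N(β̂_exp, σ_exp), β*_out ~
  N(θ̂₍₋ⱼ₎β̂_exp, σ_out), default 1 000 draws). Global and per-variant
  Monte-Carlo p-values use the +1 correction, so resolution is 1/(n_sim+1);
  per-variant p-values are Bonferroni-corrected across instruments and
  outliers called at corrected p < 0.05. The returned estimate is the
  outlier-corrected IVW, with raw/corrected estimates and the relative
  distortion in `extras`.
* **Pharmacological scaling** multiplies θ, SE and CI by a positive constant
  (the biomarker reduction the drug achieves, e.g. the SD-units CRP decrease
  of tocilizumab 8 mg/kg); z and p are invariant. The constant enters only
  as configuration — no trial meta-analysis is performed here.
* Two-sided p-values come from the normal distribution throughout (not t),
  the summary-statistic MR convention. The ratio SE carries no
  second-order or exposure-uncertainty term; with F ≥ ~80 the omitted terms
  are below a percent of the SE, but this is a documented limitation for
  weak-instrument settings.

## Permutation test of exposure-independence

A cis-instrument effect could in principle reflect the biomarker itself
rather than the target pathway. The test draws k-SNP subsets (default
k = 7) without replacement from the pool of *all* biomarker-associated
variants (the emulated design uses 187), computes each subset's IVW effect
on the outcome, and ranks the observed cis estimate in that null
distribution. The percentile is 100·#{null < observed}/n_perm —
strictly-less, ties count as not-below (the paper-silent convention chosen
here; it is the conservative direction for a "below the fifth percentile"
claim). Default n_perm = 10 000; when fewer distinct subsets exist the test
enumerates all of them exhaustively and says so. By default the observed
instruments are excluded from the pool (a null untouched by the tested
set); a toggle includes them to mirror designs that sample from the full
pool. Exchangeability — and hence uniformity of the percentile under the
global null — holds when the observed set is itself a random k-subset of
the same pool, which is how the calibration test is constructed.

## Synthetic data generator

The generator emulates the *structure* of the real data sources (a 204 402-
person biomarker GWAS; a 34 217 case / 404 630 control outcome GWAS) without
any download, directly on the summary-statistic scale:

* **Independent instruments** (`simulate_instruments`): maf p_j ~
  U(0.10, 0.50); true exposure effect γ_j ~ U(0.03, 0.12) SD per allele —
  chosen so single-variant F statistics land in the ~80–750 range typical of
  a strong cis biomarker locus at this sample size; exposure SE from the
  analytic quantitative-trait formula 1/√(2p(1−p)n); outcome SE from the
  standard log-OR approximation √((1/(2p(1−p)))(1/n_cases + 1/n_controls));
  β̂_exp ~ N(γ, σ_exp²), β̂_out ~ N(θγ + α, σ_out²) with pleiotropic offsets
  α ~ N(α_mean, α_sd²) for a configurable invalid fraction (count rounded
  half-up). The default causal effect is θ = −0.30 log-odds per SD decrease,
  a protective effect of the size a well-powered drug-target analysis
  targets; θ = 0 variants are used for null pools and calibration.
* **Cis region** (`simulate_cis_region`): AR(1) LD, r(i,k) = ρ^|i−k|
  (default ρ = 0.6) over 151 evenly spaced variants spanning the gene ±
  1.2·flank, so the outermost variants deliberately fall outside the cis
  window and exercise the window filter. Marginal z-scores follow the
  standard model z ~ MVN(R·z_causal, R), drawn as R·z_causal + chol(R)·ε.
  One lead signal at the gene center (noncentrality 13, F ≈ 170) plus two
  secondary signals (noncentrality 10, F ≈ 100) are planted by default;
  requesting causal variants closer than the LD decay allows (mutual
  r² ≥ 0.05) is an error. These noncentralities keep proxy variants at the
  clumping boundary (r² ≈ 0.1) well below genome-wide significance, so the
  retained set equals the planted set in ≥ 95% of replicates — stronger
  leads in steep-LD regions would leave significant just-outside-the-clump
  proxies, which is a real phenomenon, not a generator artifact, and can be
  explored by raising the noncentralities.
* **Region outcomes** (`simulate_region_outcome`): outcome z-scores inherit
  the region's LD with causal means (θγ_j + α_j)/σ_out,j; binary by default,
  quantitative (SD-unit) outcomes by sample size override.
* All randomness flows from a single integer seed through tagged
  `numpy.random.default_rng([seed, stream])` streams; equal configs give
  byte-identical output.

What the generator does **not** model: sample overlap between exposure and
outcome studies, allele-frequency differences between studies, strand
ambiguity (only non-palindromic allele pairs are emitted), fine-scale LD
beyond AR(1), winner's-curse in instrument discovery, and individual-level
genotypes (except inside test oracles, where a two-SNP individual-level
regression validates the conditional approximation). Passing tests therefore
demonstrate internal statistical correctness under these idealized
conditions, not performance on real GWAS data.

## Harmonization

Pairs are matched on rsid; outcome effects are aligned to the exposure
effect allele directly or via strand complement, negating β̂_out when the
match is to the swapped alleles. Palindromic variants (A/T, C/G) are
retained only when the effect-allele frequencies in both studies are on the
same side of 0.5 and both outside [0.42, 0.58] (window w = 0.08, standard
practice; the emulated study does not state its handling). Dropped pairs
stay in the output with a reason and are excluded from analysis; zero
matches is fatal with a diagnostic listing. Column dialects are explicit
name mappings, never guessed. No genome-build liftover or reference-based
strand inference is attempted.

## Multiple testing and classification

Family-wise thresholds are α/m with m derived at run time from the
configured outcome family tags (3 stroke subtypes → 0.017; 9 cardiovascular
outcomes → 0.0056 at 2 significant figures; comparisons always use full
precision). IVW p < family threshold → significant; p < α = 0.05 →
suggestive; otherwise null. Classification is a pure function of the
p-value and thresholds.

## Numerical and design choices

* Monte-Carlo p-values always use the (1 + #exceedances)/(n + 1) correction.
* Seeds are explicit everywhere; per-outcome and per-estimator seeds are
  spawned from the run seed via `numpy.random.SeedSequence`, and run reports
  embed the resolved configuration and seed for exact reruns.
* LD matrices must be symmetric within 1e−10 with exact unit diagonal;
  indefiniteness beyond −1e−8 in the smallest eigenvalue warns rather than
  fails (text-roundtripped matrices accumulate harmless error).
* A reported p-value more than two orders of magnitude from the
  normal-approximation value of |β̂/σ| triggers a validation warning, not a
  rejection.
* The contamination-mixture SE in tabular output is the profile CI width
  divided by 2·1.96 — a symmetric-normal summary of a possibly asymmetric
  interval; the CI itself is authoritative.

## Replicated experiment sizes

The calibration suite (`cismr.calibration`, driven by the acceptance script
and the acceptance tests) uses 1 000 replicates for IVW type-I error, 500
for recovery/coverage at θ = −0.30, 200 for the pleiotropy bias comparison
(replicates conditioned on the invalid instruments carrying < 50% of the
weight — the regime where the weighted median is consistent), 100 runs for
MR-PRESSO outlier power and for the permutation test (k = 7 against a
187-variant pool, 10 000 permutations each), and 200 for MR-PRESSO global
calibration. These sizes give Monte-Carlo SEs a few times smaller than the
acceptance tolerances while keeping the whole suite in well under a minute.

## Known limitations

* The conditional analysis is strictly two-variant; regions with several
  partially-correlated signals need full stepwise joint modeling, which is
  out of scope.
* First-order ratio SEs understate uncertainty for weak instruments.
* The weighted-median bootstrap resamples per-variant summary statistics
  independently, ignoring any between-study correlation from sample overlap.
* The permutation null treats pool SNPs as exchangeable; structured pools
  (e.g. clumps of correlated variants) would need pool-level thinning first.
* Binary-outcome SEs use the 1/(2p(1−p))·(1/n_cases + 1/n_controls)
  approximation, adequate at desk scale but not exact for rare outcomes.
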