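# Methods

## Model and assumptions

All analyses operate on two-sample GWAS summary statistics: per-SNP effect
estimates for an exposure X, optional mediators M_k, and an outcome Y drawn
from non-overlapping samples.  Binary-outcome effects are interpreted on the
log-odds scale; continuous-trait units are opaque and carried through.  The
core identifying assumptions are the usual instrumental-variable triad
(relevance, independence, exclusion restriction), relaxed estimator by
estimator: MR-Egger requires only InSIDE (pleiotropy independent of
instrument strength), the weighted median tolerates up to half the weight on
invalid instruments, RAPS absorbs balanced pleiotropy into an
overdispersion variance τ², and MR-PRESSO removes individual violators.

Wald ratios use the first-order SE (σ_Y/|β_X|) by default; the second-order
form adding β_Y²σ_X²/β_X⁴ is available.  The headline IVW model is
multiplicative random effects — the fixed-effect SE scaled by
max(1, √(Q/(J−1))) — because real lipid instrument sets show substantial
heterogeneity; the truncation at 1 makes the model conservative, never
anti-conservative, under homogeneity.  p-values use a normal reference for
IVW, the weighted median, ML and RAPS, and t(J−2) for both MR-Egger
coefficients.

Maximum likelihood profiles the per-SNP instrument strengths out of a
bivariate normal measurement model, leaving the objective
½Σ(β_Yj − θβ_Xj)²/(σ_Yj² + θ²σ_Xj²); its score coincides with the
squared-loss RAPS estimating equation at τ² = 0, which the tests exploit as
a cross-check.  The RAPS solver brackets the score root around the IVW
estimate and falls back to minimizing the integrated loss when the bounded
Huber score (c = 1.345) offers no sign change; τ² is solved jointly from
the moment condition mean(ψ(t)·t) = E[ψ(Z)Z] and floored at zero; SEs come
from the empirical sandwich.

## Instrument processing

Selection keeps SNPs with p < 5×10⁻⁸ and min(EAF, 1−EAF) > 0.01, drops a
caller-supplied exclusion list (the stand-in for a manual confounder
screen), then applies greedy p-value-ranked clumping (r² < 0.001 within a
10,000 kb window) against a caller-supplied LD matrix, with lexicographic
SNP-id tie-break for determinism.  Without an LD matrix survivors are
treated as independent — the correct behaviour for the simulated panels,
which are generated without LD.  Harmonization re-orients outcome effects
onto the exposure's effect allele, resolving strand flips by base
complement; palindromic SNPs are aligned by allele frequency when both
sides lie outside the 0.42–0.58 band and are otherwise dropped as ambiguous
(configurable).  Every filtering step is counted, and the counts ledger
reconciles exactly against the retained set.

## The synthetic generator

`SimTruth` fixes the structural model: J independent biallelic instruments
with MAF ~ U(0.05, 0.5) and exposure effects γ_j ~ N(0.08, 0.02²) — strong
instruments resembling genome-wide-significant lipid hits (mean F ≫ 10).
Mediator effects are γ_j·θ_xm plus, for a configurable fraction of SNPs, a
mediator-specific block with γ_j = 0 and direct mediator effects drawn from
the same strength distribution — these emulate each cytokine's own GWAS
hits and are what identifies the mediator coefficient in MVMR.  Outcome
effects are γ_j·θ_xy_direct + Σ_k (mediator effect)·θ_my[k] + α_j, with
α_j ~ N(pleiotropy_mean, pleiotropy_sd²) on an invalid fraction of SNPs.
Observed effects add N(0, se²) noise with se = (2·maf·(1−maf)·n)^(−1/2),
using an independent random stream per trait (the two-sample property).
Default sample sizes mirror the motivating data sources: 440,000 (biobank
lipids), 218,000 (biobank case-control outcome), 21,758 (cytokine
consortium).

What the generator does *not* emulate: LD between instruments, sample
overlap, winner's-curse selection, population stratification, non-normal
effect distributions, and individual-level binary sampling (outcome betas
are generated directly on the log-odds scale).  Passing tests therefore
demonstrate correctness of the estimators under the summary-statistic
model's own assumptions, not robustness to those real-data complications.

A deliberate consequence of realistic sample sizes: with a mediator GWAS of
only ~22,000, measurement error in the mediator's effect estimates
attenuates its MVMR coefficient by several percent (a NOME violation).
This is a property of MVMR-IVW itself, not a bug; recovery checks are
therefore run at n = 5×10⁵ per sample, where the attenuation is negligible.

## Mediation decomposition

Step 1 estimates β1_k (exposure→mediator) by univariable IVW on the
exposure's instruments; step 2 estimates β2_k (mediator→outcome adjusted
for the exposure) and β3 (the exposure's direct effect) from one MVMR fit
on the union of the traits' instrument sets.  The product method reports
E% = Σβ1β2 / (β3 + Σβ1β2); the difference method reports
(total − β3)/total.  The product form is the default because its
denominator reconstructs the total from the fitted path coefficients and
stays internally consistent when the univariable and multivariable fits
disagree slightly; both agree asymptotically for a single mediator with
valid instruments, and `method="both"` reports the pair.  Indirect-effect
SEs use the delta method √(β1²se(β2)² + β2²se(β1)²); the E% interval
propagates the indirect CI against a fixed denominator and is labelled
approximate.  Opposite-sign total and indirect effects set an
`inconsistent` flag rather than reporting a bare negative percentage.

## MR-PRESSO details

The observed statistic is RSS = Σ_j w_j(β_Yj − θ̂_(−j)β_Xj)² with
leave-one-out IVW slopes, so an outlier cannot mask itself.  The null is
simulated parametrically (β* drawn at the leave-one-out fitted values with
the reported SEs; default 5,000 draws, minimum 1,000); per-SNP outlier
p-values are Bonferroni-adjusted and thresholded at 0.05; the corrected
estimate is IVW on the unflagged subset; a distortion p-value compares the
raw-vs-corrected slope shift against removals of equally many random SNPs.
A global p of zero is reported as the bound "< 1/n_sim", never as 0.

## Numerical and design choices

- Instrument selection and harmonization are pure set/scan operations with
  deterministic tie-breaks; the whole pipeline is a pure function of
  (config, seed), and per-stage seeds derive from the master seed by a
  counter, keeping edges independent but reproducible.
- The weighted median interpolates cumulative weights at ½ with the
  midpoint (s_j − w_j/2) convention; its SE is a seeded parametric
  bootstrap (default 1,000 draws; below 100 draws a warning is raised).
- ML optimization is bounded scalar minimization to 1e-10 on the objective,
  initialized at the fixed-effect IVW estimate; the SE uses the numerical
  profile curvature.
- Tables are written tab-delimited with 17 significant digits, so round
  trips are lossless; missing optional fields are empty, never 0.
- Degenerate inputs fail loudly: zero exposure beta (undefined Wald ratio),
  rank-deficient MVMR designs (collinearity error naming the offending
  exposures), empty tables, duplicate SNP ids, invalid alleles.

Problem sizes in the test-suite simulations (replicate counts of 200–1000,
panels of 30–400 SNPs) were chosen to keep Monte-Carlo error well inside
each property's assertion margin.

## Known limitations

No correlated-instrument (generalized) IVW, no Steiger direction filtering,
no proxy-SNP lookup, no LD estimation from reference panels, no mode-based
or contamination-mixture estimators, and no figure rendering (plot data is
emitted as tidy coordinate tables).  The replicative single-source analysis
is a configuration variant, not separate code.  E% uncertainty is
approximate by construction; for publication-grade intervals on mediated
proportions, bootstrap over the full decomposition externally.
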