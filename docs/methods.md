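# Methods

This note documents the statistical model behind `mrscreen`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing
results.

## Model and assumptions

Two-sample MR treats genetic variants as instruments for an exposure
under the three instrumental-variable assumptions: the variant is
associated with the exposure; it is independent of confounders of the
exposure-outcome relationship; and it affects the outcome only through
the exposure. All estimators operate on per-SNP summary associations
(beta, se) estimated in non-overlapping samples, with effects on the
standardized-trait scale for continuous traits and the log-odds scale for
binary ones. Odds-ratio input columns are log-transformed at ingestion
when declared in the column map, so the whole pipeline works on one
additive scale.

## Instrument selection and harmonization

Instruments are exposure SNPs with p < 5×10⁻⁸, pruned by greedy LD
clumping: significant SNPs are ranked by ascending p (ties broken
lexicographically by snp_id for determinism) and each kept index SNP
removes every remaining SNP on the same chromosome with r² ≥ 0.01 within
a 5,000 kb window. The window is interpreted as the span within which LD
pruning applies — the standard clumping semantics. Pairs absent from the
LD table are treated as unlinked (r² = 0) and noted in the selection log.
On instances small enough to enumerate, this greedy rule provably returns
the maximal conflict-free set earliest in priority order; the test suite
checks that equivalence by brute force.

Harmonization aligns outcome records onto the exposure's effect allele:
matching alleles are copied; swapped alleles negate the outcome beta and
reflect the frequency, exactly once, with a `flipped` flag; non-palindromic
records are also reconciled across strands via complementarity.
Palindromic (A/T, C/G) SNPs cannot be strand-resolved from alleles alone;
the default policy keeps them only when both studies' effect-allele
frequencies fall outside the 0.42–0.58 ambiguity band, inferring a strand
flip when the frequencies disagree about the minor allele. `drop` and
`keep_all` policies are available; the default band and behaviour follow
common practice in summary-data MR software and are a documented choice,
since harmonization conventions differ across analyses. There is no
proxy-SNP lookup. Every dropped SNP is logged with a reason — never
silently discarded.

## Estimators

* **Wald ratio** β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order se σ_yj/|γ̂ⱼ|. The
  first-order form makes IVW coincide exactly with weighted least squares
  through the origin, which is the identity the oracle tests exploit; a
  second-order option that adds the γ̂-uncertainty term is exposed as a
  flag.
* **IVW**: weights 1/σ_yj²; "random-effects IVW" is implemented as the
  multiplicative model, scaling the fixed-effect se by √max(Q/(L−1), 1).
  The floor at 1 means the random-effects CI is never narrower than the
  fixed-effect CI; under perfect homogeneity it is mildly conservative
  (measured coverage ≈ 97% at nominal 95%), while the fixed-effect CI is
  nominal. Coverage calibration is therefore asserted on the
  correctly-specified fixed-effect interval.
* **MR-Egger**: instruments are sign-oriented so all γ̂ⱼ > 0 before the
  weighted two-parameter fit; slope and intercept p-values use a t
  distribution with L−2 df, and both standard errors carry the
  multiplicative scaling √max(Q/(L−2), 1).
* **Weighted median**: order the ratios, form cumulative weights
  sⱼ = Σₖ≤ⱼ w'ₖ − w'ⱼ/2, and interpolate linearly at s = 0.5. The se is
  the SD over a seeded parametric bootstrap that redraws each ratio from
  Normal(β̂ⱼ, seⱼ) with the observed weights held fixed.
* **Modes**: maximum of a Gaussian kernel density over the ratios
  (uniform weights for the simple mode, inverse-variance for the
  weighted mode) evaluated on a 4,096-point grid spanning the data ±3
  bandwidths. Bandwidth = factor × 1.06 × min(SD, MAD/0.6745) × L^(−1/5),
  the normal-reference rule with a robust spread; the factor defaults
  to 1 and is configurable. If all ratios coincide the common value is
  returned. Bootstrap se as for the median, with the bandwidth held at
  its observed value for stability.
* **Multivariable IVW**: zero-intercept WLS of outcome betas on the L×k
  exposure-beta matrix, weights 1/σ_yj², scaling √max(Q/(L−k), 1).
  An all-zero exposure column carries no information: it is excluded and
  its estimate reported as NaN (so a degenerate second exposure reduces
  exactly to univariable IVW), while genuine collinearity among
  informative columns raises an error naming the offending pair.

Method minima are enforced (wald 1, IVW 2, Egger/median/modes 3, MVMR
k+2); the screening pipeline computes only applicable methods and marks
the rest not-applicable, falling back to the Wald ratio for
single-instrument exposures. P-values are two-sided normal except the
Egger t-tests.

## Sensitivity analyses

Cochran's Q is computed about the IVW ratio mean (df L−1) and about the
Egger fit (df L−2); both are reported because heterogeneity calls can
differ between them. The outlier framework follows the
residual-sum-of-squares simulation approach: each SNP's weighted squared
residual is taken about the leave-one-out IVW slope; the global and
per-SNP null distributions come from n_sim parametric redraws (default
1,000); empirical p-values use the add-one estimator with floor
1/(n_sim+1); per-SNP p-values are Bonferroni-corrected across L, so n_sim
must exceed L/α for an outlier to be flaggable at level α. Outliers are
removed automatically (with the removal list logged) and IVW re-estimated
— automating a step often done by hand, because reproducibility demands
it. The distortion test compares the raw-vs-corrected shift with shifts
from removing random subsets of the same size. Leave-one-out flags any
omission that changes the estimate's sign or moves it by more than one
full-set se. Scatter and funnel plot data are emitted as TSVs; rendering
is a thin matplotlib convenience.

## Meta-analysis and mediation

Per-cohort IVW estimates are combined with fixed-effect inverse-variance
weights; cross-cohort Q is reported. The screening pipeline flags
exposures at raw p ≤ 0.05 per cohort and in the meta-analysis — no
multiple-testing correction by default, matching how discovery/replication
screens are usually read; Bonferroni and Benjamini-Hochberg options exist
but are off by default.

Two-step mediation MR: β₁ from univariable IVW of the mediator on the
exposure's instruments; β₂ from multivariable IVW of the outcome on
(mediator, exposure) over the union of both traits' instruments — a
univariable fit cannot deliver the exposure-adjusted mediator effect, so
the multivariable route is the only faithful one. The total effect is the
univariable exposure-outcome IVW from a single (configurable) outcome
cohort. Proportion = β₁β₂/total, reported in percent truncated to
[0, 100] with the untruncated value retained. Its CI uses the delta
method with zero covariance across the three fits (they share no outcome
data); a parametric bootstrap is available behind a flag and both are
labelled in output, since no single convention dominates. Totals below a
configurable floor (default 10⁻⁶) make the proportion undefined rather
than an unstable ratio. Ranked reports sort by point-estimate proportion,
ties broken by mediator name.

## The synthetic-data generator

The generator emulates the statistical structure of biobank-scale GWAS
summary data: instrument effects γⱼ ~ Normal(0, 0.03); effect-allele
frequencies uniform on [0.05, 0.95]; standard errors from standard GWAS
sampling theory, se = 1/√(2·EAF·(1−EAF)·n), with binary outcomes
approximated on the log-odds scale by the same formula; default sample
sizes of 300,000 per GWAS. These defaults give a median per-SNP F around
50, in the middle of the range reported for strong polygenic instruments.
Outcome effects are causal·γⱼ plus a per-SNP direct effect αⱼ — exactly
zero, balanced (zero-mean normal, default sd 0.002, a modest direct
effect relative to outcome sampling error at biobank n), or directional
(nonzero mean in the exposure-increasing orientation, the construction
under which InSIDE holds and IVW is biased while Egger is not). LD is
emitted as a precomputed pairwise r² table with exchangeable blocks —
clumping consumes only r², so no genotype simulation is needed; tag SNPs
carry marginal effects attenuated by √r². Palindromic alleles (default
10% of SNPs) and swapped-orientation outcome records (default 20%)
exercise harmonization. Two cohorts share true effects and draw
independent noise; a separate noise seed lets callers redraw noise around
a fixed truth. Mediator chains add mediator-specific instruments so the
multivariable step is identified; the generating total effect is
β_direct + β₁β₂ and the generating mediation proportion its indirect
share.

Not emulated: individual-level genotypes, case-control liability-scale
subtleties, population stratification, sample overlap between exposure
and outcome GWAS, and correlated sampling noise within LD blocks. Passing
tests therefore demonstrate correctness of the estimators and pipeline
under the stated generating model, not robustness to those real-data
complications.

## Problem sizes and numerical conventions

Simulation-based tests use desk-scale configurations chosen to make the
measured properties statistically decisive: calibration checks run 2,000
replicates (1,000 for coverage) with 15–30 instruments; recovery checks
run 200 replicates with 100 instruments; mediation recovery runs 200
replicates of 120-instrument chains at n = 200,000 with step effects of
order 0.1–0.5, where the proportion estimator's per-replicate SD is about
1.4 percentage points. The acceptance script uses the same conditions at
100 replicates per quantity. All writers use a fixed float format
(`%.10g`) and manifests contain no timestamps, so identical configuration
and seeds reproduce byte-identical outputs.

## Known limitations

Weak instruments bias IVW toward the null (the mean recovery check at
n = 100,000 shows the expected ~2–3% attenuation); no winner's-curse
correction is applied to selected instruments; MR-RAPS-style robust
estimators, Steiger filtering and proxy-SNP lookup are out of scope; the
mediation CI ignores covariance between steps estimated from the same
exposure instruments, which is small when step 1 and the total use
different outcome traits but not exactly zero.
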