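# Methods

## The question and the design

Children of heavier parents are heavier themselves, but that correlation
confounds two mechanisms: direct inheritance of adiposity-related alleles,
and *genetic nurture* — parental genotype shaping the child's environment
(intrauterine conditions, food availability, parenting practices) through
the parental phenotype. A mother–father–child trio design separates them.
Parental self-reported BMI is treated as an endogenous exposure and
instrumented with the parent's polygenic index (PGI) for BMI, while
conditioning on the *child's* PGI. Because a child inherits exactly half
of each parent's genome, conditioning on the child's PGI blocks the
direct-transmission path, and whatever association remains between the
parental instrument and the child's outcome must run through the parental
phenotype — the nurture path. Estimation is instrumental-variables
two-stage least squares (IV-2SLS) with both parents' BMIs as endogenous
regressors and both parental PGIs as excluded instruments.

Two conditions make the full trio necessary. Under assortative mating the
parental phenotypes (and weakly, genotypes) correlate, opening a
confounding path from one parent's PGI through the other parent. And
conditioning on the child's PGI — required to block transmission — is
conditioning on a collider of the two parental PGIs, which opens a second
path. Both paths are closed by including the other parent's PGI and BMI in
the model; both re-open in the mother-only "duo" model whenever the father
has a nonzero nurture effect. `run_bias_demo` quantifies exactly this.

## The generative model

`trio_sim` draws cohorts with the statistical structure the estimators
assume, so that every stage can be validated by parameter recovery:

* **Founders.** `n_snps` independent biallelic SNPs at Hardy–Weinberg
  proportions, frequencies uniform on `maf_range` (default 0.05–0.5).
  Per-allele effects are Gaussian, rescaled once per cohort so the genetic
  value G = Σβg explains `h2_bmi` (default 0.075) of parental BMI
  variance. This is the *PGI-captured* heritability, not total
  heritability: it is sized so the instrument strength matches what a
  genome-wide-significant adult-BMI score achieves in a trio sample of a
  few thousand families — first-stage partial F above 35 in ≥ 90% of
  replicate cohorts at n ≈ 2,600 (mean ≈ 66). A consequence of sizing to
  the PGI-captured fraction rather than total heritability is that the
  simulated genetic confounding of the phenotypic father coefficient is
  a few hundredths of a kg/m² per kg/m², far smaller than the phenotypic
  father association seen in real cohorts, which also reflects
  un-modelled shared environment and the full genetic architecture.
* **Parental BMI.** mean 24.8 (mothers) / 26.2 (fathers), common SD
  4.3 kg/m²; BMI = mean + G + Gaussian environment. A single parental SD
  keeps `h2_bmi` a single well-defined proportion for the shared genetic
  value. Self-reports add classical error (`sigma_report`, default
  1 kg/m²) and an optional mean bias (`report_bias`, default 0) since
  self-reported BMI is typically underestimated but no magnitude is
  established.
* **Assortative mating.** Phenotypic, on true BMI: each sex is ranked on
  phenotype plus Gaussian noise with variance σ²(1−ρ)/ρ and mates are
  matched by rank, which realizes a spousal phenotype correlation of
  ρ (`rho_am`, default 0.21) while inducing only the weak genetic
  correlation (≈ h²ρ) that phenotypic assortment implies — matching the
  observed pattern of a clear spousal BMI correlation beside a near-zero
  spousal PGI correlation. All of the spousal correlation is treated as
  assortment at pairing; none as post-pairing convergence.
* **Transmission.** One allele per SNP from each parent; a heterozygous
  parent transmits the effect allele with probability exactly 1/2. The
  simulated Mendelian-error rate is therefore identically zero, which the
  audit in `pgi.mendelian_error_rate` verifies (real genotype data show a
  small positive rate; the audit exists to catch pipeline corruption).
* **Child phenotypes.** BMI at sweep ages 3–17:
  `BMI_t = α_t + δ_t·z(G_child) + γm_t·(BMI_mother−μ) + γp_t·(BMI_father−μ)
  + covariate effects + residual`. The direct effect δ_t rises linearly
  from 0.2 to 0.9 kg/m² per SD and the maternal nurture effect γm_t from
  0.08 to 0.32 kg/m² per kg/m², peaking at 17y (associations strengthen
  with age); the paternal effect defaults to zero — the null the design is
  built to detect. The residual splits into a persistent child component
  (`child_track`, default 0.75 of the residual SD) and transient noise, so
  BMI tracks within child across sweeps (inter-sweep residual correlation
  ≈ 0.56) — without this, BMI-dependent attrition at one sweep would
  barely bias later sweeps, which is neither realistic nor useful for
  validating the weighting machinery. Birthweight responds to maternal
  true BMI at 15 g per kg/m² (intrauterine path). Covariate effects (sex,
  maternal education) are small and included so the covariate machinery is
  non-trivial.
* **Diet.** A latent healthiness variable is lowered by parental true BMI
  (`diet_c_m` = 0.05 SD per kg/m², paternal 0); ordinal items (1 item at
  ages 3–7, 3 at 11, 5 at 14/17, mirroring what a cohort questionnaire
  offers at each age) load on it and are cut at the quartiles of their own
  latent scale. All items are stored healthy-coded.
* **Attrition.** Participation at sweep t+1 is Bernoulli with probability
  `attrition_base + attrition_slope · z_t` (defaults 0.90 and −0.034,
  i.e., 3.4 percentage points lower participation per +1 SD prior BMI
  z-score), clipped to [0.01, 0.99], depending only on the immediately
  prior sweep (Markov). The underlying BMI is always generated;
  participation only governs observation.
* **Survey design.** Default simple random sampling with unit weights. An
  optional two-stratum design with 20 clusters per stratum, an oversampled
  "disadvantaged" stratum (hence unequal recruitment weights) and a small
  cluster intercept on child BMI exists so that the rescaling bootstrap
  has real strata/clusters to resample.
* **Discovery GWAS.** Summary statistics come from a virtual discovery
  sample (default n = 700,000 unrelated adults): per-SNP marginal
  estimates are drawn from their exact sampling distribution
  `N(β_j, σ²_resid/(n·2f_j(1−f_j)))` with Wald p-values. For independent
  SNPs this is distributionally identical to materializing the discovery
  cohort. Each SNP carries random non-ambiguous allele labels so the
  strand-ambiguity filter and allele-orientation logic are exercised.

All randomness flows from one seeded `numpy` generator; cohorts are
bit-reproducible given (config, seed).

## Estimation choices

* **PGIs** are weighted sums of effect-allele dosages using the
  summary-statistic betas (or their signs, for the unweighted variant),
  restricted to p < 5e-8, standardized to mean 0 / SD 1 using plain
  moments of the pooled complete-trio sample. LD clumping is a no-op here
  (independent SNPs) and the result is flagged `clumped=False` so users
  feeding real data know the gap.
* **WLS/2SLS** are written on the weighted normal/projection equations.
  Robust variance is an HC1-style sandwich (small-sample factor n/(n−k)),
  or CR1 cluster-summed scores when cluster ids are supplied; the 2SLS
  sandwich uses second-stage residuals `y − Xβ` with fitted instruments
  treated as fixed, the standard 2SLS convention. First-stage strength is
  the per-endogenous partial F of the excluded instruments (the simple
  diagnostic; Sanderson–Windmeijer conditional F is a non-goal).
  Collinear columns are dropped (earliest column kept) with a logged
  warning rather than an error, since class indicator columns can be
  empty in small simulations.
* **Age** enters as a natural cubic spline with 2 degrees of freedom:
  boundary knots at the observed min/max, one interior knot at the
  median, truncated-power construction (linear beyond the boundaries).
* **BMI z-scores** use the LMS method with linear interpolation in age
  and no extrapolation. The bundled reference table is synthetic (the
  licensed UK1990 charts cannot be shipped): plausible monotone M(age)
  curves, mildly negative L, S growing with age. Any user table in the
  same CSV layout is accepted.
* **Outliers**: values ≥ 3 sweep-specific SDs from the sweep mean are
  deleted once (single pass, not iterated).
* **MCA** is indicator-matrix correspondence analysis (SVD of the
  standardized residual matrix), first dimension, row principal
  coordinates, oriented so the factor correlates positively with a
  configurable healthy-coded anchor item (default: fruit) and then
  standardized. The Burt-matrix eigendecomposition is kept as a test
  oracle only.
* **Non-response weights**: logistic response model (hand-rolled IRLS) on
  configurable baseline covariates, probabilities floored at 0.02,
  combined weight = design/p̂ renormalized to mean 1 among responders.
  One combined weight per family per sweep is shared by all models at
  that sweep.
* **Rao–Wu bootstrap** resamples n_h−1 clusters per stratum with
  replacement, rescaling weights by n_h/(n_h−1) times the multiplicity;
  contrasts (e.g., MR-minus-phenotypic mother coefficient) are evaluated
  per replicate with both models refit on the same replicate weights, so
  their covariance is implicit. CIs are percentile (order statistics of
  the replicates); 500 replicates by default.
* **Estimate comparisons** use z = (est₁−est₂)/√(se₁²+se₂²−2cov); without
  a bootstrap covariance the cov term is 0 with a logged caveat (the
  same-sample correlation makes this conservative).
* Complete cases are regression-specific, not a single global analysis
  sample.

## What the validation experiments show — and what they cannot

`run_recovery_experiment` confirms the trio MR recovers the generative
nurture effects (mother within a few per cent of 0.32 kg/m² per kg/m²
over 200 cohorts of 5,000 families; father CIs cover the null at the
nominal rate). `run_bias_demo` reproduces the design's predictions: the
duo model acquires a bias of ≈ −0.03 kg/m² per kg/m² (at γp = 0.2,
ρ = 0.21) that vanishes when the paternal effect is zero. Notably the two
open paths — assortment (positive) and the child-PGI collider (negative)
— partially offset at these parameter values; the collider term
dominates, so the net duo bias is downward, and at stronger assortment
(ρ ≈ 0.4) the two nearly cancel. The demonstration reports the net
effect. `run_attrition_check` shows inverse-probability weighting
restores the full-cohort mean when the response model contains the actual
attrition driver (prior BMI z); the pipeline's default covariate set for
real use (design weight, maternal education, class, maternal age,
baseline parental BMI) is a configurable choice, not a guarantee.

Because the cohort is synthetic, passing tests demonstrate internal
consistency of the estimators with this generative model — classical
report error, purely phenotypic single-generation assortment, Markov
attrition, LD-free SNPs, no sibling structure, no time-varying parental
BMI, no pleiotropy (the exclusion restriction holds by construction).
They do not certify behaviour under violations of those assumptions; in
particular, nothing here addresses horizontal pleiotropy, which in real
data is a live concern for BMI PGIs.

## Problem sizes and numerical tolerances

Validation experiments use cohorts of 1,200–50,000 families and 120–500
SNPs, sized so each check's Monte-Carlo error is small against the effect
it measures (e.g., the duo-bias demonstration averages 20 cohorts of
30,000 families because the bias it demonstrates is ≈ −0.03 against a
per-cohort SE of ≈ 0.03). Exact identities (LMS round trip, IV closed
form, MCA oracle equivalence) are asserted at 1e-8–1e-10; statistical
checks use explicit Monte-Carlo SEs. The type-I experiment uses 4,000
families per replicate, where the 2SLS sandwich is well calibrated
(at much smaller n it is mildly conservative for the MR terms).
Degenerate inputs (zero heritability, zero-variance reference, single
diet item, one cluster per stratum, constant outcomes) raise named
errors or defined fallbacks as documented per function.
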