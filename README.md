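# trionurture

Trio-based Mendelian randomization of parental BMI effects on offspring
adiposity and diet, with a fully synthetic mother–father–child cohort
simulator for validating every stage of the analysis.

## The problem

Children of heavier parents tend to be heavier, but the correlation mixes
two mechanisms: **direct genetic effects** (the child inherits
adiposity-related alleles) and **indirect "genetic nurture" effects**
(parental genotype acts on the child through the parental phenotype — the
intrauterine environment, food parenting, the home food environment).
Ordinary regressions of child BMI on parental BMI cannot tell these
apart. The remedy used here exploits the fact that children inherit
exactly half of each parent's genome: instrument each parent's
(self-reported, error-prone) BMI with that parent's polygenic index (PGI)
while **conditioning on the child's PGI**, which blocks the
direct-transmission path. In a just-identified IV-2SLS with both parents'
BMIs endogenous,

&nbsp;&nbsp;&nbsp;&nbsp;child outcome = γ_m · BMI_mother + γ_p · BMI_father + θ'·covariates + ε,
instruments Z = (PGI_mother, PGI_father), conditioning on PGI_child,

γ_m and γ_p are the parental nurture effects. Including *both* parents is
load-bearing: conditioning on the child's PGI is conditioning on a
collider of the two parental PGIs, and assortative mating correlates the
parents, so a mother-only ("duo") model is biased whenever the father has
a nonzero effect.

Because the cohorts this design is applied to are access-restricted, the
package ships a first-class synthetic trio simulator — Hardy–Weinberg
founders, rank-matched phenotypic assortative mating, Mendelian
transmission, self-report error, latent-threshold diet items,
BMI-dependent attrition, and an optional stratified/clustered survey
design — so the whole pipeline (PGI construction → LMS z-scores → MCA
diet factor → non-response weights → phenotypic / MR / three-PGI models →
Rao–Wu bootstrap contrasts) is exercisable and validated by parameter
recovery.

## Worked example

```python
import trionurture as tn

sim = tn.SimConfig(n_families=5000, seed=1)        # paper-like defaults
cohort, truth = tn.simulate_cohort(sim, seed=1)

# GWAS summary statistics from a virtual 700k-adult discovery sample,
# thresholded at p < 5e-8, scored and standardized in the trio sample
ss = tn.SumStats(tn.simulate_gwas(truth, seed=8))
from trionurture.pipeline import attach_pgi
df = attach_pgi(cohort, ss, p_threshold=5e-8)

mr = tn.fit_trio_mr(df, "bmi_child_17", 17.0)
ph = tn.fit_phenotypic_model(df, "bmi_child_17", 17.0)
print(f"MR mother     {mr.params['bmi_mother_self']:.3f}"
      f" (SE {mr.se['bmi_mother_self']:.3f})")
print(f"MR father     {mr.params['bmi_father_self']:.3f}"
      f" (SE {mr.se['bmi_father_self']:.3f})")
print(f"pheno father  {ph.params['bmi_father_self']:.3f}"
      f" (SE {ph.se['bmi_father_self']:.3f})")
print("first-stage F:", {k: round(v) for k, v in mr.first_stage_F.items()})
```

prints

```
MR mother     0.348 (SE 0.055)
MR father     -0.110 (SE 0.055)
pheno father  0.013 (SE 0.012)
first-stage F: {'bmi_mother_self': 126, 'bmi_father_self': 118}
```

The generative maternal nurture effect at age 17 is 0.32 kg/m² per kg/m²
and the paternal effect is 0: the MR mother coefficient estimates it
(0.348 ± 0.055 here — one cohort's sampling error; the 200-replicate mean
in the recovery experiment centres on the truth), the father coefficient
is within two SEs of the null, and the parental PGIs are strong
instruments (partial F above 100 at n = 5,000, and above 35 in ≥ 90% of
cohorts at the trio-sample size of ~2,600). With the direct genetic effect switched on, the
*phenotypic* father coefficient is pushed off zero by genetic confounding
while the MR one is not — the design's headline contrast
(`tn.run_bias_demo`, `tests/test_acceptance.py`).

A CLI mirrors the library:

```bash
trionurture simulate --out cohort/ --seed 1 --vcf
trionurture pgi --cohort cohort/ --sumstats cohort/sumstats.tsv --out scores.csv
trionurture analyze --out results/ --seed 1
trionurture recover --reps 50 --seed 1 --out recovery.csv
trionurture biasdemo --seed 1
```

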