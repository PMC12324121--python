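"""Synthetic mother-father-child trio cohorts for within-family Mendelian
randomization studies of parental BMI.

The generative model mirrors the causal structure assumed by trio MR of
genetic-nurture effects:

* independent biallelic SNPs at Hardy-Weinberg proportions in the founder
  (parental) generation, with additive per-allele effects on parental BMI;
* phenotypic assortative mating on true parental BMI (rank matching with
  tuned noise), which induces a spousal BMI correlation but only a weak
  spousal correlation in genetic values;
* Mendelian transmission: each child receives exactly one allele per SNP
  from each parent, so the simulated Mendelian-error rate is exactly zero;
* child BMI at each assessment sweep driven by (i) the child's own genetic
  value (direct genetic effect, ``delta``), (ii) maternal and paternal true
  BMI (nurture effects, ``gamma_m``/``gamma_p``), and (iii) covariates and
  Gaussian noise. Parental BMI enters analyses as a noisy self-report;
* birthweight responding to maternal true BMI (intrauterine pathway);
* ordinal diet items generated by thresholding a latent diet-healthiness
  variable that parental true BMI lowers;
* BMI-dependent attrition: participation at each sweep is Bernoulli with
  a probability that decreases in the prior sweep's BMI z-score.

Everything is drawn from one seeded :class:`numpy.random.Generator`, so a
cohort is bit-reproducible given ``(SimConfig, seed)``.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "SimConfig",
    "TrioCohort",
    "SimTruth",
    "DIET_ITEMS",
    "draw_founders",
    "pair_mates",
    "transmit",
    "simulate_phenotypes",
    "simulate_attrition",
    "simulate_cohort",
    "simulate_gwas",
    "write_cohort",
    "read_cohort",
]

# Default per-sweep effect profiles rise linearly with age and peak at 17y;
# paternal nurture defaults to zero (the null the trio design is built to test).
DEFAULT_SWEEP_AGES = (3.0, 5.0, 7.0, 11.0, 14.0, 17.0)

_NONAMBIGUOUS_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                       ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

#: Diet items available per sweep age: (name, loading on latent healthiness,
#: number of ordered categories). All items are stored healthy-coded (higher
#: value = healthier behaviour), as in the analysis convention.
DIET_ITEMS: dict[float, list[tuple[str, float, int]]] = {
    3.0: [("fruitveg", 0.8, 2)],
    5.0: [("fruit", 0.8, 4)],
    7.0: [("fruit", 0.8, 4)],
    11.0: [("fruit", 0.8, 4), ("sugary_drinks", 0.7, 4),
           ("sweetened_drinks", 0.4, 4)],
    14.0: [("fruit", 0.8, 4), ("vegetables", 0.7, 4), ("fast_food", 0.6, 4),
           ("sugary_drinks", 0.7, 4), ("sweetened_drinks", 0.4, 4)],
    17.0: [("fruit", 0.8, 4), ("vegetables", 0.7, 4), ("fast_food", 0.6, 4),
           ("sugary_drinks", 0.7, 4), ("sweetened_drinks", 0.4, 4)],
}

_SOCIAL_CLASSES = ["managerial", "intermediate", "self_employed",
                   "supervisory", "routine"]


def _default_profile(ages, start, end):
    a = np.asarray(ages, dtype=float)
    lo, hi = a[0], a[-1]
    return tuple(start + (end - start) * (a - lo) / (hi - lo))


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic trio cohort.

    Units: BMI effects are kg/m^2; ``delta`` is kg/m^2 per SD of the child's
    genetic value; ``gamma_m``/``gamma_p`` are kg/m^2 offspring BMI per
    kg/m^2 parental true BMI; ``beta_bw`` is grams per kg/m^2 maternal true
    BMI; ``sigma_report`` is the SD (kg/m^2) of classical parental
    self-report error.
    """

    n_families: int = 2630
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_bmi: float = 0.075
    rho_am: float = 0.21
    mean_bmi_mother: float = 24.8
    mean_bmi_father: float = 26.2
    sd_bmi_parent: float = 4.3
    sweep_ages: tuple[float, ...] = DEFAULT_SWEEP_AGES
    delta: tuple[float, ...] | None = None       # default 0.20 -> 0.90
    gamma_m: tuple[float, ...] | None = None     # default 0.08 -> 0.32
    gamma_p: tuple[float, ...] | None = None     # default all 0
    beta_bw: float = 15.0
    sigma_report: float = 1.0
    report_bias: float = 0.0
    child_track: float = 0.75    # share of residual SD persistent within child
    diet_c_m: float = 0.05
    diet_c_p: float = 0.0
    attrition_slope: float = -0.034
    attrition_base: float = 0.90
    design: str = "srs"                          # "srs" | "stratified"
    n_clusters_per_stratum: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must lie within (0, 1) with lo <= hi")
        if not 0.0 <= self.h2_bmi <= 1.0:
            raise ValueError("h2_bmi must be in [0, 1]")
        if not abs(self.rho_am) < 1.0:
            raise ValueError("rho_am must satisfy |rho_am| < 1")
        if self.sd_bmi_parent <= 0:
            raise ValueError("sd_bmi_parent must be > 0")
        if self.sigma_report < 0:
            raise ValueError("sigma_report must be >= 0")
        if not 0.0 <= self.child_track < 1.0:
            raise ValueError("child_track must be in [0, 1)")
        ages = np.asarray(self.sweep_ages, dtype=float)
        if len(ages) < 1 or np.any(np.diff(ages) <= 0):
            raise ValueError("sweep_ages must be strictly increasing")
        if not 0.0 <= self.attrition_base <= 1.0:
            raise ValueError("attrition_base must be in [0, 1]")
        if self.design not in ("srs", "stratified"):
            raise ValueError("design must be 'srs' or 'stratified'")
        for name in ("delta", "gamma_m", "gamma_p"):
            prof = getattr(self, name)
            if prof is not None and len(prof) != len(ages):
                raise ValueError(f"{name} must have one entry per sweep age")

    # Resolved per-sweep profiles ------------------------------------------
    @property
    def delta_profile(self) -> np.ndarray:
        if self.delta is not None:
            return np.asarray(self.delta, dtype=float)
        return np.asarray(_default_profile(self.sweep_ages, 0.20, 0.90))

    @property
    def gamma_m_profile(self) -> np.ndarray:
        if self.gamma_m is not None:
            return np.asarray(self.gamma_m, dtype=float)
        return np.asarray(_default_profile(self.sweep_ages, 0.08, 0.32))

    @property
    def gamma_p_profile(self) -> np.ndarray:
        if self.gamma_p is not None:
            return np.asarray(self.gamma_p, dtype=float)
        return np.zeros(len(self.sweep_ages))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["sweep_ages"] = list(self.sweep_ages)
        for k in ("delta", "gamma_m", "gamma_p"):
            if d[k] is not None:
                d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["maf_range"] = tuple(d["maf_range"])
        d["sweep_ages"] = tuple(d["sweep_ages"])
        for k in ("delta", "gamma_m", "gamma_p"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SimTruth:
    """Generating parameters plus realized quantities for recovery checks.

    ``snp_beta`` is the per-SNP additive effect (kg/m^2 per effect allele),
    ``lambda_first_stage`` the realized slope of parental true BMI on the
    standardized true genetic value (kg/m^2 per SD) in the drawn cohort.
    """

    config: SimConfig
    snp_beta: np.ndarray
    snp_freq: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    lambda_first_stage: float

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "snp_beta": [float(b) for b in self.snp_beta],
            "snp_freq": [float(f) for f in self.snp_freq],
            "effect_allele": list(self.effect_allele),
            "other_allele": list(self.other_allele),
            "lambda_first_stage": float(self.lambda_first_stage),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            config=SimConfig.from_dict(d["config"]),
            snp_beta=np.asarray(d["snp_beta"], dtype=float),
            snp_freq=np.asarray(d["snp_freq"], dtype=float),
            effect_allele=np.asarray(d["effect_allele"], dtype=object),
            other_allele=np.asarray(d["other_allele"], dtype=object),
            lambda_first_stage=float(d["lambda_first_stage"]),
        )


@dataclass
class TrioCohort:
    """A simulated trio cohort: genotype matrices plus a wide phenotype table.

    ``pheno`` holds one row per family: parental true and self-reported BMI,
    child BMI / age / participation flag / diet items per sweep, birthweight,
    covariates and survey-design fields. Genotypes are dosage matrices
    (families x SNPs, values in {0,1,2}) counting the effect allele.
    """

    snp_ids: np.ndarray
    geno_mother: np.ndarray
    geno_father: np.ndarray
    geno_child: np.ndarray
    pheno: pd.DataFrame

    @property
    def n_families(self) -> int:
        return len(self.pheno)

    @property
    def sweep_ages(self) -> list[float]:
        ages = []
        for c in self.pheno.columns:
            if c.startswith("bmi_child_"):
                ages.append(float(c.removeprefix("bmi_child_").replace("_", ".")))
        return sorted(ages)

    def sweep_col(self, stem: str, age: float) -> str:
        return f"{stem}_{_age_tag(age)}"


def _age_tag(age: float) -> str:
    return f"{age:g}".replace(".", "_")


# ---------------------------------------------------------------------------
# Founders, mating, transmission
# ---------------------------------------------------------------------------

def draw_founders(config: SimConfig, rng: np.random.Generator):
    """Draw founder genotypes at Hardy-Weinberg proportions and SNP effects.

    Returns ``(geno_mother, geno_father, beta, freq)`` where ``beta`` is
    scaled so the population variance of the genetic value
    ``sum_j beta_j * g_j`` equals ``h2_bmi * sd_bmi_parent**2``.
    """
    n, m = config.n_families, config.n_snps
    lo, hi = config.maf_range
    freq = rng.uniform(lo, hi, size=m)
    geno_m = rng.binomial(2, freq, size=(n, m)).astype(np.int8)
    geno_f = rng.binomial(2, freq, size=(n, m)).astype(np.int8)
    beta = rng.normal(size=m)
    var_g = np.sum(beta ** 2 * 2.0 * freq * (1.0 - freq))
    target = config.h2_bmi * config.sd_bmi_parent ** 2
    if config.h2_bmi == 0.0 or var_g == 0.0:
        beta = np.zeros(m)
    else:
        beta *= np.sqrt(target / var_g)
    return geno_m, geno_f, beta, freq


def pair_mates(pheno_mother: np.ndarray, pheno_father: np.ndarray,
               rho_am: float, rng: np.random.Generator) -> np.ndarray:
    """Return a permutation pairing father ``perm[i]`` with mother ``i``.

    Mates are matched on the rank of phenotype-plus-noise in each sex. With
    exact rank matching the noisy scores are comonotone, so the spousal
    phenotype correlation converges to
    ``corr(P_m, score_m) * corr(P_f, score_f)``; choosing the noise variance
    ``sigma_n^2 = sigma_P^2 (1 - |rho|)/|rho|`` for each sex makes each
    factor ``sqrt(|rho|)`` and the product ``|rho|``. Negative targets match
    one sex's ranks in reverse. ``rho_am = 0`` is a uniform random pairing.
    """
    pheno_mother = np.asarray(pheno_mother, dtype=float)
    pheno_father = np.asarray(pheno_father, dtype=float)
    if pheno_mother.shape != pheno_father.shape:
        raise ValueError("mother and father phenotype vectors must have equal length")
    if not abs(rho_am) < 1.0:
        raise ValueError("rho_am must satisfy |rho_am| < 1")
    n = len(pheno_mother)
    if rho_am == 0.0:
        return rng.permutation(n)
    r = abs(rho_am)
    scores = []
    for p in (pheno_mother, pheno_father):
        sd = np.std(p)
        if sd == 0.0:
            # degenerate phenotype: any pairing realizes correlation 0
            sd = 1.0
        noise_sd = sd * np.sqrt((1.0 - r) / r)
        scores.append(p + rng.normal(scale=noise_sd, size=n))
    order_m = np.argsort(scores[0])
    order_f = np.argsort(scores[1])
    if rho_am < 0:
        order_f = order_f[::-1]
    perm = np.empty(n, dtype=np.intp)
    perm[order_m] = order_f
    return perm


def transmit(mother_dosages: np.ndarray, father_dosages: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Mendelian transmission: one allele from each parent per SNP.

    A heterozygous parent transmits the effect allele with probability 1/2;
    homozygotes transmit deterministically. Transmission probability per
    parent is therefore ``dosage / 2``.
    """
    gm = np.asarray(mother_dosages)
    gf = np.asarray(father_dosages)
    for g, who in ((gm, "mother"), (gf, "father")):
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError(f"{who} dosages must be in {{0, 1, 2}}")
    a_m = rng.binomial(1, gm / 2.0)
    a_f = rng.binomial(1, gf / 2.0)
    return (a_m + a_f).astype(np.int8)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def simulate_phenotypes(config: SimConfig, geno_m, geno_f, geno_c, beta,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Fill the phenotype/covariate table given paired genotypes.

    Structural model (per family, sweep t):

    * parental true BMI  = mean + G + N(0, (1 - h2) sd^2)
    * self-reported BMI  = true BMI + report_bias + N(0, sigma_report^2)
    * child BMI_t = alpha_t + delta_t * z(G_child) + gamma_m_t * (BMI_m - mu_m)
      + gamma_p_t * (BMI_f - mu_f) + covariate effects + N(0, sigma_t^2)
    * birthweight = 3400 + beta_bw * (BMI_m - mu_m) + N(0, 450^2)
    * latent diet healthiness D = -c_m (BMI_m - mu_m) - c_p (BMI_f - mu_f)
      + N(0, 1); ordinal items cut the item latent (loading * D + N(0,1))
      at its own population quartiles.
    """
    n = config.n_families
    sd_env = config.sd_bmi_parent * np.sqrt(max(0.0, 1.0 - config.h2_bmi))
    bmi_m_true = config.mean_bmi_mother + geno_m @ beta \
        + rng.normal(scale=sd_env, size=n)
    bmi_f_true = config.mean_bmi_father + geno_f @ beta \
        + rng.normal(scale=sd_env, size=n)
    return _phenotypes_given_parent_bmi(config, geno_c, beta, bmi_m_true,
                                        bmi_f_true, rng)


def _assign_design(df: pd.DataFrame, config: SimConfig,
                   rng: np.random.Generator) -> None:
    """Survey design fields: SRS with unit weights, or a two-stratum
    clustered design with the disadvantaged stratum oversampled (so
    recruitment weights are unequal) and a small cluster intercept on child
    BMI so clustering is consequential."""
    n = len(df)
    if config.design == "srs":
        df["stratum"] = 1
        df["cluster"] = np.arange(1, n + 1)
        df["weight"] = 1.0
        return
    # stratum 2 ("disadvantaged", 40% of the population) sampled at twice the
    # rate of stratum 1 -> design weights proportional to 1/rate
    stratum = (rng.random(n) < 0.5).astype(int) + 1   # sample: half and half
    k = config.n_clusters_per_stratum
    cluster = np.zeros(n, dtype=int)
    for s in (1, 2):
        idx = np.flatnonzero(stratum == s)
        cluster[idx] = (s - 1) * k + 1 + rng.integers(0, k, size=len(idx))
    w = np.where(stratum == 1, 0.6 / 0.5, 0.4 / 0.5)
    w = w / w.mean()
    # cluster-level shift on every child BMI column
    shifts = rng.normal(scale=0.3, size=2 * k + 1)
    bump = shifts[cluster]
    for c in df.columns:
        if c.startswith("bmi_child_"):
            df[c] = df[c] + bump
    df["stratum"] = stratum
    df["cluster"] = cluster
    df["weight"] = w


def simulate_attrition(df: pd.DataFrame, config: SimConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Participation flags per sweep (Markov in the prior sweep's BMI z).

    Sweep 1 participation is Bernoulli(attrition_base); at sweep t+1 the
    probability is ``attrition_base + attrition_slope * z_t`` clipped to
    [0.01, 0.99], with ``z_t`` the within-cohort standardized child BMI at
    sweep t (the underlying value, whether observed or not).
    """
    ages = np.asarray(config.sweep_ages, dtype=float)
    p0 = config.attrition_base
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("attrition_base must be in [0, 1]")
    if abs(config.attrition_slope) >= 1.0 and p0 in (0.0, 1.0):
        raise ValueError("attrition parameters produce no valid probabilities")
    n = len(df)
    prev_z = None
    for age in ages:
        tag = _age_tag(age)
        if prev_z is None or config.attrition_slope == 0.0:
            p = np.full(n, np.clip(p0, 0.0, 1.0))
        else:
            p = np.clip(p0 + config.attrition_slope * prev_z, 0.01, 0.99)
        df[f"part_{tag}"] = rng.random(n) < p
        prev_z = _standardize(df[f"bmi_child_{tag}"].to_numpy())
    return df


def simulate_cohort(config: SimConfig,
                    seed: int | None = None) -> tuple[TrioCohort, SimTruth]:
    """Draw a complete trio cohort and its generating truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    geno_m, geno_f, beta, freq = draw_founders(config, rng)
    n = config.n_families
    sd_env = config.sd_bmi_parent * np.sqrt(max(0.0, 1.0 - config.h2_bmi))
    # provisional true BMI used for mating (regenerated identically inside
    # simulate_phenotypes would break reproducibility, so pairing uses its
    # own draw of the environmental part and phenotypes are drawn after)
    gv_m = geno_m @ beta
    gv_f = geno_f @ beta
    pheno_m = config.mean_bmi_mother + gv_m + rng.normal(scale=sd_env, size=n)
    pheno_f = config.mean_bmi_father + gv_f + rng.normal(scale=sd_env, size=n)
    perm = pair_mates(pheno_m, pheno_f, config.rho_am, rng)
    geno_f = geno_f[perm]
    pheno_f = pheno_f[perm]
    geno_c = transmit(geno_m, geno_f, rng)

    df = _phenotypes_given_parent_bmi(config, geno_c, beta, pheno_m, pheno_f,
                                      rng)
    simulate_attrition(df, config, rng)

    gv_all = np.concatenate([geno_m @ beta, geno_f @ beta])
    bmi_all = np.concatenate([df["bmi_mother_true"], df["bmi_father_true"]])
    sd_gv = np.std(gv_all)
    lam = 0.0 if sd_gv == 0 else float(
        np.cov(bmi_all, gv_all / sd_gv)[0, 1] / np.var(gv_all / sd_gv))

    snp_ids = np.array([f"rs{i + 1}" for i in range(config.n_snps)])
    pair_idx = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_000_003
    ).integers(0, len(_NONAMBIGUOUS_PAIRS), size=config.n_snps)
    ea = np.array([_NONAMBIGUOUS_PAIRS[i][0] for i in pair_idx], dtype=object)
    oa = np.array([_NONAMBIGUOUS_PAIRS[i][1] for i in pair_idx], dtype=object)

    truth = SimTruth(config=config, snp_beta=beta, snp_freq=freq,
                     effect_allele=ea, other_allele=oa,
                     lambda_first_stage=lam)
    cohort = TrioCohort(snp_ids=snp_ids, geno_mother=geno_m,
                        geno_father=geno_f, geno_child=geno_c, pheno=df)
    return cohort, truth


def _phenotypes_given_parent_bmi(config, geno_c, beta, bmi_m_true, bmi_f_true,
                                 rng) -> pd.DataFrame:
    """As :func:`simulate_phenotypes` but with parental true BMI fixed
    (used after mating so the paired phenotypes are retained)."""
    n = config.n_families
    bmi_m_self = bmi_m_true + config.report_bias
    bmi_f_self = bmi_f_true + config.report_bias
    if config.sigma_report > 0:
        bmi_m_self = bmi_m_self + rng.normal(scale=config.sigma_report, size=n)
        bmi_f_self = bmi_f_self + rng.normal(scale=config.sigma_report, size=n)

    cm = bmi_m_true - config.mean_bmi_mother
    cf = bmi_f_true - config.mean_bmi_father
    gv_c = geno_c @ beta
    z_gc = _standardize(gv_c)

    sex = rng.integers(0, 2, size=n)
    maternal_age = np.clip(rng.normal(29.0, 5.0, size=n), 16.0, 45.0)
    maternal_edu = np.clip(np.round(rng.normal(13.0, 2.5, size=n)), 7, 21)
    class_latent = -0.5 * _standardize(maternal_edu) + rng.normal(size=n)
    if n > 5:
        class_idx = np.digitize(class_latent,
                                np.quantile(class_latent, [0.3, 0.5, 0.65, 0.85]))
    else:
        class_idx = np.zeros(n, dtype=int)
    social_class = np.asarray(_SOCIAL_CLASSES, dtype=object)[class_idx]
    pcs = rng.normal(size=(n, 10))

    df = pd.DataFrame({
        "family_id": np.arange(1, n + 1),
        "bmi_mother_true": bmi_m_true,
        "bmi_father_true": bmi_f_true,
        "bmi_mother_self": bmi_m_self,
        "bmi_father_self": bmi_f_self,
        "child_sex": sex,
        "maternal_age": maternal_age,
        "maternal_edu": maternal_edu,
        "social_class": social_class,
    })
    for j in range(10):
        df[f"pc{j + 1}"] = pcs[:, j]
    df["birthweight"] = (3400.0 + config.beta_bw * cm
                         + rng.normal(scale=450.0, size=n))

    ages = np.asarray(config.sweep_ages, dtype=float)
    deltas, gms, gps = (config.delta_profile, config.gamma_m_profile,
                        config.gamma_p_profile)
    alpha = np.interp(ages, [3, 5, 7, 11, 14, 17],
                      [16.3, 16.0, 16.8, 18.5, 20.5, 22.3])
    sigma = np.interp(ages, [3, 5, 7, 11, 14, 17],
                      [1.4, 1.6, 2.0, 2.6, 3.1, 3.5])
    # residual = persistent child component (tracking) + transient noise,
    # total SD sigma_t per sweep
    a = config.child_track
    persistent = rng.normal(size=n)
    for t, age in enumerate(ages):
        tag = _age_tag(age)
        df[f"age_{tag}"] = age + rng.uniform(-0.25, 0.25, size=n)
        resid = sigma[t] * (a * persistent
                            + np.sqrt(1.0 - a * a) * rng.normal(size=n))
        df[f"bmi_child_{tag}"] = (alpha[t] + deltas[t] * z_gc
                                  + gms[t] * cm + gps[t] * cf
                                  - 0.15 * sex
                                  - 0.02 * (maternal_edu - 13.0)
                                  + resid)

    diet_latent = (-config.diet_c_m * cm - config.diet_c_p * cf
                   + rng.normal(size=n))
    var_d = (config.diet_c_m ** 2 + config.diet_c_p ** 2) \
        * config.sd_bmi_parent ** 2 + 1.0
    for age in ages:
        tag = _age_tag(age)
        for name, loading, k in DIET_ITEMS.get(float(age), []):
            lat = loading * diet_latent + rng.normal(size=n)
            sd_lat = np.sqrt(loading ** 2 * var_d + 1.0)
            if k == 2:
                cuts = np.array([0.0])
            else:
                cuts = stats.norm.ppf(np.linspace(0, 1, k + 1)[1:-1]) * sd_lat
            df[f"diet_{name}_{tag}"] = (np.digitize(lat, cuts) + 1).astype(int)
    df.attrs["diet_latent_var"] = var_d

    _assign_design(df, config, rng)
    return df


# ---------------------------------------------------------------------------
# Discovery GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas(truth: SimTruth, n_discovery: int = 700_000,
                  rng: np.random.Generator | None = None,
                  seed: int | None = None) -> pd.DataFrame:
    """Summary statistics from a virtual discovery GWAS of parental BMI.

    Per-SNP marginal estimates are drawn from the exact sampling
    distribution of single-SNP OLS on an independent discovery sample of
    ``n_discovery`` unrelated adults: ``beta_hat ~ N(beta_j, se_j^2)`` with
    ``se_j^2 = sigma_resid^2 / (n * 2 f_j (1 - f_j))``, and two-sided Wald
    p-values. For independent SNPs this equals materializing the discovery
    cohort, at none of the cost.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cfg = truth.config
    freq = truth.snp_freq
    beta = truth.snp_beta
    var_snp = 2.0 * freq * (1.0 - freq)
    var_y = cfg.sd_bmi_parent ** 2
    resid = np.maximum(var_y - beta ** 2 * var_snp, 1e-12)
    se = np.sqrt(resid / (n_discovery * var_snp))
    beta_hat = rng.normal(beta, se)
    z = beta_hat / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "SNP": [f"rs{i + 1}" for i in range(cfg.n_snps)],
        "A1": truth.effect_allele,
        "A2": truth.other_allele,
        "BETA": beta_hat,
        "P": p,
    })


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_COLUMN_DICT_NOTE = {
    "family_id": "family identifier (int)",
    "bmi_mother_true": "mother's true BMI, kg/m^2",
    "bmi_father_true": "father's true BMI, kg/m^2",
    "bmi_mother_self": "mother's self-reported BMI, kg/m^2",
    "bmi_father_self": "father's self-reported BMI, kg/m^2",
    "child_sex": "child sex, 1 = male",
    "maternal_age": "maternal age at birth, years",
    "maternal_edu": "maternal education, years",
    "social_class": "family social class (5 categories)",
    "birthweight": "child birthweight, grams",
    "weight": "recruitment (design) weight, mean 1",
    "stratum": "sampling stratum id",
    "cluster": "primary sampling unit id",
    "age_<a>": "child age at sweep nominal age <a>, years",
    "bmi_child_<a>": "child BMI at sweep <a>, kg/m^2",
    "part_<a>": "participation flag at sweep <a>",
    "diet_<item>_<a>": "ordinal diet item, healthy-coded (higher = healthier)",
    "pc<k>": "genetic principal component k (generic covariate)",
}


def write_cohort(cohort: TrioCohort, truth: SimTruth | None, path: str,
                 vcf: bool = False) -> None:
    """Write a cohort to ``path/`` as plain-text files.

    Layout: ``genotypes.csv`` (rows keyed by family_id + role), wide
    ``phenotypes.csv``, ``column_dictionary.yaml``, ``truth.yaml`` when
    truth is given, and optionally ``genotypes.vcf`` (minimal VCF 4.2,
    GT only, unphased).
    """
    os.makedirs(path, exist_ok=True)
    frames = []
    for role, g in (("mother", cohort.geno_mother),
                    ("father", cohort.geno_father),
                    ("child", cohort.geno_child)):
        d = pd.DataFrame(g, columns=cohort.snp_ids)
        d.insert(0, "role", role)
        d.insert(0, "family_id", cohort.pheno["family_id"].to_numpy())
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(
        os.path.join(path, "genotypes.csv"), index=False)
    cohort.pheno.to_csv(os.path.join(path, "phenotypes.csv"), index=False)
    with open(os.path.join(path, "column_dictionary.yaml"), "w") as fh:
        yaml.safe_dump(_COLUMN_DICT_NOTE, fh, sort_keys=False)
    if truth is not None:
        with open(os.path.join(path, "truth.yaml"), "w") as fh:
            yaml.safe_dump(truth.to_dict(), fh, sort_keys=False)
    if vcf:
        write_vcf(cohort, os.path.join(path, "genotypes.vcf"),
                  truth=truth)


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(cohort: TrioCohort, path: str,
              truth: SimTruth | None = None) -> None:
    """Minimal VCF 4.2 export: GT only, one sample column per person,
    unphased; ALT is the effect (counted) allele."""
    n = cohort.n_families
    fids = cohort.pheno["family_id"].to_numpy()
    samples = [f"{fid}_{role}" for role in ("mother", "father", "child")
               for fid in fids]
    genos = np.hstack([cohort.geno_mother, cohort.geno_father,
                       cohort.geno_child]).reshape(n, 3, -1)
    if truth is not None:
        ref, alt = truth.other_allele, truth.effect_allele
    else:
        ref = np.full(len(cohort.snp_ids), "A", dtype=object)
        alt = np.full(len(cohort.snp_ids), "G", dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, snp in enumerate(cohort.snp_ids):
            gts = []
            for role_block in range(3):
                col = genos[:, role_block, j]
                gts.extend(_GT[int(v)] for v in col)
            fh.write(f"1\t{j + 1}\t{snp}\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_cohort(path: str) -> tuple[TrioCohort, SimTruth | None]:
    """Read a cohort written by :func:`write_cohort` (lossless round trip)."""
    gpath = os.path.join(path, "genotypes.csv")
    try:
        geno = pd.read_csv(gpath)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"cannot parse {gpath}: {exc}") from exc
    for col in ("family_id", "role"):
        if col not in geno.columns:
            raise ValueError(f"{gpath}: missing required column '{col}'")
    snp_ids = np.array([c for c in geno.columns
                        if c not in ("family_id", "role")])
    blocks = {}
    for role in ("mother", "father", "child"):
        sub = geno[geno["role"] == role].sort_values("family_id")
        blocks[role] = sub[snp_ids].to_numpy(dtype=np.int8)
    pheno = pd.read_csv(os.path.join(path, "phenotypes.csv"))
    pheno = pheno.sort_values("family_id").reset_index(drop=True)
    truth = None
    tpath = os.path.join(path, "truth.yaml")
    if os.path.exists(tpath):
        with open(tpath) as fh:
            truth = SimTruth.from_dict(yaml.safe_load(fh))
    cohort = TrioCohort(snp_ids=snp_ids, geno_mother=blocks["mother"],
                        geno_father=blocks["father"],
                        geno_child=blocks["child"], pheno=pheno)
    return cohort, truth
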