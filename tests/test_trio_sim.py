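"""Simulator: founder genetics, mating, transmission, phenotypes, IO."""

import numpy as np
import pandas as pd
import pytest

import trionurture as tn
from trionurture.trio_sim import _age_tag


class TestSimConfig:
    @pytest.mark.parametrize("kwargs,match", [
        ({"n_snps": 0}, "n_snps"),
        ({"maf_range": (0.0, 0.5)}, "maf_range"),
        ({"h2_bmi": 1.2}, "h2_bmi"),
        ({"rho_am": 1.0}, "rho_am"),
        ({"sweep_ages": (3.0, 3.0)}, "sweep_ages"),
        ({"sigma_report": -1.0}, "sigma_report"),
        ({"gamma_m": (0.1,)}, "gamma_m"),
    ])
    def test_invalid_parameters_are_named(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            tn.SimConfig(**kwargs)

    def test_roundtrips_through_dict(self):
        cfg = tn.SimConfig(n_families=10, gamma_m=(0.1,) * 6, seed=3)
        assert tn.SimConfig.from_dict(cfg.to_dict()) == cfg


class TestDrawFounders:
    def test_hardy_weinberg_at_half(self, rng):
        cfg = tn.SimConfig(n_families=10_000, n_snps=1, maf_range=(0.5, 0.5))
        gm, gf, beta, freq = tn.draw_founders(cfg, rng)
        counts = np.bincount(gm[:, 0], minlength=3) / 10_000
        # (0.25, 0.5, 0.25) within ~4 binomial SEs
        assert np.allclose(counts, [0.25, 0.5, 0.25], atol=0.02)

    def test_zero_heritability_zeroes_effects(self, rng):
        cfg = tn.SimConfig(n_families=50, n_snps=20, h2_bmi=0.0)
        gm, gf, beta, _ = tn.draw_founders(cfg, rng)
        assert np.all(beta == 0.0)
        assert np.all(gm @ beta == 0.0)

    def test_variance_ratio_matches_h2(self):
        cfg = tn.SimConfig(n_families=20_000, n_snps=300, h2_bmi=0.25, seed=5)
        cohort, truth = tn.simulate_cohort(cfg, seed=5)
        gv = cohort.geno_mother @ truth.snp_beta
        ratio = gv.var() / cohort.pheno["bmi_mother_true"].var()
        assert abs(ratio - 0.25) < 0.02


class TestPairMates:
    def test_zero_target_gives_independent_pairing(self, rng):
        m = rng.normal(size=2000)
        f = rng.normal(size=2000)
        perm = tn.pair_mates(m, f, 0.0, rng)
        assert sorted(perm) == list(range(2000))
        assert abs(np.corrcoef(m, f[perm])[0, 1]) < 0.05

    def test_realizes_spousal_correlation(self, rng):
        m = rng.normal(25, 4.3, size=10_000)
        f = rng.normal(26, 4.3, size=10_000)
        perm = tn.pair_mates(m, f, 0.21, rng)
        assert abs(np.corrcoef(m, f[perm])[0, 1] - 0.21) < 0.03

    def test_negative_correlation_supported(self, rng):
        m = rng.normal(size=5000)
        f = rng.normal(size=5000)
        perm = tn.pair_mates(m, f, -0.3, rng)
        r = np.corrcoef(m, f[perm])[0, 1]
        assert abs(r + 0.3) < 0.04

    def test_phenotypic_assortment_leaves_pgi_nearly_uncorrelated(self):
        # spousal BMI correlates ~0.21 yet spousal genetic values barely do
        cfg = tn.SimConfig(n_families=10_000, seed=21)
        cohort, truth = tn.simulate_cohort(cfg, seed=21)
        r_bmi = np.corrcoef(cohort.pheno["bmi_mother_true"],
                            cohort.pheno["bmi_father_true"])[0, 1]
        gv_m = cohort.geno_mother @ truth.snp_beta
        gv_f = cohort.geno_father @ truth.snp_beta
        r_pgi = np.corrcoef(gv_m, gv_f)[0, 1]
        assert abs(r_bmi - 0.21) < 0.03
        assert abs(r_pgi) < 0.05

    def test_rejects_out_of_range_target(self, rng):
        with pytest.raises(ValueError, match="rho_am"):
            tn.pair_mates(np.zeros(4), np.zeros(4), 1.5, rng)


class TestTransmit:
    def test_no_effect_alleles_available(self, rng):
        child = tn.transmit(np.zeros((50, 4), dtype=int),
                            np.zeros((50, 4), dtype=int), rng)
        assert np.all(child == 0)

    def test_double_heterozygote_frequencies(self, rng):
        gm = np.ones((10_000, 1), dtype=int)
        gf = np.ones((10_000, 1), dtype=int)
        child = tn.transmit(gm, gf, rng)
        counts = np.bincount(child[:, 0], minlength=3) / 10_000
        assert np.allclose(counts, [0.25, 0.5, 0.25], atol=0.02)

    def test_rejects_invalid_dosage(self, rng):
        with pytest.raises(ValueError, match="mother"):
            tn.transmit(np.array([[3]]), np.array([[0]]), rng)

    def test_allele_frequency_conserved(self, large_cohort):
        cohort, truth = large_cohort
        n = cohort.n_families
        f_child = cohort.geno_child.mean(axis=0) / 2
        f_founder = truth.snp_freq
        se = np.sqrt(f_founder * (1 - f_founder) / (2 * n))
        assert np.all(np.abs(f_child - f_founder) < 4 * se + 0.01)


class TestPhenotypes:
    def test_null_model_gives_uncorrelated_bmi(self):
        zero = (0.0,) * 6
        cfg = tn.SimConfig(n_families=5000, n_snps=50, delta=zero,
                           gamma_m=zero, gamma_p=zero, rho_am=0.0, seed=9)
        cohort, _ = tn.simulate_cohort(cfg, seed=9)
        df = cohort.pheno
        for parent in ("mother", "father"):
            r = np.corrcoef(df[f"bmi_{parent}_true"], df["bmi_child_17"])[0, 1]
            assert abs(r) < 0.04

    def test_birthweight_slope_recovered_by_ols(self):
        cfg = tn.SimConfig(n_families=20_000, n_snps=50, beta_bw=15.0, seed=13)
        cohort, _ = tn.simulate_cohort(cfg, seed=13)
        df = cohort.pheno
        x = df["bmi_mother_true"] - df["bmi_mother_true"].mean()
        slope = np.cov(x, df["birthweight"])[0, 1] / x.var()
        assert abs(slope - 15.0) < 1.0

    def test_zero_report_error_means_identical_reports(self):
        cfg = tn.SimConfig(n_families=200, n_snps=30, sigma_report=0.0, seed=2)
        cohort, _ = tn.simulate_cohort(cfg, seed=2)
        df = cohort.pheno
        assert np.array_equal(df["bmi_mother_true"], df["bmi_mother_self"])

    def test_report_bias_shifts_mean(self):
        cfg = tn.SimConfig(n_families=5000, n_snps=30, report_bias=-1.0,
                           seed=2)
        cohort, _ = tn.simulate_cohort(cfg, seed=2)
        df = cohort.pheno
        shift = (df["bmi_mother_self"] - df["bmi_mother_true"]).mean()
        assert abs(shift + 1.0) < 0.1


class TestAttrition:
    def test_zero_slope_is_independent_of_bmi(self):
        cfg = tn.SimConfig(n_families=10_000, n_snps=30,
                           attrition_slope=0.0, attrition_base=0.9, seed=4)
        cohort, _ = tn.simulate_cohort(cfg, seed=4)
        df = cohort.pheno
        z = (df["bmi_child_14"] - df["bmi_child_14"].mean()) \
            / df["bmi_child_14"].std()
        part = df["part_17"].astype(float)
        slope = np.cov(z, part)[0, 1] / z.var()
        assert abs(slope) < 0.012

    def test_default_slope_recovered(self):
        cfg = tn.SimConfig(n_families=20_000, n_snps=30, seed=6)
        cohort, _ = tn.simulate_cohort(cfg, seed=6)
        df = cohort.pheno
        z = (df["bmi_child_14"] - df["bmi_child_14"].mean()) \
            / df["bmi_child_14"].std()
        part = df["part_17"].astype(float)
        slope = np.cov(z, part)[0, 1] / z.var()
        assert abs(slope - (-0.034)) < 0.006

    def test_full_participation_when_degenerate(self):
        cfg = tn.SimConfig(n_families=300, n_snps=20, attrition_base=1.0,
                           attrition_slope=0.0, seed=1)
        cohort, _ = tn.simulate_cohort(cfg, seed=1)
        part_cols = [c for c in cohort.pheno.columns if c.startswith("part_")]
        assert cohort.pheno[part_cols].all().all()


class TestCohortIO:
    def test_round_trip_is_lossless(self, small_cohort, tmp_path):
        cohort, truth = small_cohort
        tn.write_cohort(cohort, truth, str(tmp_path / "c"))
        back, truth2 = tn.read_cohort(str(tmp_path / "c"))
        assert np.array_equal(back.geno_mother, cohort.geno_mother)
        assert np.array_equal(back.geno_child, cohort.geno_child)
        pd.testing.assert_frame_equal(back.pheno, cohort.pheno,
                                      check_dtype=False)
        assert np.allclose(truth2.snp_beta, truth.snp_beta)
        assert truth2.config == truth.config

    def test_vcf_gt_mapping(self, tmp_path):
        cfg = tn.SimConfig(n_families=3, n_snps=2, seed=5)
        cohort, truth = tn.simulate_cohort(cfg, seed=5)
        cohort.geno_mother[:, 0] = [2, 1, 0]
        tn.write_cohort(cohort, truth, str(tmp_path / "v"), vcf=True)
        lines = (tmp_path / "v" / "genotypes.vcf").read_text().splitlines()
        row = lines[3].split("\t")       # first variant
        assert row[9:12] == ["1/1", "0/1", "0/0"]   # the three mothers

    def test_vcf_parses_with_cyvcf2(self, tmp_path, small_cohort):
        cyvcf2 = pytest.importorskip("cyvcf2")
        cohort, truth = small_cohort
        tn.write_cohort(cohort, truth, str(tmp_path / "v"), vcf=True)
        v = cyvcf2.VCF(str(tmp_path / "v" / "genotypes.vcf"))
        rec = next(iter(v))
        dosages = np.array([sum(gt[:2]) for gt in rec.genotypes])
        expected = np.concatenate([cohort.geno_mother[:, 0],
                                   cohort.geno_father[:, 0],
                                   cohort.geno_child[:, 0]])
        assert np.array_equal(dosages, expected)

    def test_empty_cohort_round_trips(self, tmp_path):
        cohort = tn.TrioCohort(
            snp_ids=np.array(["rs1"]),
            geno_mother=np.empty((0, 1), dtype=np.int8),
            geno_father=np.empty((0, 1), dtype=np.int8),
            geno_child=np.empty((0, 1), dtype=np.int8),
            pheno=pd.DataFrame({"family_id": pd.Series([], dtype=int)}))
        tn.write_cohort(cohort, None, str(tmp_path / "e"))
        back, _ = tn.read_cohort(str(tmp_path / "e"))
        assert back.n_families == 0

    def test_missing_column_is_a_parse_error(self, tmp_path):
        d = tmp_path / "bad"
        d.mkdir()
        (d / "genotypes.csv").write_text("family_id,rs1\n1,0\n")
        (d / "phenotypes.csv").write_text("family_id\n1\n")
        with pytest.raises(ValueError, match="role"):
            tn.read_cohort(str(d))


def test_cohort_is_bit_reproducible():
    cfg = tn.SimConfig(n_families=150, n_snps=40, seed=99)
    a, ta = tn.simulate_cohort(cfg, seed=99)
    b, tb = tn.simulate_cohort(cfg, seed=99)
    assert np.array_equal(a.geno_child, b.geno_child)
    pd.testing.assert_frame_equal(a.pheno, b.pheno)
    assert np.array_equal(ta.snp_beta, tb.snp_beta)


def test_simulated_gwas_select_matches_brute_force():
    cfg = tn.SimConfig(n_families=10, n_snps=1000, h2_bmi=0.05, seed=3)
    cohort, truth = tn.simulate_cohort(cfg, seed=3)
    ss = tn.SumStats(tn.simulate_gwas(truth, n_discovery=100_000, seed=4))
    sel = tn.select_snps(ss, 5e-8)
    assert len(sel) == int((ss.table["P"] < 5e-8).sum())
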