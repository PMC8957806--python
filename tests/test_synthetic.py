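import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctprs import synthetic as syn
from ctprs.association import roc_auc
from ctprs.selection import APOE_REGION
from ctprs.survival import fit_ph_left_truncated


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"n_samples": 0}, {"n_variants": -1}, {"within_block_r": 1.0},
        {"maf_range": (0.0, 0.3)}, {"maf_range": (0.3, 0.6)},
        {"prevalence": 0.0}, {"prevalence": 1.0}, {"baseline_hazard": -0.1},
        {"causal_fraction": 1.5},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            syn.SimulationConfig(**kwargs)


class TestGenotypes:
    def test_independent_blocks_have_no_ld(self):
        cfg = syn.SimulationConfig(n_samples=5000, n_variants=50,
                                   within_block_r=0.0, seed=1)
        gm = syn.simulate_genotypes(cfg)
        r = np.corrcoef(gm.dosages.T)
        off = r[np.triu_indices(50, 1)]
        assert np.mean(off ** 2) < 0.01

    def test_within_block_r2_hits_target(self):
        """Realized dosage r^2 tracks the configured within-block
        correlation (Monte Carlo over 10 seeds)."""
        r2s = []
        for seed in range(10):
            cfg = syn.SimulationConfig(n_samples=5000, n_variants=50,
                                       block_size=10, within_block_r=0.9,
                                       seed=seed)
            gm = syn.simulate_genotypes(cfg)
            for s in range(0, 50, 10):
                c = np.corrcoef(gm.dosages[:, s:s + 10].T)
                r2s.append(np.mean(c[np.triu_indices(10, 1)] ** 2))
        assert 0.7 < np.mean(r2s) < 0.95

    def test_allele_frequency_within_binomial_bound(self):
        cfg = syn.SimulationConfig(n_samples=5000, n_variants=40,
                                   maf_range=(0.3, 0.3), seed=2)
        gm = syn.simulate_genotypes(cfg)
        af = gm.dosages.mean(axis=0) / 2
        se = np.sqrt(0.3 * 0.7 / (2 * 5000))
        # block-sharing makes allele draws within a block correlated, which
        # widens the effective SE; bound per variant stays generous
        assert np.all(np.abs(af - 0.3) < 6 * se)
        assert abs(af.mean() - 0.3) < 3 * se

    def test_hardcall_values_and_dosage_mode_range(self):
        cfg = syn.SimulationConfig(n_samples=100, n_variants=30, seed=3)
        gm = syn.simulate_genotypes(cfg)
        assert set(np.unique(gm.dosages)) <= {0.0, 1.0, 2.0}
        cfg2 = syn.SimulationConfig(n_samples=100, n_variants=30, seed=3,
                                    dosage_mode="dosage")
        gm2 = syn.simulate_genotypes(cfg2)
        assert gm2.dosages.min() >= 0 and gm2.dosages.max() <= 2
        assert len(np.unique(gm2.dosages)) > 3

    def test_map_covers_apoe_window(self):
        cfg = syn.SimulationConfig(n_samples=10, n_variants=5000, seed=4)
        gm = syn.simulate_genotypes(cfg)
        v = gm.variants
        inside = APOE_REGION.contains(v["chrom"], v["pos"])
        assert inside.sum() >= 10


class TestSummaryStats:
    def test_null_p_values_uniform(self):
        fracs = []
        for seed in range(10):
            cfg = syn.SimulationConfig(n_samples=10, n_variants=1000,
                                       causal_fraction=0.0, seed=seed)
            gm = syn.simulate_genotypes(cfg)
            ss = syn.simulate_summary_stats(np.zeros(1000), gm.variants, cfg)
            fracs.append((ss["p"] < 0.05).mean())
        assert 0.04 < np.mean(fracs) < 0.06

    def test_se_scales_with_gwas_size(self):
        cfg1 = syn.SimulationConfig(n_samples=10, n_variants=500, seed=5,
                                    n_gwas=50_000)
        cfg2 = syn.SimulationConfig(n_samples=10, n_variants=500, seed=5,
                                    n_gwas=100_000)
        gm = syn.simulate_genotypes(cfg1)
        se1 = syn.simulate_summary_stats(np.zeros(500), gm.variants, cfg1)["se"]
        se2 = syn.simulate_summary_stats(np.zeros(500), gm.variants, cfg2)["se"]
        ratio = np.median(se2 / se1)
        assert abs(ratio - 1 / np.sqrt(2)) < 0.05 / np.sqrt(2)

    def test_or_column_consistency_and_info_range(self):
        cfg = syn.SimulationConfig(n_samples=10, n_variants=200, seed=6)
        gm = syn.simulate_genotypes(cfg)
        truth = syn.simulate_truth(cfg)
        ss = syn.simulate_summary_stats(truth, gm.variants, cfg)
        assert ss["info"].between(0.5, 1.0).all()
        # two-sided normal p consistent with beta/se
        z = np.abs(ss["beta"] / ss["se"])
        np.testing.assert_allclose(ss["p"], 2 * stats.norm.sf(z), rtol=1e-10)

    def test_length_mismatch_error(self):
        cfg = syn.SimulationConfig(n_samples=10, n_variants=100, seed=7)
        gm = syn.simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="length"):
            syn.simulate_summary_stats(np.zeros(99), gm.variants, cfg)


class TestPhenotype:
    def test_null_heritability_uncorrelated(self):
        cfg = syn.SimulationConfig(n_samples=10_000, n_variants=100,
                                   causal_fraction=0.0, seed=8)
        gm = syn.simulate_genotypes(cfg)
        cohort = syn.simulate_phenotype(gm, np.zeros(100), cfg)
        # correlate case status with any genotype-derived score
        score = gm.dosages @ np.ones(100)
        r = np.corrcoef(score, cohort["case"])[0, 1]
        assert abs(r) < 0.03

    def test_case_fraction_matches_prevalence(self):
        cfg = syn.SimulationConfig(n_samples=10_000, n_variants=100, seed=9)
        gm = syn.simulate_genotypes(cfg)
        cohort = syn.simulate_phenotype(gm, syn.simulate_truth(cfg), cfg)
        se = np.sqrt(0.36 * 0.64 / 10_000)
        assert abs(cohort["case"].mean() - 0.36) < 3 * se

    def test_covariate_marginals(self):
        cfg = syn.SimulationConfig(n_samples=20_000, n_variants=50, seed=10)
        gm = syn.simulate_genotypes(cfg)
        cohort = syn.simulate_phenotype(gm, syn.simulate_truth(cfg), cfg)
        assert cohort["baseline_age"].mean() == pytest.approx(81.5, abs=0.2)
        assert cohort["education"].std() == pytest.approx(3.7, abs=0.1)
        assert cohort["e4_count"].isin([0, 1, 2]).all()
        assert set(cohort["apoe_genotype"]) <= {22, 23, 33, 24, 34, 44}

    def test_auc_monotone_in_genetic_variance(self):
        """Mean downstream AUC of the true score strictly increases with
        causal_fraction * effect_sd^2."""
        means = []
        for effect_sd in (0.0, 0.03, 0.08):
            aucs = []
            for seed in range(10):
                cfg = syn.SimulationConfig(
                    n_samples=2000, n_variants=200, causal_fraction=0.2,
                    effect_sd=effect_sd, covariate_effects={}, seed=200 + seed)
                gm = syn.simulate_genotypes(cfg)
                truth = syn.simulate_truth(cfg)
                cohort = syn.simulate_phenotype(gm, truth, cfg)
                if effect_sd == 0.0:
                    score = gm.dosages @ np.ones(200)  # no true score exists
                else:
                    score = cohort["genetic_score"]
                aucs.append(roc_auc(score, cohort["case"]).auc)
            means.append(np.mean(aucs))
        assert means[0] < means[1] < means[2]
        assert abs(means[0] - 0.5) < 0.02


class TestOnset:
    def test_null_hazard_recovered(self):
        # single-seed estimates have SE ~0.028, so average a few seeds
        coefs = []
        for seed in (11, 12, 13):
            cfg = syn.SimulationConfig(n_samples=5000, n_variants=60,
                                       prs_log_hazard=0.0, seed=seed)
            _, _, cohort, _ = syn.simulate_cohort(cfg)
            rep = fit_ph_left_truncated(
                cohort.assign(prs=cohort["genetic_score"]), ["prs"])
            coefs.append(rep.terms.loc["prs", "coef"])
        assert abs(np.mean(coefs)) < 0.05

    def test_zero_baseline_hazard_all_censored(self):
        cfg = syn.SimulationConfig(n_samples=500, n_variants=40,
                                   baseline_hazard=0.0, seed=12)
        _, _, cohort, _ = syn.simulate_cohort(cfg)
        assert cohort["event"].sum() == 0

    def test_truncation_contract(self):
        cfg = syn.SimulationConfig(n_samples=2000, n_variants=40, seed=13)
        _, _, cohort, _ = syn.simulate_cohort(cfg)
        assert (cohort["entry_age"] < cohort["event_or_censor_age"]).all()
        assert (cohort["entry_age"] > 0).all()

    def test_misaligned_scores_rejected(self):
        cfg = syn.SimulationConfig(n_samples=50, n_variants=40, seed=14)
        gm = syn.simulate_genotypes(cfg)
        cohort = syn.simulate_phenotype(gm, syn.simulate_truth(cfg), cfg)
        with pytest.raises(ValueError, match="aligned"):
            syn.simulate_onset(cohort, np.zeros(10), cfg)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        cfg = syn.SimulationConfig(n_samples=300, n_variants=120, seed=42)
        a = syn.simulate_cohort(cfg)
        b = syn.simulate_cohort(cfg)
        np.testing.assert_array_equal(a[0].dosages, b[0].dosages)
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2], b[2])
        np.testing.assert_array_equal(a[3], b[3])

    def test_different_seed_differs(self):
        a = syn.simulate_cohort(syn.SimulationConfig(n_samples=100,
                                                     n_variants=60, seed=1))
        b = syn.simulate_cohort(syn.SimulationConfig(n_samples=100,
                                                     n_variants=60, seed=2))
        assert not np.array_equal(a[0].dosages, b[0].dosages)

    def test_null_model_standalone_auc_calibrated(self):
        """With zero effects everywhere, a PRS built from the noisy summary
        statistics carries no signal."""
        aucs = []
        for seed in range(3):
            cfg = syn.SimulationConfig(n_samples=10_000, n_variants=200,
                                       causal_fraction=0.0,
                                       covariate_effects={}, seed=300 + seed)
            gm = syn.simulate_genotypes(cfg)
            truth = syn.simulate_truth(cfg)
            ss = syn.simulate_summary_stats(truth, gm.variants, cfg)
            cohort = syn.simulate_phenotype(gm, truth, cfg)
            prs = gm.dosages @ ss["beta"].to_numpy()
            aucs.append(roc_auc(prs, cohort["case"]).auc)
        assert all(0.47 < a < 0.53 for a in aucs)
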