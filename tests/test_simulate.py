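"""Synthetic generator: determinism, LD structure, marginal calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import triowa
from triowa import SimulationConfig, OutcomeTruth, PNS_CODE
from triowa.simulate import ITEM_NAMES


class TestConfigValidation:
    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_individuals=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_variants=-1)

    def test_rejects_bad_probabilities(self):
        with pytest.raises(ValueError):
            SimulationConfig(ld_rho=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(pns_rate=0.02)
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.3, 0.1))

    def test_rejects_nonincreasing_item_thresholds(self):
        t = np.tile([0.0, 1.0, 1.0, 2.0], (5, 1))
        with pytest.raises(ValueError):
            SimulationConfig(item_thresholds=t)

    def test_outcome_truth_invariants(self):
        with pytest.raises(ValueError):
            OutcomeTruth(name="x", family_truth="binary", base_rate=1.5)
        with pytest.raises(ValueError):
            OutcomeTruth(name="x", family_truth="categorical", k=2)


class TestGenotypes:
    def test_independent_variants_uncorrelated(self):
        cfg = SimulationConfig(n_individuals=5000, n_variants=40, ld_rho=0.0, seed=1)
        d = triowa.simulate_genotypes(cfg).dosages.to_numpy(float)
        corr = np.corrcoef(d.T)
        off = np.abs(corr[np.triu_indices(40, 1)])
        assert off.mean() < 0.05

    def test_block_ld_tracks_generating_correlation(self):
        cfg = SimulationConfig(n_individuals=5000, n_variants=50, block_size=10,
                               ld_rho=0.8, seed=2)
        d = triowa.simulate_genotypes(cfg).dosages.to_numpy(float)
        adj = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1]
               for b in range(5) for j in range(b * 10, b * 10 + 9)]
        assert 0.7 <= np.mean(adj) <= 0.9

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_individuals=500, n_variants=20, seed=7)
        a = triowa.simulate_genotypes(cfg)
        b = triowa.simulate_genotypes(cfg)
        assert a.dosages.equals(b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_empirical_mafs_within_range(self):
        cfg = SimulationConfig(n_individuals=8000, n_variants=40,
                               maf_range=(0.1, 0.4), seed=3)
        v = triowa.simulate_genotypes(cfg).variants
        assert (v["MAF"] > 0.1 - 0.03).all() and (v["MAF"] < 0.4 + 0.03).all()

    def test_positions_increase_within_chromosome(self, small_panel):
        for _, grp in small_panel.variants.groupby("CHR"):
            assert grp["POS"].is_monotonic_increasing


class TestCohort:
    def test_no_heritability_decouples_score_from_liability(self):
        cfg = SimulationConfig(n_individuals=10000, n_variants=20,
                               h2_liability=0.0, seed=4)
        panel = triowa.simulate_genotypes(cfg)
        coh = triowa.simulate_cohort(cfg, panel)
        r = np.corrcoef(coh.truth["score_std"], coh.truth["liability"])[0, 1]
        assert abs(r) < 0.03

    def test_binary_base_rate_calibrated(self):
        cfg = SimulationConfig(
            n_individuals=10000, n_variants=16, seed=5,
            outcome_specs=[OutcomeTruth(name="y", family_truth="binary",
                                        base_rate=0.30)])
        coh = triowa.simulate_cohort(cfg, triowa.simulate_genotypes(cfg))
        assert coh.data["y"].mean() == pytest.approx(0.30, abs=0.02)

    def test_logistic_fit_recovers_generating_log_odds_ratio(self):
        # parameter-recovery oracle: complete-data logistic regression on
        # the generating count should recover the planted log-OR
        import statsmodels.api as sm
        effect = np.log(1.5)
        ests, ses = [], []
        for seed in range(4):
            cfg = SimulationConfig(
                n_individuals=8000, n_variants=16, seed=seed,
                outcome_specs=[OutcomeTruth(name="y", family_truth="binary",
                                            base_rate=0.08,
                                            true_effect_exposure=effect)])
            coh = triowa.simulate_cohort(cfg, triowa.simulate_genotypes(cfg))
            x = np.minimum(coh.truth["count_true"], 4).astype(float)
            X = sm.add_constant(x)
            res = sm.GLM(coh.data["y"], X, family=sm.families.Binomial()).fit()
            ests.append(res.params.iloc[1])
            ses.append(res.bse.iloc[1])
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(effect, abs=2 * max(mc_se, np.mean(ses)))

    def test_item_scale_and_panel_size_checks(self, small_config, small_panel):
        coh = triowa.simulate_cohort(small_config, small_panel)
        items = coh.data[list(ITEM_NAMES)].to_numpy()
        assert items.min() >= 1 and items.max() <= 5
        bad = SimulationConfig(n_individuals=123, n_variants=24, block_size=4)
        with pytest.raises(ValueError):
            triowa.simulate_cohort(bad, small_panel)

    def test_cohort_determinism(self, small_config, small_panel):
        a = triowa.simulate_cohort(small_config, small_panel)
        b = triowa.simulate_cohort(small_config, small_panel)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestGwasEmulation:
    def test_null_pvalues_uniform(self):
        cfg = SimulationConfig(n_individuals=200, n_variants=1000, block_size=4,
                               ld_rho=0.0, n_causal=1, seed=6)
        panel = triowa.simulate_genotypes(cfg)
        ss = triowa.emulate_gwas(cfg, panel)
        null_p = ss.loc[panel.variants["beta_liability"] == 0, "P"]
        frac = (null_p < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_strong_causal_variant_reaches_genome_wide_significance(self):
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(n_individuals=200, n_variants=8, block_size=4,
                                   n_causal=2, gwas_n=200_000, seed=seed)
            panel = triowa.simulate_genotypes(cfg)
            ss = triowa.emulate_gwas(cfg, panel)
            causal = panel.variants["beta_liability"].abs() > 0
            strong = causal & (panel.variants["beta_liability"].abs()
                               > 5 * ss["SE"])
            if strong.any():
                hits += int((ss.loc[strong, "P"] < 5e-8).all())
        assert hits >= 9

    def test_se_matches_closed_form(self, small_config, small_panel):
        ss = triowa.emulate_gwas(small_config, small_panel)
        maf = ss["MAF"].to_numpy()
        expected = 1 / np.sqrt(small_config.gwas_n * 2 * maf * (1 - maf))
        np.testing.assert_allclose(ss["SE"], expected, rtol=1e-12)


class TestMissingness:
    def test_zero_rates_leave_cohort_unchanged(self, small_config, small_panel):
        coh = triowa.simulate_cohort(small_config, small_panel)
        cfg = SimulationConfig(**{**small_config.__dict__,
                                  "missing_rate_covariates": 0.0, "pns_rate": 0.0})
        out = triowa.inject_missingness(coh, cfg)
        pd.testing.assert_frame_equal(out.data, coh.data)

    def test_mar_rate_calibrated(self):
        cfg = SimulationConfig(n_individuals=10000, n_variants=16, seed=8,
                               missing_rate_covariates={"birthweight": 0.2})
        coh = triowa.simulate_cohort(cfg, triowa.simulate_genotypes(cfg))
        out = triowa.inject_missingness(coh, cfg)
        assert out.data["birthweight"].isna().mean() == pytest.approx(0.20, abs=0.01)
        assert "orig_birthweight" in out.truth.columns

    def test_missingness_depends_on_age(self):
        # MAR mechanism: older individuals should be missing more often
        cfg = SimulationConfig(n_individuals=20000, n_variants=16, seed=9,
                               missing_rate_covariates={"birthweight": 0.3})
        coh = triowa.simulate_cohort(cfg, triowa.simulate_genotypes(cfg))
        out = triowa.inject_missingness(coh, cfg)
        miss = out.data["birthweight"].isna()
        old = out.data["age_enrollment"] > out.data["age_enrollment"].median()
        assert miss[old].mean() > miss[~old].mean() + 0.02

    def test_prefer_not_to_say_rate_below_one_percent(self):
        cfg = SimulationConfig(n_individuals=10000, n_variants=16, seed=10,
                               pns_rate=0.005)
        coh = triowa.simulate_cohort(cfg, triowa.simulate_genotypes(cfg))
        out = triowa.inject_missingness(coh, cfg)
        for item in ITEM_NAMES:
            assert (out.data[item] == PNS_CODE).mean() < 0.01
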