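import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mstarr.core import ConfigurationError
from mstarr.simulate import (MethylationSimConfig, SimConfig,
                             simulate_counts, simulate_features,
                             simulate_library, simulate_luciferase,
                             simulate_methylation, simulate_monocyte_pairs)


class TestSimulateLibrary:
    def test_degenerate_no_enhancers(self):
        cfg = SimConfig(n_windows=500, enhancer_fraction=0.0, seed=1)
        _, truth = simulate_library(cfg)
        f = truth.frame
        assert (f.activity_multiplier_unmeth == 1.0).all()
        assert (f.activity_multiplier_meth == 1.0).all()
        assert not f.is_md.any()

    def test_direction_split_within_binomial_interval(self):
        # enough windows that ~1000+ MD windows are drawn
        cfg = SimConfig(n_windows=100_000, enhancer_fraction=0.2,
                        md_fraction_of_enhancers=0.5, seed=2)
        _, truth = simulate_library(cfg)
        md = truth.frame[truth.frame.is_md]
        n = len(md)
        assert n >= 1000
        k = md.md_unmeth_higher.sum()
        lo = stats.binom.ppf(0.005, n, 0.86)
        hi = stats.binom.ppf(0.995, n, 0.86)
        assert lo <= k <= hi

    def test_same_seed_identical_truth(self):
        cfg = SimConfig(n_windows=300, seed=5)
        _, t1 = simulate_library(cfg)
        _, t2 = simulate_library(cfg)
        assert t1.frame.equals(t2.frame)

    def test_cpg_free_windows_never_md(self):
        cfg = SimConfig(n_windows=20_000, enhancer_fraction=0.5,
                        md_fraction_of_enhancers=0.5,
                        cpg_density_model={"mean_cpg": 0.5, "slope": 2.0}, seed=3)
        _, truth = simulate_library(cfg)
        f = truth.frame
        assert not f.loc[f.cpg_count == 0, "is_md"].any()
        assert f.is_md.sum() > 0

    def test_md_implies_enhancer_and_positive_multipliers(self):
        cfg = SimConfig(n_windows=5000, seed=4)
        _, truth = simulate_library(cfg)
        f = truth.frame
        assert (f.is_md <= f.is_enhancer).all()
        assert (f.activity_multiplier_unmeth > 0).all()
        assert (f.activity_multiplier_meth > 0).all()

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="enhancer_fraction"):
            simulate_library(SimConfig(enhancer_fraction=1.5))
        with pytest.raises(ConfigurationError, match="dispersion"):
            simulate_library(SimConfig(dispersion=-1.0))


class TestSimulateCounts:
    def test_poisson_limit_ratio_recovery(self):
        """One 4x window: empirical RNA/DNA ratio within 10% of 4."""
        ratios = []
        for seed in range(50):
            cfg = SimConfig(n_windows=50, seed=seed, dispersion=np.inf,
                            mean_depth=1e7, enhancer_fraction=0.0)
            _, truth = simulate_library(cfg)
            truth.frame.iloc[0, truth.frame.columns.get_loc("activity_multiplier_unmeth")] = 4.0
            truth.frame.iloc[0, truth.frame.columns.get_loc("activity_multiplier_meth")] = 4.0
            counts = simulate_counts(truth, cfg)
            s = counts.samples
            rna = counts.counts.loc[:, s.type == "RNA"].iloc[0].mean()
            dna = counts.counts.loc[:, s.type == "DNA"].iloc[0].mean()
            ratios.append(rna / dna)
        assert abs(np.mean(ratios) - 4.0) / 4.0 < 0.10

    def test_null_ratio_centered_at_one(self):
        cfg = SimConfig(n_windows=200, seed=6, mean_depth=1e7,
                        enhancer_fraction=0.0, dispersion=np.inf)
        _, truth = simulate_library(cfg)
        counts = simulate_counts(truth, cfg)
        s = counts.samples
        rna = counts.counts.loc[:, s.type == "RNA"].mean(axis=1)
        dna = counts.counts.loc[:, s.type == "DNA"].mean(axis=1)
        assert np.median(rna / dna) == pytest.approx(1.0, abs=0.05)

    def test_dropped_replicate_absent(self):
        cfg = SimConfig(n_windows=50, seed=7,
                        dropped_reps=[("methylated", 3)])
        _, truth = simulate_library(cfg)
        counts = simulate_counts(truth, cfg)
        s = counts.samples
        # 11 replicates x 2 types instead of 12 x 2
        assert counts.n_samples == 22
        assert not ((s.condition == "methylated") & (s.replicate == 3)).any()

    def test_negative_binomial_moments(self):
        """Sample moments match NB(mean, dispersion) within Monte Carlo error."""
        cfg = SimConfig(n_windows=2, seed=8, dispersion=5.0, mean_depth=2e5,
                        enhancer_fraction=0.0)
        _, truth = simulate_library(cfg)
        p = truth.frame.baseline_propensity.to_numpy()
        draws = []
        for seed in range(300):
            c2 = SimConfig(n_windows=2, seed=seed, dispersion=5.0, mean_depth=2e5,
                           enhancer_fraction=0.0)
            _, t2 = simulate_library(c2)
            t2.frame["baseline_propensity"] = p
            draws.append(simulate_counts(t2, c2).counts.iloc[0, 0])
        draws = np.array(draws)
        mu = 2e5 * p[0]
        var_expected = mu + mu ** 2 / 5.0
        assert abs(draws.mean() - mu) / mu < 0.1
        assert 0.5 < draws.var() / var_expected < 2.0


class TestSimulateFeatures:
    def test_no_informative_features_chance_accuracy(self):
        cfg = SimConfig(n_windows=1200, enhancer_fraction=1.0,
                        md_fraction_of_enhancers=0.5, seed=9)
        _, truth = simulate_library(cfg)
        table = simulate_features(truth, n_features=10, n_informative=0, seed=9)
        # labels exchangeable with features: correlation ~ 0
        r = [abs(np.corrcoef(table.is_md, table[c])[0, 1])
             for c in table.columns if c != "is_md"]
        assert max(r) < 0.1

    def test_effect_size_realized_in_class_means(self):
        cfg = SimConfig(n_windows=4000, enhancer_fraction=1.0,
                        md_fraction_of_enhancers=0.5, seed=10)
        _, truth = simulate_library(cfg)
        table = simulate_features(truth, n_features=5, n_informative=1,
                                  effect_size=2.0, seed=10)
        diff = (table.loc[table.is_md, "informative_1"].mean()
                - table.loc[~table.is_md, "informative_1"].mean())
        assert diff == pytest.approx(2.0, rel=0.10)

    def test_missing_fraction(self):
        cfg = SimConfig(n_windows=1000, seed=11)
        _, truth = simulate_library(cfg)
        table = simulate_features(truth, n_features=20, n_informative=2,
                                  missing_fraction=0.1, seed=11)
        frac = table.drop(columns="is_md").isna().to_numpy().mean()
        assert frac == pytest.approx(0.1, abs=0.01)

    def test_informative_exceeding_total_rejected(self):
        cfg = SimConfig(n_windows=100, seed=12)
        _, truth = simulate_library(cfg)
        with pytest.raises(ConfigurationError):
            simulate_features(truth, n_features=5, n_informative=6)


class TestSimulateMethylation:
    def _truth(self, n=500, seed=13):
        cfg = SimConfig(n_windows=n, seed=seed)
        return simulate_library(cfg)[1]

    def test_zero_drift_post_equals_pre(self):
        truth = self._truth()
        mcfg = MethylationSimConfig(baseline_rate=0.0, error_rate=0.0,
                                    coverage=200.0, seed=13)
        sim = simulate_methylation(truth, mcfg)
        level = sim.meth / np.maximum(sim.total, 1)
        # expectation equals pre exactly; observed binomial means close
        assert np.nanmax(np.abs(sim.post_level_true - sim.pre_level)) == 0.0
        assert abs(level.mean() - sim.pre_level.mean()) < 0.02

    def test_tfbs_demethylation_rate_recovered(self):
        truth = self._truth(n=2000, seed=14)
        mcfg = MethylationSimConfig(tfbs_rates={"GATA1": 0.3},
                                    baseline_rate=0.0, error_rate=0.0,
                                    coverage=50.0, sites_per_window=2.0, seed=14)
        sim = simulate_methylation(truth, mcfg)
        meth_cols = (sim.samples.condition == "methylated").to_numpy()
        in_tf = (sim.sites.tf == "GATA1").to_numpy()
        assert in_tf.sum() >= 500
        lev = sim.meth[np.ix_(in_tf, meth_cols)] / np.maximum(
            sim.total[np.ix_(in_tf, meth_cols)], 1)
        endog = sim.sites.endogenous[in_tf].mean()
        expected = 1.0 + 0.3 * (endog - 1.0)
        assert abs(lev.mean() - expected) < 0.03

    def test_spikein_conversion_efficiency(self):
        from mstarr.methylation import conversion_efficiency
        truth = self._truth()
        mcfg = MethylationSimConfig(error_rate=0.003, n_spikein=5000,
                                    coverage=50.0, seed=15)
        sim = simulate_methylation(truth, mcfg)
        spike = sim.sites.is_spikein.to_numpy()
        eff = conversion_efficiency(sim.meth[spike], sim.total[spike])
        assert np.all(eff > 0.995)
        assert np.allclose(eff, 0.997, atol=0.002)


class TestSimulateMonocytePairs:
    def test_null_mean_rho_near_zero(self):
        meth, expr, flags = simulate_monocyte_pairs(
            n_individuals=300, n_pairs=10_000, causal_fraction=0.0, seed=16)
        m = meth.to_numpy()
        e = expr.to_numpy()
        mc = m - m.mean(1, keepdims=True)
        ec = e - e.mean(1, keepdims=True)
        r = (mc * ec).sum(1) / np.sqrt((mc ** 2).sum(1) * (ec ** 2).sum(1))
        assert abs(r.mean()) < 0.01

    def test_strong_causal_rho_recovered(self):
        meth, expr, flags = simulate_monocyte_pairs(
            n_individuals=1200, n_pairs=500, causal_fraction=1.0,
            rho_causal=-0.9, seed=17)
        m = meth.to_numpy()
        e = expr.to_numpy()
        mc = m - m.mean(1, keepdims=True)
        ec = e - e.mean(1, keepdims=True)
        r = (mc * ec).sum(1) / np.sqrt((mc ** 2).sum(1) * (ec ** 2).sum(1))
        assert (r < -0.8).mean() > 0.95

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_monocyte_pairs(n_individuals=2, n_pairs=10)


class TestSimulateLuciferase:
    def test_noiseless_recovery_by_mixed_model(self):
        from mstarr.invivo import luciferase_mixed_model
        est = np.linspace(-1, 3, 18)
        table, truth = simulate_luciferase(est, batch_sd=0.0, noise_sd=0.0,
                                           seed=18)
        fit = luciferase_mixed_model(table)
        slope = fit.fixed_effects["mstarr_estimate"]
        assert slope == pytest.approx(truth["slope"], abs=1e-5)

    def test_replicate_counts_between_six_and_eight(self):
        est = np.linspace(0, 2, 18)
        table, _ = simulate_luciferase(est, seed=19)
        per = table.groupby("construct").size()
        assert per.between(6, 8).all()

    def test_batch_variance_recovered_over_seeds(self):
        from mstarr.invivo import luciferase_mixed_model
        est = np.linspace(-1, 3, 18)
        vars_ = []
        for seed in range(20):
            table, _ = simulate_luciferase(est, batch_sd=1.0, noise_sd=0.3,
                                           seed=seed)
            fit = luciferase_mixed_model(table)
            vars_.append(fit.batch_variance)
        assert abs(np.mean(vars_) - 1.0) < 0.5
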