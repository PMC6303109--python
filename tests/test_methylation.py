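import numpy as np
import pandas as pd
import pytest
from itertools import permutations
from scipy import stats

from mstarr.core import InputError
from mstarr.methylation import (conversion_efficiency,
                                convergence_correlation,
                                demethylation_logistic, ifna_effect,
                                ifna_methylation_coupling, methylation_level,
                                site_mean_levels, tfbs_methylation_delta,
                                top_k_family_enrichment)


class TestMethylationLevel:
    def test_simple_fraction(self):
        assert methylation_level(5, 10) == pytest.approx(0.5)

    def test_zero_coverage_absent(self):
        assert np.isnan(methylation_level(0, 0))

    def test_coverage_floor(self):
        assert np.isnan(methylation_level(2, 4, min_cov=5))
        assert methylation_level(2, 5, min_cov=5) == pytest.approx(0.4)

    def test_meth_exceeding_total_rejected(self):
        with pytest.raises(InputError):
            methylation_level(6, 5)


class TestConversionEfficiency:
    def test_closed_form(self):
        assert conversion_efficiency([[2]], [[1000]])[0] == pytest.approx(0.998)

    def test_perfect_conversion(self):
        assert conversion_efficiency([[0], [0]], [[500], [500]])[0] == 1.0

    def test_scale_invariance(self):
        m = np.array([[3], [1], [2]])
        t = np.array([[100], [200], [300]])
        assert conversion_efficiency(m, t)[0] == pytest.approx(
            conversion_efficiency(m * 10, t * 10)[0])

    def test_zero_coverage_absent(self):
        assert np.isnan(conversion_efficiency([[0]], [[0]])[0])

    def test_simulated_error_rate_calibration(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            total = np.full((10_000, 1), 1)
            meth = rng.binomial(total, 0.003)
            hits += conversion_efficiency(meth, total)[0] > 0.995
        assert hits >= 19


class TestConvergenceCorrelation:
    def test_identity_rho_one(self):
        x = np.linspace(0, 1, 50)
        rho, _ = convergence_correlation(x, x)
        assert rho == pytest.approx(1.0)

    def test_independent_null(self):
        rng = np.random.default_rng(1)
        rho, _ = convergence_correlation(rng.random(10_000), rng.random(10_000))
        assert abs(rho) < 0.05

    def test_drift_toward_endogenous_positive(self):
        rng = np.random.default_rng(2)
        endo = rng.random(5000)
        post = 1.0 + 0.3 * (endo - 1.0) + rng.normal(0, 0.05, 5000)
        rho, p = convergence_correlation(post, endo)
        assert rho > 0.5
        assert p < 1e-10

    def test_too_few_sites_rejected(self):
        with pytest.raises(InputError):
            convergence_correlation(np.ones(5), np.ones(5))


class TestSpearmanOracle:
    def test_matches_exhaustive_rank_oracle_with_ties(self):
        """scipy Spearman equals the rank-then-Pearson definition exactly."""
        rng = np.random.default_rng(3)
        for n in (4, 6, 9, 12):
            for _ in range(20):
                x = rng.integers(0, 4, size=n).astype(float)  # heavy ties
                y = rng.integers(0, 4, size=n).astype(float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
                rx = stats.rankdata(x)  # average ranks
                ry = stats.rankdata(y)
                expect = np.corrcoef(rx, ry)[0, 1]
                got = stats.spearmanr(x, y).statistic
                assert got == pytest.approx(expect, abs=1e-12)


class TestTfbsDelta:
    def test_no_drift_zero_delta(self):
        init = np.ones(500)
        post = np.ones(500)
        tf = np.array(["A"] * 250 + ["B"] * 250, dtype=object)
        d = tfbs_methylation_delta(init, post, tf, min_sites=100)
        assert np.allclose(d, 0.0)

    def test_simulated_demethylation_recovered(self):
        rng = np.random.default_rng(4)
        n = 500
        init = np.ones(n)
        # -0.3 mean change observed through binomial sampling at coverage 50
        post = rng.binomial(50, 0.7, size=n) / 50.0
        tf = np.array(["GATA1"] * n, dtype=object)
        d = tfbs_methylation_delta(init, post, tf, min_sites=100)
        assert d["GATA1"] == pytest.approx(-0.3, abs=0.03)

    def test_below_min_sites_omitted(self):
        init = np.zeros(199)
        post = np.zeros(199)
        tf = np.array(["A"] * 100 + ["B"] * 99, dtype=object)
        d = tfbs_methylation_delta(init, post, tf, min_sites=100)
        assert "A" in d.index
        assert "B" not in d.index

    def test_pooled_delta_is_coverage_weighted_mean(self):
        init = np.zeros(400)
        post = np.concatenate([np.full(300, 0.2), np.full(100, 0.6)])
        tf_sep = np.array(["A"] * 300 + ["B"] * 100, dtype=object)
        tf_pool = np.array(["AB"] * 400, dtype=object)
        sep = tfbs_methylation_delta(init, post, tf_sep, min_sites=50)
        pool = tfbs_methylation_delta(init, post, tf_pool, min_sites=50)
        weighted = (300 * sep["A"] + 100 * sep["B"]) / 400
        assert pool["AB"] == pytest.approx(weighted, abs=1e-12)

    def test_empty_map_rejected(self):
        with pytest.raises(InputError):
            tfbs_methylation_delta(np.array([]), np.array([]), np.array([]))


class TestTopKFamilyEnrichment:
    def _deltas(self):
        # 120 TFs; GATA family of 3 with the strongest losses
        names = [f"TF{i:03d}" for i in range(117)] + ["GATA1", "GATA2", "GATA3"]
        vals = list(np.linspace(-0.05, 0.1, 117)) + [-0.5, -0.45, -0.4]
        return pd.Series(vals, index=names)

    def _families(self):
        d = self._deltas()
        fam = pd.Series("Other", index=d.index)
        fam[["GATA1", "GATA2", "GATA3"]] = "GATA"
        return fam

    def test_fully_contained_family_fold(self):
        res = top_k_family_enrichment(self._deltas(), self._families(), k=20)
        assert res.loc["GATA", "fold"] == pytest.approx((3 / 20) / (3 / 120))
        assert res.loc["GATA", "fold"] == pytest.approx(6.0)
        assert res.loc["GATA", "p"] < 0.01

    def test_absent_family_fold_zero(self):
        d = self._deltas()
        fam = self._families()
        fam[["GATA1", "GATA2", "GATA3"]] = "Other"
        fam["TF116"] = "LateFam"   # weakest loss, never in top 20
        res = top_k_family_enrichment(d, fam, k=20)
        assert res.loc["LateFam", "fold"] == 0.0
        assert res.loc["LateFam", "p"] == 1.0

    def test_tie_break_by_name_deterministic(self):
        d = pd.Series([-0.3] * 30, index=[f"TF{i:02d}" for i in range(30)])
        fam = pd.Series("F", index=d.index)
        r1 = top_k_family_enrichment(d, fam, k=10)
        r2 = top_k_family_enrichment(d, fam, k=10)
        assert r1.equals(r2)

    def test_k_exceeding_tfs_rejected(self):
        with pytest.raises(InputError):
            top_k_family_enrichment(pd.Series([1.0]), pd.Series(["F"]), k=5)


class TestIfnaEffect:
    def _values(self, shift=0.0):
        rng = np.random.default_rng(5)
        idx = [f"w{i}" for i in range(200)]
        cols = ["p1", "p2", "m1", "m2"]
        vals = pd.DataFrame(rng.normal(5, 1, size=(200, 4)), index=idx,
                            columns=cols)
        vals[["p1", "p2"]] += shift
        treatment = pd.Series(["IFNA+", "IFNA+", "IFNA-", "IFNA-"], index=cols)
        return vals, treatment

    def test_identical_groups_zero(self):
        vals, tr = self._values()
        vals[["p1", "p2"]] = vals[["m1", "m2"]].to_numpy()
        assert np.allclose(ifna_effect(vals, tr), 0.0)

    def test_injected_shift_recovered(self):
        vals, tr = self._values(shift=1.0)
        eff = ifna_effect(vals, tr)
        assert eff.mean() == pytest.approx(1.0, abs=0.2)

    def test_window_missing_one_group_excluded(self):
        vals, tr = self._values()
        vals.loc["w0", ["p1", "p2"]] = np.nan
        eff = ifna_effect(vals, tr)
        assert "w0" not in eff.index


class TestIfnaCoupling:
    def test_null_strata_small_rho(self):
        rng = np.random.default_rng(6)
        idx = [f"w{i}" for i in range(3000)]
        eff = pd.Series(rng.normal(size=3000), index=idx)
        dl = pd.Series(rng.normal(size=3000), index=idx)
        res = ifna_methylation_coupling(eff, dl, n_quantiles=10)
        assert res["rho"].abs().max() < 0.12

    def test_top_quantile_coupling_increases(self):
        rng = np.random.default_rng(7)
        n = 5000
        idx = [f"w{i}" for i in range(n)]
        eff = pd.Series(rng.normal(size=n), index=idx)
        noise = rng.normal(size=n)
        top = eff > eff.quantile(0.9)
        delta = pd.Series(np.where(top, -0.5 * eff + 0.5 * noise, noise),
                          index=idx)
        res = ifna_methylation_coupling(eff, -delta, n_quantiles=10)
        assert res["rho"].iloc[-1] > res["rho"].iloc[0]

    def test_thin_stratum_absent(self):
        rng = np.random.default_rng(8)
        eff = pd.Series(rng.normal(size=30))
        dl = pd.Series(rng.normal(size=30))
        res = ifna_methylation_coupling(eff, dl, n_quantiles=15, min_pairs=10)
        assert res["rho"].isna().any()


class TestDemethylationLogistic:
    def test_null_coefficient_near_zero(self):
        rng = np.random.default_rng(9)
        eff = pd.Series(rng.normal(size=4000))
        lost = pd.Series(rng.random(4000) < 0.3)
        coef, p, r2, flag = demethylation_logistic(eff, lost.astype(int))
        assert abs(coef) < 0.15
        assert r2 < 0.01

    def test_unit_slope_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            eff = pd.Series(rng.normal(size=7000))
            logits = 1.0 * eff - 0.5
            lost = pd.Series(rng.random(7000) < 1 / (1 + np.exp(-logits)))
            coef, _, _, flag = demethylation_logistic(eff, lost.astype(int))
            hits += abs(coef - 1.0) <= 0.1
        assert hits >= 9

    def test_single_class_rejected(self):
        eff = pd.Series(np.arange(10.0))
        with pytest.raises(InputError):
            demethylation_logistic(eff, pd.Series(np.zeros(10, dtype=int)))

    def test_complete_separation_flagged(self):
        eff = pd.Series(np.linspace(-2, 2, 40))
        lost = pd.Series((eff > 0).astype(int))
        coef, p, r2, flag = demethylation_logistic(eff, lost)
        assert flag == "penalized_fallback"
        assert coef > 0
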