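"""Gaussian trait models: likelihood oracles, fitting, AICc machinery, ASR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal, norm

from moltpath import evomodel_continuous as emc
from moltpath import synthetic_data as sd
from moltpath import treekit as tk

from conftest import star_tree


class TestLoglik:
    def test_star_tree_reduces_to_iid(self):
        t = star_tree(6, depth=2.0)
        C = tk.vcv_matrix(t)
        x = np.array([0.3, -1.2, 0.7, 2.0, -0.4, 1.1])
        expected = norm.logpdf(x, loc=0.5, scale=np.sqrt(1.5 * 2.0)).sum()
        assert emc.gaussian_phylo_loglik(C, x, 1.5, 0.5) == pytest.approx(expected)

    def test_dense_mvn_oracle_three_tips(self, three_tip):
        C = tk.vcv_matrix(three_tip)
        x = np.array([0.1, 0.9, -0.5])
        dense = multivariate_normal.logpdf(x, mean=np.full(3, 0.2),
                                           cov=0.7 * C.matrix)
        assert abs(emc.gaussian_phylo_loglik(C, x, 0.7, 0.2) - dense) < 1e-10

    def test_quadratic_scaling(self, three_tip):
        C = tk.vcv_matrix(three_tip)
        x = np.array([0.4, -0.3, 1.2])
        base = emc.gaussian_phylo_loglik(C, x, 1.0, 0.0)
        scaled = emc.gaussian_phylo_loglik(C, 3.0 * x, 1.0, 0.0)
        const = -0.5 * (3 * np.log(2 * np.pi)
                        + np.linalg.slogdet(C.matrix)[1])
        quad = base - const
        assert scaled - const == pytest.approx(9.0 * quad)


class TestFitModel:
    def test_two_tip_closed_form_gls(self, cherry):
        # hand GLS: V = I, z0 = mean = 1, ML sigma2 = ((0-1)^2+(2-1)^2)/2 = 1
        lnL, s2, z0 = emc._profile_loglik(tk.vcv_matrix(cherry).matrix,
                                          np.array([0.0, 2.0]))
        assert z0 == pytest.approx(1.0)
        assert s2 == pytest.approx(1.0)

    def test_invariant_character_rejected(self, yule48):
        with pytest.raises(ValueError, match="invariant"):
            emc.fit_model(yule48, np.ones(48), "BM")

    def test_nesting_invariants(self, yule48):
        for seed in range(5):
            x = sd.simulate_continuous(yule48, "BM", sigma2=1.0, seed=seed)
            bm = emc.fit_model(yule48, x, "BM")
            assert emc.fit_model(yule48, x, "OU").lnL >= bm.lnL - 1e-6
            assert emc.fit_model(yule48, x, "EB").lnL >= bm.lnL - 1e-6
            lam = emc.fit_model(yule48, x, "lambda")
            assert lam.lnL >= bm.lnL - 1e-6  # lambda=1 is nested

    def test_sigma2_recovery_sanity(self, yule100):
        meds = [emc.fit_model(yule100,
                              sd.simulate_continuous(yule100, "BM", sigma2=2.0,
                                                     seed=500 + r), "BM").sigma2
                for r in range(30)]
        assert 1.6 < np.median(meds) < 2.4

    def test_binary_trait_flagged(self, yule48):
        x = (sd.simulate_continuous(yule48, "BM", seed=3) > 0).astype(float)
        fit = emc.fit_model(yule48, x, "BM")
        assert fit.meta["binary_trait"]


class TestAicc:
    def test_forced_arithmetic(self):
        assert emc.aicc(0, 2, 48) == pytest.approx(4.0 + 12 / 45)
        assert emc.aicc(-10, 3, 48) == pytest.approx(20 + 6 + 24 / 44)

    def test_limit_to_aic(self):
        assert emc.aicc(0, 3, 10**5) - 6.0 < 0.01

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            emc.aicc(0, 3, 4)

    def test_weights_equal_values_uniform(self):
        assert np.allclose(emc.aicc_weights([10.0, 10.0, 10.0]), 1 / 3)

    def test_weights_shift_invariant(self):
        v = np.array([100.0, 102.0, 105.0])
        assert np.allclose(emc.aicc_weights(v), emc.aicc_weights(v + 55.0))

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = emc.aicc_weights(rng.uniform(50, 250, size=rng.integers(2, 15)))
            assert w.sum() == pytest.approx(1.0)
            assert (w >= 0).all()

    def test_weights_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            emc.aicc_weights([1.0, np.nan])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=-500, max_value=500), min_size=1,
                    max_size=12),
           st.floats(min_value=-100, max_value=100))
    def test_property_simplex_and_shift_invariance(self, values, shift):
        w = emc.aicc_weights(values)
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()
        assert np.allclose(w, emc.aicc_weights(np.asarray(values) + shift),
                           atol=1e-12)


class TestWeightedRateSummary:
    def _fit(self, model, sigma2, aicc_val):
        return emc.ContinuousFit(model, sigma2, 0.0, 0.0, 2, 48, aicc_val)

    def test_degenerate_weights_pick_single_model(self):
        fits = {"head": {"BM": self._fit("BM", 3.0, 0.0),
                         "OU": self._fit("OU", 9.0, 1e6),
                         "EB": self._fit("EB", 5.0, 1e6)}}
        out = emc.weighted_rate_summary(fits)
        assert out["BM"] == pytest.approx(3.0)
        assert out["OU"] == pytest.approx(0.0, abs=1e-12)

    def test_two_identical_regions_double(self):
        region = {"BM": self._fit("BM", 2.0, 10.0), "OU": self._fit("OU", 4.0, 11.0),
                  "EB": self._fit("EB", 1.0, 12.0)}
        one = emc.weighted_rate_summary({"a": region})
        two = emc.weighted_rate_summary({"a": region, "b": region})
        for m in one:
            assert two[m] == pytest.approx(2 * one[m])

    def test_hand_computed_three_regions(self):
        fits = {}
        expected = {"BM": 0.0, "OU": 0.0, "EB": 0.0}
        vals = {"r1": {"BM": (1.0, 10.0), "OU": (2.0, 11.0), "EB": (0.5, 14.0)},
                "r2": {"BM": (3.0, 20.0), "OU": (1.0, 20.0), "EB": (2.0, 22.0)},
                "r3": {"BM": (0.2, 5.0), "OU": (0.4, 9.0), "EB": (0.1, 6.0)}}
        for region, models in vals.items():
            fits[region] = {m: self._fit(m, s, a) for m, (s, a) in models.items()}
            a = np.array([models[m][1] for m in ("BM", "EB", "OU")])
            w = np.exp(-(a - a.min()) / 2)
            w /= w.sum()
            for m, wi in zip(("BM", "EB", "OU"), w):
                expected[m] += wi * models[m][0]
        out = emc.weighted_rate_summary(fits)
        for m in expected:
            assert out[m] == pytest.approx(expected[m])

    def test_missing_model_named_in_error(self):
        fits = {"head": {"BM": self._fit("BM", 1.0, 0.0),
                         "OU": self._fit("OU", 1.0, 0.0)},
                "tail": {"BM": self._fit("BM", 1.0, 0.0)}}
        with pytest.raises(ValueError, match="tail"):
            emc.weighted_rate_summary(fits)


class TestPhyloSignal:
    def test_optimum_dominates_endpoints(self, yule48):
        x = sd.simulate_continuous(yule48, "lambda", param=0.5, seed=8)
        sig = emc.phylo_signal_lambda(yule48, x)
        assert sig["lnL"] >= max(sig["lnL_0"], sig["lnL_1"]) - 1e-8

    def test_noise_on_deep_tree_gives_low_lambda(self, yule48):
        rng = np.random.default_rng(4)
        x = 5.0 + 0.01 * rng.standard_normal(48)
        assert emc.phylo_signal_lambda(yule48, x)["lambda"] < 0.3


class TestASRContinuous:
    def test_symmetric_tree_root_is_mean(self):
        t = tk.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        res = emc.asr_continuous(t, {"A": 0.0, "B": 2.0, "C": 0.0, "D": 2.0})
        root_idx = list(res["node_index"]).index(t.root)
        assert res["estimate"][root_idx] == pytest.approx(1.0)

    def test_constant_tips_give_constant_nodes(self, yule48):
        x = np.full(48, 3.0)
        x[0] = 3.0 + 1e-9  # dodge the invariant-character guard
        res = emc.asr_continuous(yule48, x)
        assert np.allclose(res["estimate"], 3.0, atol=1e-6)
        assert (res["variance"] >= 0).all()

    def test_dense_gaussian_conditional_oracle(self):
        t = tk.read_newick("((A:1,B:1):1,(C:1.5,D:0.5):1);")
        x = np.array([0.3, -0.8, 1.4, 0.2])
        res = emc.asr_continuous(t, x)
        fit = res["fit"]
        M = emc._full_mrca_depths(t)
        tips = np.arange(4)
        nodes = res["node_index"]
        Ctt, Cnt = M[np.ix_(tips, tips)], M[np.ix_(nodes, tips)]
        mean = fit.z0 + Cnt @ np.linalg.solve(Ctt, x - fit.z0)
        cond = np.diag(M[np.ix_(nodes, nodes)]) - np.einsum(
            "ij,ji->i", Cnt, np.linalg.solve(Ctt, Cnt.T))
        assert np.allclose(res["estimate"], mean, atol=1e-10)
        assert np.allclose(res["variance"], fit.sigma2 * cond, atol=1e-10)
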