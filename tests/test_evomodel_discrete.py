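"""Mk models: pruning vs enumeration, fits, ASR, transitions, Pagel test."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from moltpath import evomodel_discrete as emd
from moltpath import synthetic_data as sd
from moltpath import treekit as tk


def enumeration_loglik(tree, tips, Q, prior):
    """Oracle: sum over all internal-state assignments of path products."""
    m = Q.shape[0]
    internals = list(range(tree.n_tips, tree.n_nodes))
    P = {i: expm(Q * tree.blen[i]) for i in range(tree.n_nodes)}
    total = 0.0
    for assign in itertools.product(range(m), repeat=len(internals)):
        state = {node: s for node, s in zip(internals, assign)}
        state.update({i: tips[i] for i in range(tree.n_tips)})
        like = prior[state[tree.root]]
        for node in range(tree.n_nodes):
            p = tree.parent[node]
            if p != -1:
                like *= P[node][state[p], state[node]]
        total += like
    return np.log(total)


class TestMkLoglik:
    def test_zero_rate_constant_tips(self, cherry):
        Q = emd.build_er_q(2, 0.0)
        lnL = emd.mk_loglik(cherry, [0, 0], Q)
        assert lnL == pytest.approx(np.log(0.5))

    @pytest.mark.parametrize("seed", range(8))
    def test_pruning_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t = sd.simulate_yule_tree(rng.integers(3, 6), seed=seed)
        m = int(rng.integers(2, 4))
        Q = emd.build_ard_q(m, rng.uniform(0.1, 2.0, m * (m - 1)))
        tips = rng.integers(0, m, t.n_tips).tolist()
        prior = np.full(m, 1.0 / m)
        assert abs(emd.mk_loglik(t, tips, Q, prior)
                   - enumeration_loglik(t, tips, Q, prior)) < 1e-10

    def test_transition_rows_sum_to_one(self, yule48):
        Q = emd.build_ard_q(2, [0.7, 0.2])
        P = emd.branch_transition_matrices(Q, yule48.blen)
        assert np.allclose(P.sum(axis=2), 1.0, atol=1e-8)

    def test_four_state_transition_rows_sum_to_one(self, yule48):
        Q = sd.dependent_pair_q(sd.STRONG_DEPENDENCE_RATES)
        P = emd.branch_transition_matrices(Q, yule48.blen)
        assert np.allclose(P.sum(axis=2), 1.0, atol=1e-8)

    def test_unknown_state_rejected(self, cherry):
        with pytest.raises(ValueError, match="state"):
            emd.mk_loglik(cherry, [0, 2], emd.build_er_q(2, 1.0))


class TestFitMk:
    def test_symmetric_data_symmetric_rates(self):
        t = tk.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        ard = emd.fit_mk(t, {"A": 0, "B": 1, "C": 1, "D": 0}, "ARD")
        assert ard.Q[0, 1] == pytest.approx(ard.Q[1, 0], rel=0.05)

    def test_ard_never_worse_than_er(self, yule48):
        x = sd.simulate_mk(yule48, emd.build_er_q(2, 1.0), seed=5)
        er = emd.fit_mk(yule48, x, "ER")
        ard = emd.fit_mk(yule48, x, "ARD")
        assert ard.lnL >= er.lnL - 1e-6

    def test_invariant_rejected(self, yule48):
        with pytest.raises(ValueError, match="invariant"):
            emd.fit_mk(yule48, [0] * 48, "ER")

    def test_q_row_sums(self, yule48):
        x = sd.simulate_mk(yule48, emd.build_er_q(2, 1.0), seed=6)
        fit = emd.fit_mk(yule48, x, "ARD")
        assert np.allclose(fit.Q.sum(axis=1), 0.0, atol=1e-10)


class TestLRT:
    def test_equal_likelihoods(self):
        res = emd.lrt(-10.0, -10.0, 1)
        assert res["statistic"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_chi_square_quantile_identity(self):
        assert emd.lrt(0.0, 3.841 / 2, 1)["p"] == pytest.approx(0.05, abs=1e-3)

    def test_matches_quadrature(self):
        from scipy.integrate import quad
        stat, df = 5.3, 4
        tail, _ = quad(lambda u: chi2.pdf(u, df), stat, np.inf)
        assert emd.lrt(0.0, stat / 2, df)["p"] == pytest.approx(tail, abs=1e-6)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError, match="lower likelihood"):
            emd.lrt(-5.0, -7.0, 1)


class TestMarginalASR:
    def test_low_rate_all_present(self, yule48):
        Q = emd.build_er_q(2, 1e-7)
        asr = emd.marginal_asr(yule48, [1] * 47 + [1], Q)
        assert np.allclose(asr.probabilities[:, 1], 1.0, atol=1e-4)

    def test_probabilities_normalized(self, yule48):
        x = sd.simulate_mk(yule48, emd.build_er_q(2, 1.0), seed=9)
        fit = emd.fit_mk(yule48, x, "ER")
        asr = emd.marginal_asr(yule48, x, fit.Q)
        assert np.allclose(asr.probabilities.sum(axis=1), 1.0, atol=1e-8)
        assert (asr.probabilities >= 0).all()

    @pytest.mark.parametrize("tips", [[0, 1, 1], [1, 0, 1], [0, 0, 1]])
    def test_brute_force_conditionals(self, three_tip, tips):
        Q = emd.build_ard_q(2, [0.7, 0.3])
        prior = np.array([0.5, 0.5])
        asr = emd.marginal_asr(three_tip, tips, Q, prior)
        # enumerate joint over (root, internal) states
        idx = {lbl: i for i, lbl in enumerate(three_tip.tip_labels)}
        P = {i: expm(Q * three_tip.blen[i]) for i in range(three_tip.n_nodes)}
        inner = [c for c in three_tip.children[three_tip.root]
                 if c >= three_tip.n_tips][0]
        ab = [c for c in three_tip.children[inner]]
        other_tip = [c for c in three_tip.children[three_tip.root] if c < 3][0]
        marg_root = np.zeros(2)
        marg_inner = np.zeros(2)
        for r in range(2):
            for s in range(2):
                L = (prior[r] * P[inner][r, s]
                     * P[ab[0]][s, tips[ab[0]]] * P[ab[1]][s, tips[ab[1]]]
                     * P[other_tip][r, tips[other_tip]])
                marg_root[r] += L
                marg_inner[s] += L
        rows = {node: i for i, node in enumerate(asr.node_index)}
        assert np.allclose(asr.probabilities[rows[three_tip.root]],
                           marg_root / marg_root.sum(), atol=1e-10)
        assert np.allclose(asr.probabilities[rows[inner]],
                           marg_inner / marg_inner.sum(), atol=1e-10)

    def test_state_relabeling_permutes_probabilities(self, yule48):
        x = sd.simulate_mk(yule48, emd.build_er_q(2, 1.0), seed=10)
        Q = emd.build_ard_q(2, [0.8, 0.4])
        asr = emd.marginal_asr(yule48, x, Q)
        # relabeling states permutes probability vectors exactly
        asr_swapped = emd.marginal_asr(yule48, [1 - s for s in x],
                                       emd.build_ard_q(2, [0.4, 0.8]))
        assert np.allclose(asr.probabilities, asr_swapped.probabilities[:, ::-1],
                           atol=1e-10)


class TestCountTransitions:
    def test_all_absent(self, yule48):
        Q = emd.build_er_q(2, 1e-7)
        states = [0] * 48
        states[0] = 1  # minimal variation to keep ASR meaningful
        asr = emd.marginal_asr(yule48, states, Q)
        res = emd.count_transitions(asr, yule48, states)
        assert res["gains"] == 1 and res["losses"] == 0

    def test_cherry_forced_gain(self, cherry):
        # gain-prone, loss-averse rates reconstruct the root as absent,
        # forcing a single gain on the branch to the present tip
        asr = emd.marginal_asr(cherry, [0, 1], emd.build_ard_q(2, [1.0, 0.1]))
        assert asr.map_states[0] == 0
        res = emd.count_transitions(asr, cherry, [0, 1])
        assert (res["gains"], res["losses"]) == (1, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_map_path_enumeration(self, seed):
        t = sd.simulate_yule_tree(6, seed=100 + seed)
        x = sd.simulate_mk(t, emd.build_er_q(2, 1.5), seed=seed)
        if len(set(x)) < 2:
            return
        fit = emd.fit_mk(t, x, "ER")
        asr = emd.marginal_asr(t, x, fit.Q)
        res = emd.count_transitions(asr, t, x)
        states = np.zeros(t.n_nodes, int)
        states[: t.n_tips] = x
        for i, node in enumerate(asr.node_index):
            states[node] = asr.map_states[i]
        gains = sum(states[t.parent[i]] == 0 and states[i] == 1
                    for i in range(t.n_nodes) if t.parent[i] != -1)
        losses = sum(states[t.parent[i]] == 1 and states[i] == 0
                     for i in range(t.n_nodes) if t.parent[i] != -1)
        assert (res["gains"], res["losses"]) == (gains, losses)


class TestPagelDependence:
    def test_perfectly_coupled_traits_favor_dependent(self):
        t = sd.simulate_yule_tree(50, seed=31)
        x = sd.simulate_mk(t, emd.build_er_q(2, 1.0), seed=32)
        assert len(set(x)) == 2
        res = emd.pagel_dependence_test(t, x, x.copy())
        assert res["aic_dependent"] < res["aic_independent"]

    def test_nesting(self, yule48):
        x = sd.simulate_mk(yule48, emd.build_er_q(2, 0.8), seed=33)
        y = sd.simulate_mk(yule48, emd.build_er_q(2, 0.8), seed=34)
        res = emd.pagel_dependence_test(yule48, x, y)
        assert res["dependent"].lnL >= res["independent"].lnL - 1e-6
        assert res["independent"].k == 4 and res["dependent"].k == 8

    def test_invariant_trait_rejected(self, yule48):
        with pytest.raises(ValueError, match="invariant"):
            emd.pagel_dependence_test(yule48, [0] * 48, [0, 1] * 24)

    def test_dual_transitions_zero(self, yule48):
        x = sd.simulate_mk(yule48, emd.build_er_q(2, 0.8), seed=35)
        y = sd.simulate_mk(yule48, emd.build_er_q(2, 0.8), seed=36)
        res = emd.pagel_dependence_test(yule48, x, y)
        for fit in (res["independent"], res["dependent"]):
            assert fit.Q[0, 3] == 0.0 and fit.Q[3, 0] == 0.0
            assert fit.Q[1, 2] == 0.0 and fit.Q[2, 1] == 0.0
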