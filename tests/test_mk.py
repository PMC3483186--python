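"""Mk1/AsymmMk likelihoods, fits and marginal ancestral reconstruction."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import chi2

from sciophylo.mk import (
    MkModel,
    fit_asymm,
    fit_mk1,
    marginal_asr,
    pruning_loglik,
    transition_probabilities,
)
from sciophylo.simulate import SimConfig, simulate_discrete, simulate_tree
from sciophylo.trees import read_newick

from .oracles import mk_enum_loglik, random_bifurcating_newick

AB = ("a", "b")


class TestTransitionProbabilities:
    @pytest.mark.parametrize("model", [
        MkModel(k=2, rate=0.3),
        MkModel(k=5, rate=1.7),
        MkModel(k=2, q01=0.9, q10=0.1),
    ])
    def test_zero_time_is_identity_and_rows_sum_to_one(self, model):
        assert np.allclose(transition_probabilities(model, 0.0),
                           np.eye(model.k))
        for t in (0.01, 0.5, 3.0):
            P = transition_probabilities(model, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert (P >= 0).all()

    def test_long_time_reaches_stationarity(self):
        P = transition_probabilities(MkModel(k=4, rate=1.0), 1e6)
        assert np.allclose(P, 0.25)
        m = MkModel(k=2, q01=0.6, q10=0.2)
        P = transition_probabilities(m, 1e6)
        assert np.allclose(P, [[0.25, 0.75], [0.25, 0.75]])

    def test_symmetric_asymm_equals_mk1(self):
        for t in (0.1, 1.0, 4.0):
            Pa = transition_probabilities(MkModel(k=2, q01=0.4, q10=0.4), t)
            Pm = transition_probabilities(MkModel(k=2, rate=0.4), t)
            assert np.allclose(Pa, Pm, atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probabilities(MkModel(k=2, rate=1.0), -0.1)


class TestPruningLoglik:
    def test_three_tip_case_matches_enumeration(self):
        t = read_newick("((t1:1,t2:1):1,t3:2);")
        m = MkModel(k=2, rate=0.1)
        states = {"t1": "0", "t2": "0", "t3": "1"}
        got = pruning_loglik(t, states, m, ("0", "1"))
        assert got == pytest.approx(
            mk_enum_loglik(t, states, m, ("0", "1")), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_enumeration_on_random_instances(self, seed):
        """Pruning ≡ exhaustive interior-assignment sum, ≤ 6 tips."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        tree = read_newick(random_bifurcating_newick(rng, n))
        if rng.random() < 0.5:
            k = int(rng.integers(2, 5))
            model = MkModel(k=k, rate=float(rng.uniform(0.05, 2.0)))
        else:
            k = 2
            model = MkModel(
                k=2, q01=float(rng.uniform(0.05, 2.0)),
                q10=float(rng.uniform(0.05, 2.0)),
                root_prior="stationary" if rng.random() < 0.5 else "uniform",
            )
        alphabet = tuple(str(i) for i in range(k))
        states = {
            lab: ("?" if rng.random() < 0.15
                  else str(rng.integers(k)))
            for lab in tree.tip_labels
        }
        got = pruning_loglik(tree, states, model, alphabet)
        want = mk_enum_loglik(tree, states, model, alphabet)
        assert got == pytest.approx(want, abs=1e-9)

    def test_zero_rate_limit_is_log_prior(self):
        t = read_newick("((t1:1,t2:1):1,t3:2);")
        m = MkModel(k=3, rate=1e-9)
        lnl = pruning_loglik(t, {"t1": "0", "t2": "0", "t3": "0"}, m,
                             ("0", "1", "2"))
        assert lnl == pytest.approx(np.log(1 / 3), abs=1e-6)

    def test_all_missing_gives_zero(self):
        t = read_newick("((t1:1,t2:1):1,t3:2);")
        m = MkModel(k=2, rate=0.5)
        lnl = pruning_loglik(t, dict.fromkeys(["t1", "t2", "t3"], "?"),
                             m, AB)
        assert lnl == pytest.approx(0.0, abs=1e-12)

    def test_absent_tip_raises(self):
        t = read_newick("(t1:1,t2:1);")
        with pytest.raises(KeyError, match="t2"):
            pruning_loglik(t, {"t1": "a"}, MkModel(k=2, rate=1.0), AB)

    def test_mk1_root_placement_invariance(self):
        """Same unrooted tree, two rootings: identical Mk1 likelihood."""
        r1 = read_newick("((t1:1,t2:2):0.5,(t3:0.8,t4:1.2):0.5);")
        # same unrooted tree, re-rooted along t1's pendant branch
        r2 = read_newick("(t1:0.4,(t2:2,(t3:0.8,t4:1.2):1.0):0.6);")
        states = {"t1": "a", "t2": "b", "t3": "a", "t4": "b"}
        m = MkModel(k=2, rate=0.37)
        l1 = pruning_loglik(r1, states, m, AB)
        l2 = pruning_loglik(r2, states, m, AB)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_polytomy_handled_natively(self):
        t = read_newick("((t1:1,t2:1,t3:1):1,t4:2);")
        m = MkModel(k=2, rate=0.2)
        lnl = pruning_loglik(t, {"t1": "a", "t2": "a", "t3": "b",
                                 "t4": "b"}, m, AB)
        assert np.isfinite(lnl)
        assert lnl == pytest.approx(
            mk_enum_loglik(t, {"t1": "a", "t2": "a", "t3": "b",
                               "t4": "b"}, m, AB), abs=1e-9)


class TestFitMk1:
    def test_optimum_beats_coarse_grid(self):
        t = read_newick("((t1:1.0,t2:2.0):0.5,(t3:0.8,(t4:1.2,t5:0.3):0.7):1.5);")
        states = {"t1": "a", "t2": "a", "t3": "a", "t4": "b", "t5": "b"}
        model, lnl = fit_mk1(t, states, k=2, alphabet=AB)
        for r in np.geomspace(1e-4, 50, 40):
            other = pruning_loglik(t, states, MkModel(k=2, rate=float(r)), AB)
            assert lnl >= other - 1e-6

    def test_matches_independent_r_implementation(self):
        """Frozen oracle: ape::ace (ER model) on the same tree/character
        gives rate 0.5018709270 and, after adding the ln k root-prior
        factor ace omits, log-likelihood -3.4244634377; root marginals
        (0.6478015, 0.3521985)."""
        t = read_newick(
            "((t1:1.0,t2:2.0):0.5,(t3:0.8,(t4:1.2,t5:0.3):0.7):1.5);"
        )
        states = {"t1": "a", "t2": "a", "t3": "a", "t4": "b", "t5": "b"}
        model, lnl = fit_mk1(t, states, k=2, alphabet=AB)
        assert model.rate == pytest.approx(0.5018709270, rel=1e-4)
        assert lnl == pytest.approx(-3.4244634377, abs=1e-6)
        asr = marginal_asr(t, states, model, AB)
        assert asr.marginal_probabilities(t.root) == pytest.approx(
            [0.6478015, 0.3521985], abs=1e-5
        )

    def test_monomorphic_pins_rate_with_warning(self):
        t = read_newick("(t1:1,(t2:1,t3:1):1);")
        with pytest.warns(UserWarning, match="no variation"):
            model, _ = fit_mk1(t, dict.fromkeys(["t1", "t2", "t3"], "a"),
                               k=2, alphabet=AB)
        assert model.rate <= 1e-7
        with pytest.raises(ValueError):
            fit_mk1(t, dict.fromkeys(["t1", "t2", "t3"], "a"), k=2,
                    alphabet=AB, strict=True)

    def test_recovers_simulated_rate(self):
        """Simulation calibration: r̂ on 200-tip Yule data stays within a
        generous bracket of the truth."""
        true_r = 0.5
        estimates = []
        for seed in range(8):
            tree = simulate_tree(SimConfig(seed=seed, n_tips=200,
                                           tree_height=1.0))
            tips, _ = simulate_discrete(
                tree, MkModel(k=2, rate=true_r), seed=seed + 1000,
                alphabet=AB,
            )
            if len(set(tips.values())) < 2:
                continue
            model, _ = fit_mk1(tree, tips, k=2, alphabet=AB)
            estimates.append(model.rate)
        med = np.median(estimates)
        assert 0.25 < med < 1.0


class TestFitAsymm:
    def test_nesting_vs_mk1(self):
        t = read_newick("((t1:1.0,t2:2.0):0.5,(t3:0.8,(t4:1.2,t5:0.3):0.7):1.5);")
        states = {"t1": "a", "t2": "a", "t3": "a", "t4": "b", "t5": "b"}
        _, lnl1 = fit_mk1(t, states, k=2, alphabet=AB)
        _, lnl2 = fit_asymm(t, states, AB)
        assert lnl2 >= lnl1 - 1e-4

    def test_non_binary_rejected(self):
        t = read_newick("(t1:1,t2:1);")
        with pytest.raises(ValueError, match="binary"):
            fit_asymm(t, {"t1": "0", "t2": "1"}, ("0", "1", "2"))

    def test_symmetric_data_small_lr(self):
        """On data simulated under the symmetric model the LR statistic
        stays in the bulk of its chi-square(1) null."""
        lrs = []
        for seed in range(6):
            tree = simulate_tree(SimConfig(seed=seed, n_tips=120,
                                           tree_height=1.0))
            tips, _ = simulate_discrete(
                tree, MkModel(k=2, rate=0.6), seed=seed + 77, alphabet=AB
            )
            if len(set(tips.values())) < 2:
                continue
            _, l1 = fit_mk1(tree, tips, k=2, alphabet=AB)
            _, l2 = fit_asymm(tree, tips, AB, n_restarts=3)
            lrs.append(max(0.0, 2 * (l2 - l1)))
        # all six statistics below the chi2_1 99.9% point would be very
        # unlikely under misbehaving fits; generous to Monte-Carlo noise
        assert np.median(lrs) < chi2.ppf(0.95, df=1)


class TestMarginalAsr:
    def test_two_tip_symmetric_root_is_ambiguous(self):
        t = read_newick("(t1:1,t2:1);")
        m = MkModel(k=2, rate=0.3)
        asr = marginal_asr(t, {"t1": "a", "t2": "b"}, m, AB)
        assert set(asr.significant_sets[t.root]) == {"a", "b"}

    @pytest.mark.parametrize("seed", range(10))
    def test_clamped_logliks_match_enumeration(self, seed):
        """Per-node conditional lnLs equal brute force with the node
        clamped (5-taxon random instances)."""
        rng = np.random.default_rng(100 + seed)
        tree = read_newick(random_bifurcating_newick(rng, 5))
        k = int(rng.integers(2, 4))
        alphabet = tuple(str(i) for i in range(k))
        if k == 2 and rng.random() < 0.5:
            model = MkModel(k=2, q01=float(rng.uniform(0.1, 1.5)),
                            q10=float(rng.uniform(0.1, 1.5)),
                            root_prior="stationary")
        else:
            model = MkModel(k=k, rate=float(rng.uniform(0.1, 1.5)))
        states = {lab: str(rng.integers(k)) for lab in tree.tip_labels}
        asr = marginal_asr(tree, states, model, alphabet)
        for node, v in asr.node_logliks.items():
            for s in range(k):
                want = mk_enum_loglik(tree, states, model, alphabet,
                                      clamp=(node, s))
                assert v[s] == pytest.approx(want, abs=1e-9)

    def test_node_marginals_sum_to_one_and_bounded(self):
        rng = np.random.default_rng(5)
        tree = read_newick(random_bifurcating_newick(rng, 12))
        states = {lab: str(rng.integers(2)) for lab in tree.tip_labels}
        model, lnl = fit_mk1(tree, states, k=2, alphabet=("0", "1"))
        asr = marginal_asr(tree, states, model, ("0", "1"))
        for i, v in asr.node_logliks.items():
            assert asr.marginal_probabilities(i).sum() == pytest.approx(1.0)
            assert v.max() <= lnl + 1e-6
            assert len(asr.significant_sets[i]) >= 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(6)
        tree = read_newick(random_bifurcating_newick(rng, 15))
        states = {lab: str(rng.integers(3)) for lab in tree.tip_labels}
        model, _ = fit_mk1(tree, states, k=3, alphabet=("0", "1", "2"))
        asr = marginal_asr(tree, states, model, ("0", "1", "2"))
        for i in asr.node_logliks:
            small = set(asr.states_within(i, 1.0))
            mid = set(asr.states_within(i, 2.0))
            large = set(asr.states_within(i, 5.0))
            assert small <= mid <= large


class TestDropUnknownsRerun:
    def test_no_missing_identical_runs(self):
        rng = np.random.default_rng(9)
        tree = read_newick(random_bifurcating_newick(rng, 10))
        states = {lab: str(rng.integers(2)) for lab in tree.tip_labels}
        from sciophylo.mk import drop_unknowns_rerun

        out = drop_unknowns_rerun(tree, states, ("0", "1"), model="mk1")
        assert out["agreement_fraction"] == pytest.approx(1.0)

    def test_masked_tips_agreement_reported(self):
        from sciophylo.mk import drop_unknowns_rerun

        rng = np.random.default_rng(10)
        tree = simulate_tree(SimConfig(seed=11, n_tips=40, tree_height=1.0))
        tips, _ = simulate_discrete(
            tree, MkModel(k=2, rate=0.4), seed=12, alphabet=("0", "1"),
            missing_fraction=0.1,
        )
        out = drop_unknowns_rerun(tree, tips, ("0", "1"), model="mk1")
        assert 0.0 <= out["agreement_fraction"] <= 1.0
        assert len(out["agreement"]) > 0
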