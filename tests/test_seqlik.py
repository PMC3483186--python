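"""GTR+Γ(+I) site likelihoods on fixed topologies."""

import numpy as np
import pytest

from sciophylo.alignments import Alignment
from sciophylo.seqlik import (
    SubstModel,
    gamma_category_rates,
    gtr_generator,
    optimize_branch_lengths,
    partitioned_site_logliks,
    site_logliks,
)
from sciophylo.simulate import SimConfig, simulate_alignment, simulate_tree
from sciophylo.trees import read_newick


def jc_transition(t):
    P = np.full((4, 4), (1 - np.exp(-4 / 3 * t)) / 4)
    np.fill_diagonal(P, 1 / 4 + 3 / 4 * np.exp(-4 / 3 * t))
    return P


class TestGenerator:
    def test_gtr_rows_sum_to_zero_and_mean_rate_one(self):
        m = SubstModel(
            exchangeabilities=(1.2, 3.1, 0.7, 0.9, 4.0, 1.0),
            base_freqs=(0.3, 0.2, 0.2, 0.3),
        )
        Q = gtr_generator(m)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        pi = np.array(m.base_freqs)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)
        # detailed balance (GTR is reversible)
        assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)

    def test_gamma_rates_mean_one(self):
        for a in (0.2, 0.8, 2.0, 50.0):
            r = gamma_category_rates(a)
            assert r.mean() == pytest.approx(1.0, abs=1e-10)
            assert (np.diff(r) > 0).all()

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            SubstModel(base_freqs=(0.5, 0.5, 0.1, 0.1))
        with pytest.raises(ValueError):
            SubstModel(p_inv=1.0)
        with pytest.raises(ValueError):
            SubstModel(alpha=-1.0)


class TestSiteLogliks:
    def test_jukes_cantor_closed_form_three_taxa(self):
        """GTR machinery in the equal-rates/equal-frequency limit equals
        the JC closed form, summed over root states."""
        t = read_newick("(a:0.1,b:0.25,c:0.4);")
        aln = Alignment(["a", "b", "c"], ["ACGTA", "AAGTC", "ACGAC"])
        got = site_logliks(t, aln, SubstModel())
        code = {c: i for i, c in enumerate("ACGT")}
        Ps = {lab: jc_transition(dict(a=0.1, b=0.25, c=0.4)[lab])
              for lab in "abc"}
        for s in range(aln.length):
            want = sum(
                0.25
                * Ps["a"][r, code[aln.sequences[0][s]]]
                * Ps["b"][r, code[aln.sequences[1][s]]]
                * Ps["c"][r, code[aln.sequences[2][s]]]
                for r in range(4)
            )
            assert got[s] == pytest.approx(np.log(want), abs=1e-10)

    def test_two_taxon_closed_form(self):
        """Per-site lnL of a 2-taxon alignment is log(π_i P_ij(t_total))."""
        t = read_newick("(a:0.12,b:0.3);")
        aln = Alignment(["a", "b"], ["AG", "AT"])
        m = SubstModel(
            exchangeabilities=(1.5, 2.5, 0.8, 1.1, 3.0, 1.0),
            base_freqs=(0.35, 0.15, 0.2, 0.3),
        )
        got = site_logliks(t, aln, m)
        from scipy.linalg import expm

        P = expm(gtr_generator(m) * 0.42)
        pi = np.array(m.base_freqs)
        code = {c: i for i, c in enumerate("ACGT")}
        for s in range(2):
            i, j = code[aln.sequences[0][s]], code[aln.sequences[1][s]]
            assert got[s] == pytest.approx(np.log(pi[i] * P[i, j]),
                                           abs=1e-10)

    def test_identical_sequences_identical_across_topologies(self):
        seqs = ["ACGTACGTAA"] * 4
        aln = Alignment(["a", "b", "c", "d"], seqs)
        m = SubstModel(alpha=0.7)
        t1 = read_newick("((a:0.1,b:0.2):0.1,(c:0.3,d:0.1):0.2);")
        t2 = read_newick("((a:0.1,c:0.2):0.1,(b:0.3,d:0.1):0.2);")
        assert np.allclose(site_logliks(t1, aln, m),
                           site_logliks(t2, aln, m))

    def test_root_placement_invariance(self):
        """Pulley principle: total lnL identical for re-rootings of the
        same unrooted tree under the reversible model."""
        aln = Alignment(
            ["t1", "t2", "t3", "t4"],
            ["ACGTACGTCC", "ACGAACGTCA", "GCGTATGTCC", "GCTTACGACC"],
        )
        m = SubstModel(
            exchangeabilities=(1.2, 2.8, 0.6, 1.0, 3.5, 1.0),
            base_freqs=(0.3, 0.2, 0.25, 0.25),
            alpha=1.2, p_inv=0.1,
        )
        r1 = read_newick("((t1:0.1,t2:0.2):0.05,(t3:0.08,t4:0.12):0.05);")
        r2 = read_newick("(t1:0.04,(t2:0.2,(t3:0.08,t4:0.12):0.1):0.06);")
        assert site_logliks(r1, aln, m).sum() == pytest.approx(
            site_logliks(r2, aln, m).sum(), abs=1e-8
        )

    def test_gamma_limit_matches_no_gamma(self):
        aln = Alignment(["a", "b", "c"], ["ACGTA", "AAGTC", "ACGAC"])
        t = read_newick("(a:0.1,b:0.25,c:0.4);")
        near = site_logliks(t, aln, SubstModel(alpha=5000.0))
        flat = site_logliks(t, aln, SubstModel())
        assert np.allclose(near, flat, atol=1e-3)

    def test_partition_multipliers(self):
        tree = simulate_tree(SimConfig(seed=21, n_tips=6, tree_height=0.3))
        fast = SubstModel(alpha=1.0, multiplier=2.0)
        slow = SubstModel(alpha=1.0, multiplier=0.5)
        aln = simulate_alignment(
            tree, slow, 50, seed=3,
            partitions={"fast": fast, "slow": slow},
        )
        sl = partitioned_site_logliks(
            tree, aln, {"fast": fast, "slow": slow}
        )
        assert np.isfinite(sl).all() and sl.shape == (100,)
        # doubling the multiplier equals doubling every branch length
        doubled = tree.copy()
        for nd in doubled.nodes:
            if nd.length is not None:
                nd.length *= 2.0
        a = site_logliks(tree, aln, fast, aln.partitions["fast"])
        b = site_logliks(doubled, aln, SubstModel(alpha=1.0),
                         aln.partitions["fast"])
        assert np.allclose(a, b, atol=1e-9)


class TestBranchLengthOptimization:
    def test_improves_and_converges(self):
        tree = simulate_tree(SimConfig(seed=31, n_tips=6, tree_height=0.4))
        m = SubstModel(alpha=1.0)
        aln = simulate_alignment(tree, m, 300, seed=32)
        start = tree.copy()
        for nd in start.nodes:
            if nd.length is not None:
                nd.length = 0.05
        before = partitioned_site_logliks(start, aln, {"all": m}).sum()
        opt, after = optimize_branch_lengths(start, aln, {"all": m},
                                             max_sweeps=10)
        assert after >= before
        # should approach the generating tree's likelihood
        truth = partitioned_site_logliks(tree, aln, {"all": m}).sum()
        assert after >= truth - 5.0
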