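import numpy as np
import pytest
from oracles import exhaustive_quartet_loglik

from nodevo.codon_model import (
    CODONS,
    CODON_INDEX,
    N_CODONS,
    CodonModelParams,
    assign_uniform_classes,
    build_rate_matrix,
    empirical_codon_frequencies,
    f3x4_frequencies,
    fit_model,
    prune_loglik,
    transition_matrix,
)
from nodevo.data_io import CodonAlignment, DataError, RunConfig, read_newick
from nodevo.simulate import SeqSimConfig, gen_codon_alignment


def random_pi(rng):
    return rng.dirichlet(np.ones(N_CODONS))


class TestRateMatrix:
    def test_rows_sum_to_zero_random_params(self, rng):
        for _ in range(5):
            q = build_rate_matrix(
                rng.uniform(0.5, 8), rng.uniform(0.05, 3), random_pi(rng)
            )
            assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_neutral_uniform_rates_all_equal(self):
        pi = np.full(N_CODONS, 1.0 / N_CODONS)
        q = build_rate_matrix(1.0, 1.0, pi)
        off = q[q > 0]
        assert np.allclose(off, off[0])

    def test_detailed_balance(self, rng):
        for _ in range(5):
            pi = random_pi(rng)
            q = build_rate_matrix(rng.uniform(0.5, 8), rng.uniform(0.05, 3), pi)
            flux = pi[:, None] * q
            assert np.abs(flux - flux.T).max() < 1e-14

    def test_unit_expected_substitution_rate(self, rng):
        pi = random_pi(rng)
        q = build_rate_matrix(3.0, 0.4, pi)
        assert -(pi * np.diag(q)).sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_transition_matrix_stochastic(self, t, rng):
        pi = random_pi(rng)
        q = build_rate_matrix(2.0, 0.5, pi)
        p = transition_matrix(q, t, pi)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-10
        assert p.min() >= 0


class TestFrequencies:
    def test_f3x4_matches_closed_form(self):
        # alignment with known positional nucleotide composition
        aln = CodonAlignment({"t1": "ATGATG", "t2": "CTGATG"})
        pi = f3x4_frequencies(aln)
        f1 = {"A": 0.75, "C": 0.25, "G": 0.0, "T": 0.0}
        f2 = {"A": 0.0, "C": 0.0, "G": 0.0, "T": 1.0}
        f3 = {"A": 0.0, "C": 0.0, "G": 1.0, "T": 0.0}
        raw = np.array([f1[c[0]] * f2[c[1]] * f3[c[2]] for c in CODONS])
        raw = np.maximum(raw, 1e-10)
        assert np.allclose(pi, raw / raw.sum(), atol=1e-9)

    def test_empirical_frequencies_reflect_counts(self):
        aln = CodonAlignment({"t1": "ATGATG", "t2": "ATGCTG"})
        pi = empirical_codon_frequencies(aln)
        assert pi[CODON_INDEX["ATG"]] == pytest.approx(0.75, abs=1e-6)
        assert pi[CODON_INDEX["CTG"]] == pytest.approx(0.25, abs=1e-6)


class TestPruning:
    def test_zero_length_star_tree_gives_log_pi(self, rng):
        phy = assign_uniform_classes(read_newick("(A:0.0,B:0.0,C:0.0);"))
        pi = random_pi(rng)
        codon = CODONS[17]
        aln = CodonAlignment({t: codon for t in "ABC"})
        fit = prune_loglik(aln, phy, CodonModelParams(2.0, {"background": 0.5}, pi))
        assert fit.site_lnl[0] == pytest.approx(np.log(pi[17]), abs=1e-10)

    def test_matches_exhaustive_enumeration(self, quartet_tree, rng):
        codons = list(CODON_INDEX)
        aln = CodonAlignment(
            {t: "".join(rng.choice(codons, 3)) for t in "ABCD"}
        )
        params = CodonModelParams(2.3, {"background": 0.7}, random_pi(rng))
        fit = prune_loglik(aln, quartet_tree, params)
        oracle = exhaustive_quartet_loglik(quartet_tree, aln, params)
        assert np.abs(fit.site_lnl - oracle).max() < 1e-8

    def test_missing_codon_integrates_over_states(self, quartet_tree, rng):
        params = CodonModelParams(2.0, {"background": 0.5}, random_pi(rng))
        aln1 = CodonAlignment({"A": "ATG", "B": "NNN", "C": "ATG", "D": "ATC"})
        fit1 = prune_loglik(aln1, quartet_tree, params)
        # marginalizing B by direct summation over its possible states
        total = 0.0
        for codon in CODONS:
            aln2 = CodonAlignment({"A": "ATG", "B": codon, "C": "ATG", "D": "ATC"})
            total += np.exp(prune_loglik(aln2, quartet_tree, params).site_lnl[0])
        assert fit1.site_lnl[0] == pytest.approx(np.log(total), abs=1e-8)

    def test_doubling_sites_doubles_loglik(self, quartet_tree, rng):
        codons = list(CODON_INDEX)
        seqs = {t: "".join(rng.choice(codons, 4)) for t in "ABCD"}
        params = CodonModelParams(2.0, {"background": 0.3}, random_pi(rng))
        single = prune_loglik(CodonAlignment(seqs), quartet_tree, params)
        doubled = prune_loglik(
            CodonAlignment({t: s + s for t, s in seqs.items()}), quartet_tree, params
        )
        assert doubled.lnl_total == pytest.approx(2 * single.lnl_total, abs=1e-8)

    def test_rerooting_invariance(self, rng):
        # time-reversibility: likelihood unchanged by root placement
        phy = assign_uniform_classes(
            read_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.1);")
        )
        aln, _ = gen_codon_alignment(
            SeqSimConfig(tree=phy, n_codons=20, seed=4)
        )
        params = CodonModelParams(2.0, {"background": 0.5}, f3x4_frequencies(aln))
        base = prune_loglik(aln, phy, params)
        phy2 = phy.copy()
        tree2 = phy2.tree
        leaf_c = [l for l in tree2.leaf_node_iter() if l.taxon.label == "C"][0]
        half = leaf_c.edge.length / 2
        tree2.reroot_at_edge(
            leaf_c.edge, length1=half, length2=half, update_bipartitions=False
        )
        assign_uniform_classes(phy2)
        rerooted = prune_loglik(aln, phy2, params)
        assert rerooted.lnl_total == pytest.approx(base.lnl_total, abs=1e-6)

    def test_unlabeled_branch_fatal(self, rng):
        phy = read_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.1);")
        aln = CodonAlignment({t: "ATG" for t in "ABCD"})
        with pytest.raises(DataError, match="unlabeled"):
            prune_loglik(aln, phy, CodonModelParams(2.0, {"background": 1.0}, random_pi(rng)))


class TestFitModel:
    def test_recovers_simulated_omega(self, octet_tree, fast_config):
        aln, truth = gen_codon_alignment(
            SeqSimConfig(
                tree=octet_tree,
                omega_by_class={"background": 0.2},
                kappa=2.0,
                n_codons=400,
                seed=5,
            )
        )
        fit = fit_model(aln, octet_tree, (), fast_config)
        assert 0.12 <= fit.params.omega_by_class["background"] <= 0.30
        assert 1.4 <= fit.params.kappa <= 2.8

    def test_nesting_inequality(self, fast_config):
        from nodevo.scenarios import default_clades, default_species_tree, label_branches

        tree = default_species_tree()
        clades = default_clades()
        label_branches(tree, clades)
        aln, _ = gen_codon_alignment(
            SeqSimConfig(tree=tree, omega_by_class={"background": 0.3, "a": 1.0},
                         n_codons=150, seed=6)
        )
        null = fit_model(aln, tree, (), fast_config)
        shared = dict(fixed_lengths=null.branch_lengths, branch_length_mode="fixed")
        single = fit_model(aln, tree, ("a",), fast_config, **shared)
        multi = fit_model(aln, tree, ("b", "c", "d"), fast_config, **shared)
        two = fit_model(aln, tree, ("a", "b", "c", "d"), fast_config, **shared)
        null_shared = fit_model(aln, tree, (), fast_config, **shared)
        tol = 1e-4  # optimizer tolerance, not model slack
        assert two.lnl_total >= single.lnl_total - tol
        assert two.lnl_total >= multi.lnl_total - tol
        assert single.lnl_total >= null_shared.lnl_total - tol
        assert multi.lnl_total >= null_shared.lnl_total - tol

    def test_deterministic_refit(self, quartet_tree, fast_config):
        aln, _ = gen_codon_alignment(
            SeqSimConfig(tree=quartet_tree, n_codons=100, seed=7)
        )
        f1 = fit_model(aln, quartet_tree, (), fast_config, branch_length_mode="fixed")
        f2 = fit_model(aln, quartet_tree, (), fast_config, branch_length_mode="fixed")
        assert f1.lnl_total == pytest.approx(f2.lnl_total, abs=1e-9)
        # re-evaluating the fitted point reproduces the fitted likelihood
        refit = prune_loglik(aln, quartet_tree, f1.params)
        assert refit.lnl_total == pytest.approx(f1.lnl_total, abs=1e-6)

    def test_free_class_absent_from_tree_fatal(self, quartet_tree, fast_config):
        aln, _ = gen_codon_alignment(
            SeqSimConfig(tree=quartet_tree, n_codons=10, seed=8)
        )
        with pytest.raises(DataError, match="free class"):
            fit_model(aln, quartet_tree, ("a",), fast_config)
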