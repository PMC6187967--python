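import numpy as np
import pytest

from nodevo.codon_model import CodonModelParams, FitResult
from nodevo.data_io import DataError, RunConfig, read_newick
from nodevo.scenarios import (
    SCENARIOS,
    CladeDefinitions,
    ScenarioTestResult,
    available_scenarios,
    default_clades,
    default_species_tree,
    kh_test,
    label_branches,
    run_group,
    sh_test,
    tabulate,
)
from nodevo.simulate import SeqSimConfig, gen_codon_alignment


def fake_fit(site_lnl):
    site_lnl = np.asarray(site_lnl, dtype=float)
    params = CodonModelParams(2.0, {"background": 0.5}, np.full(61, 1 / 61))
    return FitResult(float(site_lnl.sum()), site_lnl, params, np.zeros(1))


def edge_classes(phy):
    out = {}
    for edge in phy.tree.preorder_edge_iter():
        if edge.head_node is phy.tree.seed_node:
            continue
        out.setdefault(edge.branch_class, []).append(edge)
    return out


class TestLabelBranches:
    def test_default_tree_has_one_branch_per_class(self):
        tree = default_species_tree()
        avail = label_branches(tree, default_clades())
        assert avail == {"a": True, "b": True, "c": True, "d": True}
        classes = edge_classes(tree)
        for cls in "abcd":
            assert len(classes[cls]) == 1
        # b and c are the terminal branches of the two actinorhizal hosts
        assert classes["b"][0].head_node.taxon.label == "Cth"
        assert classes["c"][0].head_node.taxon.label == "Dgl"

    def test_non_monophyletic_nfc_disables_class_a(self):
        # outgroup nested inside the NFC members
        tree = read_newick("(((Cth:1,Ath:1):1,(Dgl:1,Mtr:1):1):1,Vvi:2);")
        clades = CladeDefinitions(
            frozenset({"Cth", "Dgl", "Mtr"}), frozenset({"Mtr"}), "Cth", "Dgl"
        )
        avail = label_branches(tree, clades)
        assert not avail["a"]
        assert avail["b"] and avail["c"] and avail["d"]
        assert available_scenarios(avail) == ["NULL", "MULTI"]

    def test_three_taxon_toy(self):
        tree = read_newick("(Cth:1,Dgl:1,Out:2);")
        clades = CladeDefinitions(
            frozenset({"Cth", "Dgl"}), frozenset(), "Cth", "Dgl"
        )
        avail = label_branches(tree, clades)
        assert avail["b"] and avail["c"]
        assert not avail["a"] and not avail["d"]

    def test_missing_focal_tip_fatal(self):
        tree = read_newick("(Dgl:1,Mtr:1,Vvi:2);")
        with pytest.raises(DataError, match="Cth"):
            label_branches(tree, default_clades())


class TestKHTest:
    def test_identical_vectors_give_p_one(self):
        f = fake_fit(np.full(100, -3.0))
        assert kh_test(f, f, n_rell=200, seed=0) == 1.0

    def test_uniform_advantage_is_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(-3, 1, size=500)
        f1 = fake_fit(base + 0.1)  # better at every site
        f2 = fake_fit(base)
        assert kh_test(f1, f2, n_rell=1000, seed=1) < 0.05

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        f1 = fake_fit(rng.normal(-3, 1, 200))
        f2 = fake_fit(rng.normal(-3, 1, 200))
        assert kh_test(f1, f2, 500, seed=3) == kh_test(f2, f1, 500, seed=3)

    def test_length_mismatch_fatal(self):
        with pytest.raises(DataError):
            kh_test(fake_fit(np.zeros(10)), fake_fit(np.zeros(11)), 100, 0)


class TestSHTest:
    def test_identical_candidates_nothing_rejected(self):
        lnl = np.random.default_rng(0).normal(-3, 1, 300)
        fits = {name: fake_fit(lnl) for name in SCENARIOS}
        _, rejected = sh_test(fits, n_rell=500, alpha=0.05, seed=0)
        assert rejected == set()

    def test_dominated_candidate_rejected(self):
        rng = np.random.default_rng(1)
        base = rng.normal(-3, 1, 300)
        fits = {
            "GOOD": fake_fit(base),
            "BAD": fake_fit(base - 50.0 / 300),  # worse by 50 lnL in total
        }
        p, rejected = sh_test(fits, n_rell=1000, alpha=0.05, seed=2)
        assert rejected == {"BAD"}
        assert p["GOOD"] >= 0.05

    def test_best_candidate_never_rejected(self):
        rng = np.random.default_rng(3)
        base = rng.normal(-3, 1, 200)
        fits = {"A": fake_fit(base + 1), "B": fake_fit(base), "C": fake_fit(base - 1)}
        _, rejected = sh_test(fits, 500, 0.05, seed=4)
        assert "A" not in rejected

    def test_input_order_invariant(self):
        rng = np.random.default_rng(5)
        fits = {n: fake_fit(rng.normal(-3, 1, 200)) for n in ("X", "Y", "Z")}
        p1, r1 = sh_test(fits, 500, 0.05, seed=6)
        reordered = {k: fits[k] for k in ("Z", "X", "Y")}
        p2, r2 = sh_test(reordered, 500, 0.05, seed=6)
        assert p1 == p2 and r1 == r2

    def test_single_candidate_empty_rejection(self):
        _, rejected = sh_test({"NULL": fake_fit(np.zeros(10))}, 100, 0.05, 0)
        assert rejected == set()


def make_result(group_id, a_cat, bcd_cat):
    return ScenarioTestResult(
        group_id, {}, {}, {}, set(), True, a_cat, bcd_cat, None
    )


class TestTabulate:
    def test_empty_input_all_zero(self):
        table = tabulate([])
        assert (table["total"] == 0).all()

    def test_hand_built_counts(self):
        results = (
            [make_result(f"g{i}", "reject_SINGLE", "reject_neither") for i in range(4)]
            + [make_result("g4", "reject_neither", "reject_MULTI")]
            + [make_result("g5", "reject_TWOSTEP", "n.a.")]
            + [make_result("g6", "n.a.", "n.a.")]
        )
        table = tabulate(results).set_index("branches")
        assert table.loc["a", "alternative"] == "SINGLE"
        assert table.loc["a", "reject_alternative"] == 4
        assert table.loc["a", "reject_neither"] == 1
        assert table.loc["a", "reject_TWOSTEP"] == 1
        assert table.loc["a", "total"] == 6
        assert table.loc["b,c,d", "reject_alternative"] == 1
        assert table.loc["b,c,d", "total"] == 5
        for row in ("a", "b,c,d"):
            pct = [v for c, v in table.loc[row].items() if str(c).endswith("_pct")]
            assert sum(pct) == pytest.approx(100.0)


class TestRunGroup:
    def test_missing_clades_yield_na_categories(self):
        # no legumes on the tree: MULTI and TWOSTEP cannot be tested
        nwk = "((Cth:0.2,Dgl:0.2):0.1,(Ath:0.3,Vvi:0.3):0.1);"
        tree = read_newick(nwk)
        clades = CladeDefinitions(
            frozenset({"Cth", "Dgl", "Mtr"}), frozenset({"Mtr"}), "Cth", "Dgl"
        )
        label_branches(tree, clades)
        aln, _ = gen_codon_alignment(SeqSimConfig(tree=tree, n_codons=80, seed=9))
        cfg = RunConfig(n_starts=1, n_rell=300, seed=1)
        res = run_group(aln, read_newick(nwk), None, clades, cfg)
        assert set(res.skipped) == {"MULTI", "TWOSTEP"}
        assert res.branch_bcd_category == "n.a."
        # NULL-simulated data: NULL should not be rejected
        assert not res.null_rejected
        assert res.branch_a_category == "n.a."

    def test_unconstrained_tree_used_only_when_better(self):
        clades = default_clades()
        tree = default_species_tree()
        label_branches(tree, clades)
        aln, _ = gen_codon_alignment(SeqSimConfig(tree=tree, n_codons=120, seed=10))
        cfg = RunConfig(n_starts=1, n_rell=300, seed=2)
        # same topology offered as "unconstrained": cannot be significantly better
        res = run_group(
            aln, default_species_tree(), default_species_tree(), clades, cfg
        )
        assert res.tree_choice.chosen == "constrained"
        assert res.tree_choice.kh_p >= 0.05

    def test_strong_branch_a_shift_detected(self):
        clades = default_clades()
        tree = default_species_tree()
        label_branches(tree, clades)
        aln, _ = gen_codon_alignment(
            SeqSimConfig(
                tree=tree,
                omega_by_class={"background": 0.1, "a": 8.0},
                n_codons=500,
                seed=11,
            )
        )
        cfg = RunConfig(n_starts=1, n_rell=500, seed=3)
        res = run_group(aln, default_species_tree(), None, clades, cfg)
        assert res.null_rejected
        # scenarios allowing a shift on branch a must be retained
        assert "SINGLE" not in res.rejected
        assert "TWOSTEP" not in res.rejected
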