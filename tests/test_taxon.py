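"""Monophyly tests, clade counts, and the PMT/TCI/TRI indices."""

import numpy as np
import pytest

import genegauge as gg
from _oracles import min_steps_by_enumeration, random_tree


def group(members, rank="genus", name="X"):
    return gg.ConcordanceGroup(rank, name, frozenset(members))


def membership(tree, assignment: dict[str, str], rank="genus"):
    terminals = sorted(assignment)
    byname: dict[str, set] = {}
    for t, g in assignment.items():
        byname.setdefault(g, set()).add(t)
    groups = [gg.ConcordanceGroup(rank, n, frozenset(m))
              for n, m in sorted(byname.items())]
    return gg.MembershipMatrix(rank, terminals, groups)


class TestMonophyly:
    def test_clade_is_monophyletic(self, balanced_quartet):
        assert gg.is_monophyletic(balanced_quartet, group({"a", "b"}))

    def test_scattered_group_is_not(self, balanced_quartet):
        assert not gg.is_monophyletic(balanced_quartet, group({"a", "c"}))

    def test_all_leaves_is_the_root_clade(self, balanced_quartet):
        assert gg.is_monophyletic(balanced_quartet, group(set("abcd")))

    def test_rooted_convention_rejects_complement(self):
        tree = gg.tree_from_newick("(a,(b,(c,d)));")
        assert not gg.is_monophyletic(tree, group({"a", "b"}))
        assert gg.is_monophyletic(tree, group({"a", "b"}), unrooted=True)

    def test_absent_member_rejected(self, balanced_quartet):
        with pytest.raises(gg.ValidationError):
            gg.is_monophyletic(balanced_quartet, group({"a", "z"}))


class TestCladeCount:
    def test_monophyletic_group_is_one_clade(self, balanced_quartet):
        assert gg.clade_count(balanced_quartet, group({"c", "d"})) == 1

    def test_split_group_counts_its_pieces(self, balanced_quartet):
        assert gg.clade_count(balanced_quartet, group({"a", "c"})) == 2

    def test_all_leaves_clamped_to_one(self, balanced_quartet):
        assert gg.clade_count(balanced_quartet, group(set("abcd"))) == 1

    def test_equals_membership_character_steps(self, rng):
        """s_t equals the exact parsimony length of the 0/1 character."""
        for _ in range(120):
            n = int(rng.integers(5, 11))
            labels = [f"t{i}" for i in range(n)]
            tree = random_tree(labels, rng, p_polytomy=0.2)
            size = int(rng.integers(1, n))
            members = set(rng.choice(labels, size=size, replace=False))
            char = {lab: int(lab in members) for lab in labels}
            expected = max(1, min_steps_by_enumeration(tree, char))
            assert gg.clade_count(tree, group(members)) == expected

    def test_bounded_by_member_count(self, rng):
        labels = [f"t{i}" for i in range(8)]
        tree = random_tree(labels, rng)
        members = {"t0", "t3", "t6"}
        assert 1 <= gg.clade_count(tree, group(members)) <= len(members)


class TestTaxonCongruence:
    def test_all_monophyletic_scores_one(self):
        tree = gg.tree_from_newick(
            "(((a1,a2),(b1,b2)),((c1,c2),(d1,d2)));")
        mm = membership(tree, {t: t[0].upper() for t in
                               gg.io.leaf_labels(tree)})
        sc = gg.taxon_congruence(tree, mm)
        assert (sc.pmt, sc.tci, sc.tri) == (1.0, 1.0, 1.0)

    def test_ten_leaf_hand_computed_example(self):
        # 10 terminals, 3 groups; A and B are clades, C falls in two clades
        # separated by B, so s = (1, 1, 2) and S_t = 4
        tree = gg.tree_from_newick(
            "(((a1,a2),a3),((c1,c2),((b1,(b2,b3)),(c3,c4))));"
        )
        mm = membership(tree, {
            "a1": "A", "a2": "A", "a3": "A",
            "b1": "B", "b2": "B", "b3": "B",
            "c1": "C", "c2": "C", "c3": "C", "c4": "C",
        })
        sc = gg.taxon_congruence(tree, mm)
        assert sc.M_t == 3 and sc.G_t == 10 and sc.S_t == 4
        assert sc.tci == pytest.approx(0.75)
        assert sc.tri == pytest.approx(6 / 7)
        assert sc.pmt == pytest.approx(2 / 3)

    def test_worst_case_tri_is_zero(self):
        # two groups, every member isolated on a comb: S_t = G_t
        tree = gg.tree_from_newick("(a1,(b1,(a2,(b2,(a3,b3)))));")
        mm = membership(tree, {"a1": "A", "a2": "A", "a3": "A",
                               "b1": "B", "b2": "B", "b3": "B"})
        sc = gg.taxon_congruence(tree, mm)
        assert sc.S_t == sc.G_t
        assert sc.tri == 0.0

    def test_tci_one_iff_pmt_one(self, rng):
        """For minority groups (< half the leaves) TCI = 1 iff PMT = 1.

        A group smaller than half the leaf set forms a single clade (one
        membership-character step) exactly when it is rooted-monophyletic;
        only a majority group whose complement is a buried clade can break
        the equivalence, and concordance groups are never like that.
        """
        for _ in range(40):
            n = int(rng.integers(7, 13))
            labels = [f"t{i}" for i in range(n)]
            tree = random_tree(labels, rng)
            shuffled = list(rng.permutation(labels))
            assignment = {lab: f"G{i % 3}" for i, lab in enumerate(shuffled)}
            mm = membership(tree, assignment)
            assert all(len(g.members) < n / 2 for g in mm.groups)
            sc = gg.taxon_congruence(tree, mm)
            assert (sc.tci == 1.0) == (sc.pmt == 1.0)

    def test_undefined_tri_reported_missing(self):
        tree = gg.tree_from_newick("(a,b);")
        mm = membership(tree, {"a": "A", "b": "B"})
        sc = gg.taxon_congruence(tree, mm)
        assert sc.tri is None

    def test_empty_group_set_rejected(self, balanced_quartet):
        mm = gg.MembershipMatrix("genus", list("abcd"), [])
        with pytest.raises(gg.ValidationError):
            gg.taxon_congruence(balanced_quartet, mm)


class TestMultiTree:
    def test_identical_trees_have_zero_range(self):
        trees = [gg.tree_from_newick("((a,b),(c,d));") for _ in range(3)]
        mm = membership(trees[0], {"a": "A", "b": "A", "c": "B", "d": "B"})
        df = gg.taxon_congruence_multi(trees, mm)
        mean = df[df["tree"] == "__mean__"].iloc[0]
        lo = df[df["tree"] == "__min__"].iloc[0]
        hi = df[df["tree"] == "__max__"].iloc[0]
        assert mean["tci"] == lo["tci"] == hi["tci"] == 1.0

    def test_mean_is_halfway_for_two_trees(self):
        t1 = gg.tree_from_newick("((a,b),(c,d));")
        t2 = gg.tree_from_newick("((a,c),(b,d));")
        mm = membership(t1, {"a": "A", "b": "A", "c": "B", "d": "B"})
        df = gg.taxon_congruence_multi([t1, t2], mm)
        per_tree = df[df["tree"].isin(["0", "1"])]["pmt"].tolist()
        mean = df[df["tree"] == "__mean__"].iloc[0]["pmt"]
        assert mean == pytest.approx(np.mean(per_tree))
        assert sorted(per_tree) == [0.0, 1.0]

    def test_consensus_never_beats_the_best_tree(self, rng):
        labels = [f"t{i}" for i in range(8)]
        assignment = {lab: f"G{i % 3}" for i, lab in enumerate(labels)}
        for _ in range(10):
            trees = [random_tree(labels, rng) for _ in range(2)]
            mm = membership(trees[0], assignment)
            df = gg.taxon_congruence_multi(trees, mm, consensus=True)
            best = df[df["tree"].isin(["0", "1"])]["pmt"].max()
            cons = df[df["tree"] == "__consensus__"].iloc[0]["pmt"]
            assert cons <= best + 1e-12

    def test_leaf_set_mismatch_rejected(self):
        t1 = gg.tree_from_newick("((a,b),(c,d));")
        t2 = gg.tree_from_newick("((a,b),(c,e));")
        mm = membership(t1, {"a": "A", "b": "A", "c": "B", "d": "B"})
        with pytest.raises(gg.ValidationError):
            gg.taxon_congruence_multi([t1, t2], mm)


class TestSyntheticRecovery:
    def test_perfect_recovery_on_clade_taxonomy(self):
        cfg = gg.ScenarioConfig(n_species=32, seq_length=40, seed=17)
        bundle = gg.simulate_bundle(cfg)
        for rank in gg.RANKS:
            mm = gg.build_membership_matrix(
                bundle.taxonomy, rank, sorted(bundle.taxonomy.index),
                min_size=1)
            sc = gg.taxon_congruence(bundle.tree, mm)
            assert (sc.pmt, sc.tci, sc.tri) == (1.0, 1.0, 1.0)

    def test_degradation_with_label_perturbation(self):
        levels = [0.0, 0.2, 0.5]
        means = []
        for level in levels:
            vals = []
            for seed in range(8):
                cfg = gg.ScenarioConfig(n_species=24, seq_length=10,
                                        perturb_fraction=level, seed=seed)
                b = gg.simulate_bundle(cfg)
                mm = gg.build_membership_matrix(
                    b.taxonomy, "genus", sorted(b.taxonomy.index), min_size=1)
                vals.append(gg.taxon_congruence(b.tree, mm).tci)
            means.append(np.mean(vals))
        assert means[0] == 1.0
        assert means[0] >= means[1] >= means[2]
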