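"""Calibration arithmetic, Brownian covariance, signal statistics and
squared-change parsimony, checked against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

import eelmorph as em
from eelmorph.errors import CalibrationError, TreeError
from eelmorph.phylocomp import _lambda_loglik, lambda_transform
from eelmorph.types import CalibrationConstraint


def _constraint(labels, age, kind="fixed"):
    return CalibrationConstraint(mrca_of=frozenset(labels), age=age, kind=kind)


class TestCalibration:
    def test_mean_of_brackets_interpolation(self):
        # unconstrained node bracketed by a 99 Ma ancestor and an 86 Ma
        # descendant clade dates to their mean, 92.5 Ma
        phy = em.from_newick("(((A,B),C),D);")
        cal = em.calibrate_tree(
            phy,
            constraints=[_constraint("ABCD", 99.0), _constraint("AB", 86.0)],
        )
        assert cal.node_age(cal.mrca(["A", "B", "C"])) == pytest.approx(92.5)

    def test_extant_terminal_branch_spans_full_parent_age(self):
        phy = em.from_newick("((A,B),C);")
        cal = em.calibrate_tree(
            phy, constraints=[_constraint("ABC", 80.0), _constraint("AB", 60.0)]
        )
        tip = next(l for l in cal.tree.leaf_node_iter() if l.taxon.label == "A")
        assert cal.node_age(tip.parent_node) - cal.node_age(tip) == pytest.approx(60.0)

    def test_fossil_terminal_branch_is_ghost_lineage_arithmetic(self):
        # a 49 Ma fossil under an 81 Ma node leaves a 32 Ma terminal branch
        phy = em.from_newick("((F,X),Y);")
        cal = em.calibrate_tree(
            phy,
            tip_ages={"F": (49.0, 40.0)},
            constraints=[_constraint("FXY", 99.0), _constraint("FX", 81.0)],
        )
        tip = next(l for l in cal.tree.leaf_node_iter() if l.taxon.label == "F")
        assert cal.node_age(tip.parent_node) - cal.node_age(tip) == pytest.approx(32.0)

    def test_minimum_constraint_pushed_by_older_fossil(self):
        phy = em.from_newick("((F,X),Y);")
        cal = em.calibrate_tree(
            phy,
            tip_ages={"F": (70.0, 60.0)},
            constraints=[_constraint("FXY", 99.0), _constraint("FX", 50.0, "minimum")],
        )
        assert cal.node_age(cal.mrca(["F", "X"])) == pytest.approx(70.0)

    def test_fixed_constraint_younger_than_fossil_conflicts(self):
        phy = em.from_newick("((F,X),Y);")
        with pytest.raises(CalibrationError, match="F"):
            em.calibrate_tree(
                phy,
                tip_ages={"F": (70.0, 60.0)},
                constraints=[_constraint("FXY", 99.0), _constraint("FX", 50.0, "fixed")],
            )

    def test_parent_strictly_older_everywhere_and_idempotent(self):
        phy = em.from_newick("(((A,B),(C,D)),(E,(F,G)));")
        constraints = [_constraint("ABCDEFG", 100.0), _constraint("AB", 40.0)]
        ages = {"C": (55.0, 50.0), "F": (20.0, 10.0)}
        cal = em.calibrate_tree(phy, tip_ages=ages, constraints=constraints)
        for node in cal.tree.preorder_node_iter():
            if node.parent_node is not None:
                assert cal.node_age(node.parent_node) > cal.node_age(node)
        again = em.calibrate_tree(cal, tip_ages=ages, constraints=constraints)
        for n1, n2 in zip(cal.tree.preorder_node_iter(), again.tree.preorder_node_iter()):
            assert cal.node_age(n1) == pytest.approx(again.node_age(n2))

    def test_polytomies_calibrate_without_resolution(self):
        phy = em.from_newick("((A,B,C,D),(E,F));")
        cal = em.calibrate_tree(phy, constraints=[_constraint("ABCDEF", 50.0)])
        poly = cal.mrca(["A", "B", "C", "D"])
        assert len(poly.child_nodes()) == 4
        assert cal.node_age(poly) == pytest.approx(25.0)


class TestBMCovariance:
    def test_star_tree_is_diagonal(self):
        phy = em.star_tree([f"t{i}" for i in range(5)], depth=3.0)
        C = em.bm_covariance(phy).to_numpy()
        assert np.allclose(C, 3.0 * np.eye(5))

    def test_sister_pair_shares_half_depth(self, small_dated_tree):
        C = em.bm_covariance(small_dated_tree)
        assert C.loc["A", "B"] == pytest.approx(7.0)  # root 10, MRCA(A,B) at 3
        assert C.loc["A", "A"] == pytest.approx(10.0)
        assert C.loc["A", "D"] == 0.0

    def test_matches_path_enumeration_oracle(self):
        phy = em.simulate_yule_tree(12, 1.0, seed=11)
        C = em.bm_covariance(phy)
        labels = C.index.tolist()
        root_age = phy.node_age(phy.root)
        leaves = {l.taxon.label: l for l in phy.tree.leaf_node_iter()}

        def ancestors(node):
            out = []
            while node is not None:
                out.append(node)
                node = node.parent_node
            return out

        for i, j in itertools.combinations_with_replacement(labels, 2):
            anc_i = ancestors(leaves[i])
            anc_j = set(ancestors(leaves[j]))
            mrca = next(n for n in anc_i if n in anc_j)
            assert C.loc[i, j] == pytest.approx(root_age - phy.node_age(mrca), abs=1e-12)

    def test_uncalibrated_tree_rejected(self):
        with pytest.raises(TreeError, match="calibrate"):
            em.bm_covariance(em.from_newick("((A,B),C);"))


class TestBlombergK:
    def test_star_tree_gives_k_of_one_for_any_trait(self):
        phy = em.star_tree([f"t{i}" for i in range(10)], depth=2.0)
        rng = np.random.default_rng(12)
        for _ in range(5):
            tr = pd.Series(rng.normal(size=10), index=phy.tip_labels)
            r = em.blomberg_k(phy, tr, n_permutations=0)
            assert r.estimate == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self):
        phy = em.simulate_yule_tree(16, 1.0, seed=13)
        tr = em.simulate_bm_trait(phy, seed=13)
        k1 = em.blomberg_k(phy, tr, n_permutations=0).estimate
        k2 = em.blomberg_k(phy, -3.2 * tr + 7.0, n_permutations=0).estimate
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_white_noise_on_imbalanced_tree_has_low_k(self):
        # a caterpillar (maximally imbalanced) tree: traitless-of-structure
        # data should look less similar among relatives than BM predicts
        newick = "(" * 31 + "t0,t1)" + "".join(f",t{i})" for i in range(2, 32)) + ";"
        phy = em.from_newick(newick)
        for i, node in enumerate(phy.tree.postorder_node_iter()):
            node.age = 0.0 if node.is_leaf() else None
        # date internals: each caterpillar level one unit older
        depth = {}
        for node in phy.tree.postorder_node_iter():
            if node.is_leaf():
                depth[node] = 0
            else:
                depth[node] = max(depth[c] for c in node.child_nodes()) + 1
                node.age = float(depth[node])
        rng = np.random.default_rng(14)
        ks = []
        for i in range(50):
            tr = pd.Series(rng.normal(size=32), index=phy.tip_labels)
            ks.append(em.blomberg_k(phy, tr, n_permutations=0).estimate)
        assert np.median(ks) < 1.0

    def test_permutation_p_value_detects_bm_signal(self):
        phy = em.simulate_yule_tree(32, 1.0, seed=15)
        tr = em.simulate_bm_trait(phy, seed=15)
        r = em.blomberg_k(phy, tr, n_permutations=199, seed=0)
        assert 0.0 < r.p_value <= 0.10
        assert r.n_permutations == 199


class TestPagelLambda:
    def test_transform_endpoints(self, small_dated_tree):
        C = em.bm_covariance(small_dated_tree).to_numpy()
        assert np.allclose(lambda_transform(C, 1.0), C)
        assert np.allclose(lambda_transform(C, 0.0), np.diag(np.diag(C)))

    def test_optimality_of_estimate(self):
        phy = em.simulate_yule_tree(32, 1.0, seed=16)
        C = em.bm_covariance(phy).to_numpy()
        tr = em.simulate_bm_trait(phy, lambda_true=0.5, seed=16)
        r = em.pagel_lambda(phy, tr)
        x = tr.reindex(em.bm_covariance(phy).index).to_numpy()
        assert r.log_likelihood >= _lambda_loglik(0.0, C, x) - 1e-8
        assert r.log_likelihood >= _lambda_loglik(1.0, C, x) - 1e-8

    def test_affine_invariance(self):
        phy = em.simulate_yule_tree(24, 1.0, seed=17)
        tr = em.simulate_bm_trait(phy, lambda_true=0.6, seed=17)
        l1 = em.pagel_lambda(phy, tr).estimate
        l2 = em.pagel_lambda(phy, 5.0 * tr - 2.0).estimate
        assert l1 == pytest.approx(l2, abs=1e-4)

    def test_strong_signal_vs_shuffled(self):
        phy = em.simulate_yule_tree(48, 1.0, seed=18)
        tr = em.simulate_bm_trait(phy, seed=18)
        strong = em.pagel_lambda(phy, tr)
        rng = np.random.default_rng(18)
        shuffled = pd.Series(rng.permutation(tr.to_numpy()), index=tr.index)
        weak = em.pagel_lambda(phy, shuffled)
        assert strong.estimate > 0.8
        assert weak.estimate < strong.estimate


def _grid_minimise(phy, trait, step=1e-3):
    """Coordinate-wise grid descent oracle for squared-change parsimony."""
    internals = [n for n in phy.tree.preorder_node_iter() if not n.is_leaf()]
    vals = {n: float(trait[n.taxon.label]) for n in phy.tree.leaf_node_iter()}
    lo = float(trait.min()) - 1.0
    hi = float(trait.max()) + 1.0
    grid = np.arange(lo, hi + step, step)
    for n in internals:
        vals[n] = float(trait.mean())

    def cost():
        return sum(
            (vals[n.parent_node] - vals[n]) ** 2
            for n in phy.tree.preorder_node_iter()
            if n.parent_node is not None
        )

    prev = np.inf
    for _ in range(200):
        for n in internals:
            neigh = [vals[c] for c in n.child_nodes()]
            if n.parent_node is not None:
                neigh.append(vals[n.parent_node])
            contrib = np.sum([(grid - v) ** 2 for v in neigh], axis=0)
            vals[n] = float(grid[np.argmin(contrib)])
        c = cost()
        if prev - c < 1e-12:
            break
        prev = c
    return vals, cost()


class TestParsimonyASR:
    def test_constant_trait_reconstructs_at_zero_cost(self):
        phy = em.from_newick("((A,B),(C,(D,E)));")
        tr = pd.Series(4.0, index=phy.tip_labels)
        r = em.parsimony_asr(phy, tr)
        assert r.cost == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(4.0) for v in r.node_values.values())

    def test_two_tip_closed_form(self):
        phy = em.from_newick("(A,B);")
        r = em.parsimony_asr(phy, pd.Series({"A": 1.0, "B": 5.0}))
        assert r.root_value(phy) == pytest.approx(3.0)
        assert r.cost == pytest.approx((1.0 - 5.0) ** 2 / 2.0)

    def test_matches_grid_minimisation_oracle(self):
        rng = np.random.default_rng(19)
        for rep in range(20):
            phy = em.simulate_yule_tree(5, 1.0, seed=100 + rep)
            tr = pd.Series(rng.uniform(0, 5, size=5), index=phy.tip_labels)
            r = em.parsimony_asr(phy, tr)
            oracle_vals, oracle_cost = _grid_minimise(phy, tr)
            for node, v in oracle_vals.items():
                assert r.node_values[node] == pytest.approx(v, abs=2e-3)
            assert r.cost <= oracle_cost + 1e-9

    def test_polytomy_handled_natively(self):
        phy = em.from_newick("(A,B,C,D);")
        tr = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0, "D": 6.0})
        r = em.parsimony_asr(phy, tr)
        assert r.root_value(phy) == pytest.approx(3.0)  # mean of the tips

    def test_missing_tip_values_listed(self):
        phy = em.from_newick("((A,B),C);")
        with pytest.raises(TreeError, match="C"):
            em.parsimony_asr(phy, pd.Series({"A": 1.0, "B": 2.0}))

    def test_cost_decreases_as_tip_approaches_neighbour(self):
        rng = np.random.default_rng(20)
        for rep in range(10):
            phy = em.simulate_yule_tree(8, 1.0, seed=200 + rep)
            tr = pd.Series(rng.uniform(0, 10, size=8), index=phy.tip_labels)
            base = em.parsimony_asr(phy, tr)
            tip = phy.tip_labels[0]
            neighbour_value = base.node_values[
                next(l for l in phy.tree.leaf_node_iter()).parent_node
            ]
            moved = tr.copy()
            moved[tip] = tr[tip] + 0.5 * (neighbour_value - tr[tip])
            assert em.parsimony_asr(phy, moved).cost <= base.cost + 1e-9
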