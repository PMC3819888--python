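"""Kernel-tree engine and GP evolution for the multiple-kernel SVM."""

import numpy as np
import pytest

from erpkit.emk import (EXP_CAP, GPConfig, KernelTree, crossover,
                        eval_kernel_tree, evolve, fitness, gram_matrix,
                        mutate, random_tree)

TABLE5_THETA_0BACK = ("(exp (* -1.68 (* (* K_Poly K_Poly)"
                      " (* K_RBF K_RBF))))")


def stack_eval(tree: KernelTree, kp: float, kr: float) -> float:
    """Independent oracle: iterative post-order stack evaluation."""
    order, stack = [], [tree]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(node.children)
    values = {}
    for node in reversed(order):
        if node.op == "poly":
            values[id(node)] = kp
        elif node.op == "rbf":
            values[id(node)] = kr
        elif node.op == "const":
            values[id(node)] = node.value
        elif node.op == "+":
            values[id(node)] = (values[id(node.children[0])] +
                                values[id(node.children[1])])
        elif node.op == "*":
            values[id(node)] = (values[id(node.children[0])] *
                                values[id(node.children[1])])
        elif node.op == "exp":
            arg = values[id(node.children[0])]
            values[id(node)] = float(np.exp(np.clip(arg, -EXP_CAP,
                                                    EXP_CAP)))
    return values[id(tree)]


class TestEvaluation:
    def test_poly_leaf_matches_definition(self):
        tree = KernelTree("poly")
        assert eval_kernel_tree(tree, [1, 2], [3, 4]) == pytest.approx(12.0)

    def test_rbf_leaf_at_coincident_points(self):
        tree = KernelTree("rbf")
        assert eval_kernel_tree(tree, [1.5, -2], [1.5, -2]) == \
            pytest.approx(1.0)

    def test_published_theta_kernel_anchor_value(self):
        """exp(-1.68 K_Poly^2 K_RBF^2) at x = y = 0 is exp(-1.68)."""
        tree = KernelTree.from_string(TABLE5_THETA_0BACK)
        val = eval_kernel_tree(tree, np.zeros(3), np.zeros(3))
        assert val == pytest.approx(np.exp(-1.68), rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            eval_kernel_tree(KernelTree("rbf"), [1, 2], [1, 2, 3])

    def test_exp_overflow_saturates_with_warning(self):
        tree = KernelTree("exp", children=[KernelTree("poly")])
        with pytest.warns(RuntimeWarning):
            val = eval_kernel_tree(tree, [100.0], [100.0])
        assert val == pytest.approx(np.exp(EXP_CAP))

    @pytest.mark.parametrize("seed", range(40))
    def test_symmetry_and_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        cfg = GPConfig(pop_size=2)
        tree = random_tree(cfg, rng)
        x, y = rng.standard_normal((2, 4))
        kxy = eval_kernel_tree(tree, x, y)
        kyx = eval_kernel_tree(tree, y, x)
        assert abs(kxy - kyx) < 1e-12
        kp = float(np.dot(x, y) + 1.0)
        kr = float(np.exp(-0.5 * np.sum((x - y) ** 2)))
        assert kxy == pytest.approx(stack_eval(tree, kp, kr), rel=1e-12,
                                    abs=1e-12)

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            tree = random_tree(GPConfig(pop_size=2), rng)
            back = KernelTree.from_string(tree.to_string())
            assert back.to_string() == tree.to_string()


class TestGram:
    def test_rbf_gram_already_psd(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        G, repair = gram_matrix(KernelTree("rbf"), X)
        assert repair.min_eigenvalue >= -1e-10
        assert not repair.clipped

    def test_indefinite_tree_repaired_to_psd(self):
        # K_Poly - 0.9: shifts the spectrum negative
        tree = KernelTree("+", children=[
            KernelTree("poly"), KernelTree("const", value=-0.9)])
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 2)) * 0.1
        G, repair = gram_matrix(tree, X)
        evals = np.linalg.eigvalsh(G)
        assert evals.min() >= -1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_random_negative_alpha_trees_clipped(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(GPConfig(pop_size=2), rng)
        X = rng.standard_normal((20, 4))
        G, _ = gram_matrix(tree, X)
        assert np.linalg.eigvalsh(G).min() >= -1e-10

    def test_closure_safe_trees_need_no_repair(self):
        """Sums/products/exp of PSD kernels stay PSD (closure property)."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((25, 3))
        for expr in ("(+ K_Poly K_RBF)", "(* K_RBF K_RBF)", "(exp K_RBF)",
                     "(* K_Poly (+ K_Poly K_RBF))"):
            _, repair = gram_matrix(KernelTree.from_string(expr), X)
            assert repair.min_eigenvalue >= -1e-8


class TestTreeGeneration:
    def test_draws_satisfy_invariants(self):
        rng = np.random.default_rng(0)
        cfg = GPConfig()
        depths = []
        for _ in range(300):
            tree = random_tree(cfg, rng)
            tree.validate(cfg.max_depth)
            depths.append(tree.depth())
        assert max(depths) <= 8
        assert len(set(depths)) >= 3  # ramped generator spans depths

    def test_fixed_seed_reproducible(self):
        cfg = GPConfig()
        t1 = [random_tree(cfg, np.random.default_rng(7)).to_string()
              for _ in range(5)]
        t2 = [random_tree(cfg, np.random.default_rng(7)).to_string()
              for _ in range(5)]
        assert t1 == t2


class TestVariation:
    def test_single_leaf_crossover_swaps_leaves(self):
        a, b = KernelTree("poly"), KernelTree("rbf")
        c1, c2 = crossover(a, b, np.random.default_rng(0))
        assert {c1.op, c2.op} == {"poly", "rbf"}

    def test_offspring_remain_valid(self):
        rng = np.random.default_rng(1)
        cfg = GPConfig()
        for _ in range(200):
            a = random_tree(cfg, rng)
            b = random_tree(cfg, rng)
            c1, c2 = crossover(a, b, rng)
            m = mutate(a, rng)
            for t in (c1, c2, m):
                t.validate(cfg.max_depth)

    def test_mutated_constants_stay_in_range(self):
        rng = np.random.default_rng(2)
        cfg = GPConfig()
        tree = KernelTree.from_string("(+ K_RBF 0.95)")
        for _ in range(200):
            tree2 = mutate(tree, rng)
            consts = [n.value for n in tree2.nodes() if n.op == "const"]
            assert all(-1.0 <= v <= 1.0 for v in consts)


class TestFitness:
    def _blobs(self, seed=0, n=40, sep=4.0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 2))
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        X[y == "b"] += sep / np.sqrt(2)
        return X, y

    def test_separated_blobs_scored_high(self):
        X, y = self._blobs()
        acc = fitness(KernelTree("rbf"), X, y, GPConfig(seed=3))
        assert acc >= 0.95

    def test_shuffled_labels_score_near_chance(self):
        X, _ = self._blobs()
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = rng.permutation(np.array(["a", "b"] * 20))
            accs.append(fitness(KernelTree("rbf"), X, y,
                                GPConfig(seed=seed)))
        assert 0.3 <= np.mean(accs) <= 0.7

    def test_contradictory_duplicates_bounded_by_half(self):
        X = np.tile(np.arange(10.0)[:, None], (2, 2))
        y = np.array(["a"] * 10 + ["b"] * 10)
        acc = fitness(KernelTree("rbf"), X, y, GPConfig(seed=1))
        assert acc <= 0.5

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(ValueError):
            fitness(KernelTree("rbf"), X, np.array(["a"] * 10), GPConfig())


class TestEvolve:
    def test_history_monotone_under_elitism(self):
        X, y = TestFitness()._blobs(seed=5, sep=1.5)
        cfg = GPConfig(pop_size=10, max_gen=6, seed=2)
        res = evolve(X, y, cfg)
        hist = res.best_fitness_history
        assert np.all(np.diff(hist) >= 0)
        assert 0.0 <= res.best_fitness <= 1.0

    def test_zero_generations_returns_initial_best(self):
        X, y = TestFitness()._blobs(seed=6)
        res = evolve(X, y, GPConfig(pop_size=8, max_gen=0, seed=3))
        assert res.best_generation == 0
        assert len(res.history) == 0

    def test_fixed_seed_bit_stable(self):
        X, y = TestFitness()._blobs(seed=7, sep=1.0)
        cfg = GPConfig(pop_size=10, max_gen=4, seed=11)
        r1 = evolve(X, y, cfg)
        r2 = evolve(X, y, cfg)
        assert r1.best_tree.to_string() == r2.best_tree.to_string()
        assert r1.best_fitness == r2.best_fitness
        assert r1.history.equals(r2.history)
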