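"""Flexible neural trees: evaluation, grammar, variation operators, PSO, GGGP."""

import numpy as np
import pytest

from conftest import stack_evaluate
from dfnforest.fnt import (
    FNTNode,
    FNTree,
    GPConfig,
    PSOConfig,
    TreeStructureError,
    crossover,
    evaluate_tree,
    evaluate_tree_batch,
    gggp_search,
    mutate,
    pso_optimize,
    sample_tree,
    tree_from_text,
    tree_rmse,
    tree_to_text,
)


def _leaf(i):
    return FNTNode(kind="terminal", feature_index=i)


def _neuron(children, weights, a=0.0, b=1.0):
    return FNTNode(kind="neuron", children=children, weights=np.asarray(weights, float), a=a, b=b)


@pytest.fixture
def depth2_tree():
    inner = _neuron([_leaf(0), _leaf(1)], [0.5, -0.3], a=0.2, b=0.8)
    root = _neuron([inner, _leaf(2)], [1.2, 0.4], a=-0.1, b=1.5)
    return FNTree(root=root, function_set=frozenset({2}), n_features=3, max_depth=2)


class TestEvaluate:
    def test_terminal_passthrough(self):
        tree = FNTree(root=_leaf(0), function_set=frozenset({2}), n_features=3, max_depth=1)
        assert evaluate_tree(tree, np.array([0.7, 0.0, 0.0])) == pytest.approx(0.7)

    def test_zero_weights_output_one(self, rng):
        root = _neuron([_leaf(0), _leaf(1)], [0.0, 0.0], a=0.0, b=1.0)
        tree = FNTree(root=root, function_set=frozenset({2}), n_features=2, max_depth=1)
        assert evaluate_tree(tree, rng.standard_normal(2)) == pytest.approx(1.0)

    def test_depth2_matches_scalar_arithmetic(self, depth2_tree):
        x = np.array([0.4, -0.6, 1.1])
        inner_net = 0.5 * 0.4 + (-0.3) * (-0.6)
        inner_val = np.exp(-(((inner_net - 0.2) / 0.8) ** 2))
        root_net = 1.2 * inner_val + 0.4 * 1.1
        expected = np.exp(-(((root_net - (-0.1)) / 1.5) ** 2))
        assert evaluate_tree(depth2_tree, x) == pytest.approx(expected, rel=1e-14)

    def test_recursive_equals_stack_oracle_on_random_trees(self):
        rng = np.random.default_rng(202)
        for _ in range(300):
            tree = sample_tree({2, 3, 4}, 6, 3, rng)
            x = rng.standard_normal(6)
            assert evaluate_tree(tree, x) == pytest.approx(
                stack_evaluate(tree, x), rel=1e-14
            )

    def test_batch_matches_scalar(self, depth2_tree, rng):
        X = rng.standard_normal((20, 3))
        batch = evaluate_tree_batch(depth2_tree, X)
        for i in range(20):
            assert batch[i] == pytest.approx(evaluate_tree(depth2_tree, X[i]))

    def test_invalid_arity_rejected(self):
        root = _neuron([_leaf(0), _leaf(1), _leaf(2)], [1.0, 1.0, 1.0])
        with pytest.raises(TreeStructureError, match="arity"):
            FNTree(root=root, function_set=frozenset({2}), n_features=3, max_depth=2)


class TestRmse:
    def test_perfect_predictions(self):
        tree = FNTree(root=_leaf(0), function_set=frozenset({2}), n_features=1, max_depth=1)
        X = np.array([[0.2], [0.9]])
        assert tree_rmse(tree, X, np.array([0.2, 0.9])) == 0.0

    def test_constant_one_versus_zeros(self, rng):
        root = _neuron([_leaf(0), _leaf(1)], [0.0, 0.0])
        tree = FNTree(root=root, function_set=frozenset({2}), n_features=2, max_depth=1)
        assert tree_rmse(tree, rng.standard_normal((7, 2)), np.zeros(7)) == pytest.approx(1.0)

    def test_three_sample_hand_computation(self, depth2_tree):
        X = np.array([[0.1, 0.2, 0.3], [0.0, 0.0, 0.0], [1.0, -1.0, 0.5]])
        y = np.array([0.5, 1.0, 0.0])
        preds = [evaluate_tree(depth2_tree, row) for row in X]
        expected = np.sqrt(np.mean([(p - t) ** 2 for p, t in zip(preds, y)]))
        assert tree_rmse(depth2_tree, X, y) == pytest.approx(expected)

    def test_empty_data_raises(self, depth2_tree):
        with pytest.raises(TreeStructureError, match="empty"):
            tree_rmse(depth2_tree, np.zeros((0, 3)), np.zeros(0))


class TestGrammar:
    def test_depth_one_gives_neuron_over_terminals(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tree = sample_tree({2, 3}, 4, 1, rng)
            assert tree.root.kind == "neuron"
            assert all(c.kind == "terminal" for c in tree.root.children)

    def test_arity_closure_and_depth_bound(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            tree = sample_tree({2, 3, 4}, 8, 3, rng)
            tree.validate()
            assert tree.root.depth() <= 3

            def arities(node):
                if node.kind == "neuron":
                    yield node.arity
                    for c in node.children:
                        yield from arities(c)

            assert set(arities(tree.root)) <= {2, 3, 4}

    def test_sampling_deterministic_under_seed(self):
        t1 = sample_tree({2, 3}, 5, 3, np.random.default_rng(42))
        t2 = sample_tree({2, 3}, 5, 3, np.random.default_rng(42))
        assert tree_to_text(t1) == tree_to_text(t2)

    def test_operators_preserve_validity(self):
        rng = np.random.default_rng(7)
        pool = [sample_tree({2, 3, 4}, 6, 3, rng) for _ in range(20)]
        for _ in range(500):
            i, j = rng.integers(len(pool), size=2)
            c1, c2 = crossover(pool[int(i)], pool[int(j)], rng)
            m = mutate(c1, rng)
            for t in (c1, c2, m):
                t.validate()  # raises on any grammar violation
                assert t.root.depth() <= t.max_depth


class TestSerialization:
    def test_text_round_trip_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            tree = sample_tree({2, 3, 5}, 7, 3, rng)
            clone = tree_from_text(tree_to_text(tree))
            assert tree_to_text(clone) == tree_to_text(tree)
            x = rng.standard_normal(7)
            assert evaluate_tree(clone, x) == evaluate_tree(tree, x)


class TestPSO:
    def test_zero_iterations_returns_tree_unchanged(self, depth2_tree, rng):
        X = rng.standard_normal((10, 3))
        out = pso_optimize(depth2_tree, X, rng.random(10), PSOConfig(iterations=0, seed=0))
        np.testing.assert_array_equal(out.get_parameters(), depth2_tree.get_parameters())

    def test_gbest_trace_nonincreasing(self, rng):
        for seed in range(5):
            tree = sample_tree({2, 3}, 4, 2, np.random.default_rng(seed))
            X = rng.standard_normal((30, 4))
            y = rng.random(30)
            _, trace = pso_optimize(
                tree, X, y, PSOConfig(swarm_size=8, iterations=30, seed=seed),
                return_trace=True,
            )
            assert all(a >= b - 1e-15 for a, b in zip(trace, trace[1:]))

    def test_recovers_single_parameter_optimum(self, rng):
        # teacher tree generates the targets; a grid search over the first
        # weight (others held at teacher values) is the independent oracle
        teacher = FNTree(
            root=_neuron([_leaf(0), _leaf(1)], [1.3, 0.0], a=0.2, b=0.9),
            function_set=frozenset({2}), n_features=2, max_depth=1,
        )
        X = rng.uniform(-1, 1, size=(60, 2))
        y = evaluate_tree_batch(teacher, X)

        grid_best = min(
            tree_rmse(
                FNTree(
                    root=_neuron([_leaf(0), _leaf(1)], [w, 0.0], a=0.2, b=0.9),
                    function_set=frozenset({2}), n_features=2, max_depth=1,
                ),
                X, y,
            )
            for w in np.linspace(-3, 3, 1201)
        )
        start = FNTree(
            root=_neuron([_leaf(0), _leaf(1)], [-0.5, 0.4], a=-0.3, b=1.4),
            function_set=frozenset({2}), n_features=2, max_depth=1,
        )
        tuned = pso_optimize(
            start, X, y, PSOConfig(swarm_size=20, iterations=100, seed=11)
        )
        assert tree_rmse(tuned, X, y) <= grid_best + 0.05

    def test_velocity_cap_bounds_position_steps(self, rng):
        # with a tiny v_max every coordinate moves at most v_max per iteration
        tree = sample_tree({2}, 3, 2, np.random.default_rng(1))
        X = rng.standard_normal((20, 3))
        y = rng.random(20)
        cfg = PSOConfig(swarm_size=4, iterations=1, v_max=1e-3, seed=2)
        out = pso_optimize(tree, X, y, cfg)
        base = tree.get_parameters()
        # gbest came from an initial particle or moved <= v_max per coordinate;
        # after one iteration no parameter can sit farther than init spread + v_max
        assert np.all(np.abs(out.get_parameters() - base) <= 2.0 + 1e-3 + 1e-12)

    def test_seed_determinism(self, depth2_tree, rng):
        X = rng.standard_normal((15, 3))
        y = rng.random(15)
        cfg = PSOConfig(swarm_size=6, iterations=10, seed=4)
        a = pso_optimize(depth2_tree, X, y, cfg)
        b = pso_optimize(depth2_tree, X, y, cfg)
        np.testing.assert_array_equal(a.get_parameters(), b.get_parameters())

    def test_b_kept_away_from_zero(self, rng):
        tree = sample_tree({2, 3}, 4, 2, np.random.default_rng(0))
        X = rng.standard_normal((10, 4))
        y = rng.random(10)
        out = pso_optimize(tree, X, y, PSOConfig(swarm_size=6, iterations=20, seed=1))

        def min_abs_b(node):
            if node.kind == "terminal":
                return np.inf
            return min(abs(node.b), *(min_abs_b(c) for c in node.children))

        assert min_abs_b(out.root) >= 0.05


class TestGGGP:
    def test_learns_gaussian_bump_pattern(self):
        # y = 1 where x0 is near 0; a single +2 neuron expresses this exactly,
        # so the search must reach RMSE < 0.2 within 20 generations
        rng = np.random.default_rng(5)
        X = rng.uniform(-2, 2, size=(80, 3))
        y = np.exp(-(X[:, 0] ** 2))
        hand = FNTree(
            root=_neuron([_leaf(0), _leaf(1)], [1.0, 0.0], a=0.0, b=1.0),
            function_set=frozenset({2}), n_features=3, max_depth=2,
        )
        assert tree_rmse(hand, X, y) < 0.2  # feasibility certificate
        tree = gggp_search(
            X, y, {2, 3},
            GPConfig(population_size=20, generations=20, seed=1),
            PSOConfig(swarm_size=8, iterations=30, seed=1),
            max_depth=2,
        )
        assert tree_rmse(tree, X, y) < 0.2

    def test_no_variation_population_preserved(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.random(20)
        gp = GPConfig(
            population_size=8, crossover_prob=0.0, mutation_prob=0.0,
            generations=3, seed=2, final_candidates=1,
        )
        pso = PSOConfig(swarm_size=4, iterations=5, seed=2)
        tree = gggp_search(X, y, {2, 3}, gp, pso, max_depth=2)
        tree.validate()

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((25, 4))
        y = (X[:, 0] > 0).astype(float)
        gp = GPConfig(population_size=10, generations=3, seed=6)
        pso = PSOConfig(swarm_size=5, iterations=10, seed=6)
        t1 = gggp_search(X, y, {2, 3}, gp, pso, max_depth=2)
        t2 = gggp_search(X, y, {2, 3}, gp, pso, max_depth=2)
        assert tree_to_text(t1) == tree_to_text(t2)
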