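import numpy as np
import pytest

from lrhunt.forest_core import (
    ForestParams,
    Tree,
    best_split,
    draw_bootstrap,
    grow_forest,
    grow_tree,
    select_pseudo_responses,
    split_statistic,
)


def brute_force_best_split(data, cases, candidate_vars, response_set):
    """Exhaustive enumeration oracle: every candidate variable, every
    midpoint between consecutive distinct observed values."""
    best = None
    y = data[np.asarray(cases)][:, np.asarray(response_set)]
    for var in sorted(int(v) for v in candidate_vars):
        x = data[cases, var]
        obs = ~np.isnan(x)
        distinct = np.unique(x[obs])
        for a, b in zip(distinct[:-1], distinct[1:]):
            s = 0.5 * (a + b)
            d = split_statistic(y[obs], x[obs] <= s)
            if best is None or d < best[0] - 1e-12:
                best = (d, var, s)
    return best


class TestBootstrap:
    def test_single_case_never_oob(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            inbag, oob = draw_bootstrap(1, rng)
            assert len(inbag) == 1 and len(oob) == 0

    def test_zero_cases_error(self):
        with pytest.raises(ValueError):
            draw_bootstrap(0, np.random.default_rng(0))

    def test_inbag_oob_partition(self):
        rng = np.random.default_rng(1)
        inbag, oob = draw_bootstrap(50, rng)
        assert len(inbag) == 50
        assert set(inbag) | set(oob) == set(range(50))
        assert set(inbag) & set(oob) == set()

    def test_oob_fraction_small_n_closed_form(self):
        # E[|oob|/n] = (1 - 1/n)^n; n=10 gives ~0.3487
        rng = np.random.default_rng(2)
        n, reps = 10, 10_000
        fracs = np.array([len(draw_bootstrap(n, rng)[1]) / n for _ in range(reps)])
        expected = (1 - 1 / n) ** n
        se = fracs.std(ddof=1) / np.sqrt(reps)
        assert abs(fracs.mean() - expected) < 3 * se


class TestPseudoResponses:
    def test_all_variables_when_q_equals_p(self):
        out = select_pseudo_responses(5, 5, np.random.default_rng(0))
        assert sorted(out) == list(range(5))

    def test_reproducible_singleton(self):
        a = select_pseudo_responses(5, 1, np.random.default_rng(3))
        b = select_pseudo_responses(5, 1, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_q_too_large_error(self):
        with pytest.raises(ValueError):
            select_pseudo_responses(3, 4, np.random.default_rng(0))

    def test_uniform_selection_frequency(self):
        rng = np.random.default_rng(4)
        p, q, reps = 100, 10, 10_000
        counts = np.zeros(p)
        for _ in range(reps):
            counts[select_pseudo_responses(p, q, rng)] += 1
        freq = counts / reps
        assert np.all(np.abs(freq - q / p) < 0.01)


class TestSplitStatistic:
    def test_hand_arithmetic(self):
        # values (1,2,3,4) split {1,2}|{3,4}: 0.5 + 0.5 = 1.0
        vals = np.array([1.0, 2.0, 3.0, 4.0])[:, None]
        assert split_statistic(vals, np.array([True, True, False, False])) == pytest.approx(1.0)

    def test_constant_column_is_zero(self):
        vals = np.full((6, 2), 3.14)
        assert split_statistic(vals, np.array([1, 1, 0, 0, 0, 1], bool)) == 0.0

    def test_piecewise_constant_is_zero(self):
        vals = np.array([0.0, 0.0, 10.0, 10.0])[:, None]
        assert split_statistic(vals, np.array([True, True, False, False])) == 0.0

    def test_empty_daughter_error(self):
        with pytest.raises(ValueError):
            split_statistic(np.ones((3, 1)), np.array([True, True, True]))

    def test_nan_entries_discarded(self):
        vals = np.array([[1.0], [2.0], [np.nan], [4.0]])
        ref = np.array([[1.0], [2.0], [4.0]])
        got = split_statistic(vals, np.array([True, True, False, False]))
        want = split_statistic(ref, np.array([True, True, False]))
        assert got == pytest.approx(want)

    @pytest.mark.parametrize("seed", range(5))
    def test_variance_decomposition(self, seed):
        # parent within-node SS >= left SS + right SS for any split
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(20, 3))
        left = rng.random(20) < 0.5
        left[0], left[1] = True, False
        parent_ss = float(((y - y.mean(axis=0)) ** 2).sum())
        assert split_statistic(y, left) <= parent_ss + 1e-9


class TestBestSplit:
    def test_perfect_separation(self):
        # predictor (1,2,3,4), response (0,0,10,10) -> split at 2.5, D=0
        data = np.column_stack([[1.0, 2, 3, 4], [0.0, 0, 10, 10]])
        var, s = best_split(data, np.arange(4), [0], [1])
        assert var == 0 and s == pytest.approx(2.5)

    def test_all_constant_returns_none(self):
        data = np.ones((8, 3))
        assert best_split(data, np.arange(8), [0, 1, 2], [0, 1, 2]) is None

    def test_tie_broken_to_lower_variable_index(self):
        # columns 0 and 1 identical -> equally optimal; lower index wins
        x = np.array([1.0, 2, 3, 4])
        data = np.column_stack([x, x, [0.0, 0, 10, 10]])
        var, _ = best_split(data, np.arange(4), [0, 1], [2])
        assert var == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        p = int(rng.integers(2, 7))
        data = rng.normal(size=(n, p))
        if seed % 3 == 0:  # sprinkle missingness
            data[rng.random(data.shape) < 0.15] = np.nan
        cand = list(range(p))
        resp = list(rng.choice(p, size=min(2, p), replace=False))
        got = best_split(data, np.arange(n), cand, resp)
        want = brute_force_best_split(data, np.arange(n), cand, resp)
        if want is None:
            assert got is None
            return
        var, s = got
        x = data[:, var]
        obs = ~np.isnan(x)
        y = data[:, resp]
        d_got = split_statistic(y[obs], x[obs] <= s)
        assert d_got == pytest.approx(want[0], abs=1e-9)


class TestGrowTree:
    def test_nodesize_larger_than_n_gives_root_terminal(self):
        data = np.random.default_rng(0).normal(size=(10, 3))
        rng = np.random.default_rng(1)
        inbag, oob = draw_bootstrap(10, rng)
        tree = grow_tree(data, ForestParams(nodesize=10), inbag, oob, rng)
        assert tree.n_nodes == 1 and tree.depth[0] == 0 and tree.is_terminal(0)

    def test_binary_variable_perfect_partition(self):
        # one binary column separating two pseudo-response clusters -> depth-1
        rng = np.random.default_rng(2)
        g = np.repeat([0.0, 1.0], 10)
        y = np.where(g[:, None] > 0, 10.0, 0.0) + 0.01 * rng.normal(size=(20, 2))
        data = np.column_stack([g, y])
        inbag, oob = draw_bootstrap(20, rng)
        tree = grow_tree(
            data,
            ForestParams(nodesize=5, mtry=3, q_pseudo=3, max_depth=1),
            inbag,
            oob,
            rng,
        )
        assert tree.split_var[0] == 0
        assert tree.depth.max() == 1

    def test_membership_and_depth_invariants(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(50, 5))
        inbag, oob = draw_bootstrap(50, rng)
        tree = grow_tree(data, ForestParams(nodesize=3), inbag, oob, rng)
        for node in range(tree.n_nodes):
            terminal = tree.split_var[node] < 0
            assert terminal == (tree.left[node] < 0) == (tree.right[node] < 0)
            if not terminal:
                assert tree.depth[tree.left[node]] == tree.depth[node] + 1
                assert tree.depth[tree.right[node]] == tree.depth[node] + 1
        # every case is in exactly one terminal, as in-bag xor OOB
        for case in range(50):
            ib, ob = tree.inbag_terminal[case], tree.oob_terminal[case]
            assert (ib >= 0) != (ob >= 0)
            node = ib if ib >= 0 else ob
            assert tree.is_terminal(node)
        assert set(np.nonzero(tree.inbag_count)[0]) == set(inbag)

    def test_all_missing_data_single_node(self):
        data = np.full((10, 3), np.nan)
        rng = np.random.default_rng(4)
        inbag, oob = draw_bootstrap(10, rng)
        tree = grow_tree(data, ForestParams(nodesize=1), inbag, oob, rng)
        assert tree.n_nodes == 1


class TestGrowForest:
    def test_deterministic_given_seed(self):
        data = np.random.default_rng(5).normal(size=(40, 6))
        params = ForestParams(n_trees=5, seed=11)
        a = grow_forest(data, params)
        b = grow_forest(data, params)
        for ta, tb in zip(a.trees, b.trees):
            assert ta.to_json() == tb.to_json()

    def test_oob_fraction_matches_closed_form(self):
        data = np.random.default_rng(6).normal(size=(200, 4))
        forest = grow_forest(data, ForestParams(n_trees=100, seed=7, nodesize=50))
        fracs = np.array(
            [(t.oob_terminal >= 0).mean() for t in forest.trees]
        )
        expected = (1 - 1 / 200) ** 200
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - expected) < 3 * se

    def test_tree_json_round_trip(self, small_forest):
        tree = small_forest.trees[0]
        back = Tree.from_json(tree.to_json())
        assert back.to_json() == tree.to_json()

    def test_synthetic_contrast_mode(self):
        data = np.random.default_rng(8).normal(size=(30, 4))
        params = ForestParams(
            n_trees=3, seed=9, unsupervised_mode="synthetic_contrast"
        )
        forest = grow_forest(data, params)
        assert forest.n_trees == 3
        for tree in forest.trees:
            assert tree.n_cases == 30
        again = grow_forest(data, params)
        assert forest.trees[0].to_json() == again.trees[0].to_json()

    def test_synthetic_contrast_rejects_missing(self):
        data = np.random.default_rng(8).normal(size=(30, 4))
        data[0, 0] = np.nan
        with pytest.raises(ValueError):
            grow_forest(
                data,
                ForestParams(n_trees=1, unsupervised_mode="synthetic_contrast"),
            )
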