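"""Ring-toss optimizer: score bars, throws, greedy acceptance, convergence."""

import numpy as np
import pytest

from leafdx import rtgo


SPACE_1D = rtgo.SearchSpace(lower=(-5.0,), upper=(5.0,))


class TestPopulation:
    def test_init_within_bounds_and_seeded(self):
        space = rtgo.SearchSpace(lower=(0.0,), upper=(1.0,))
        rng = np.random.default_rng(0)
        pop = rtgo.init_population(rtgo.sphere, space, 10, rng)
        assert pop.X.shape == (10, 1)
        assert (pop.X >= 0).all() and (pop.X <= 1).all()
        pop2 = rtgo.init_population(rtgo.sphere, space, 10, np.random.default_rng(0))
        assert np.array_equal(pop.X, pop2.X)

    def test_integral_dimension_sampling(self):
        space = rtgo.SearchSpace(lower=(1.0,), upper=(8.0,), integral=(True,))
        rng = np.random.default_rng(1)
        pop = rtgo.init_population(rtgo.sphere, space, 20, rng)
        assert np.array_equal(pop.X, np.round(pop.X))
        assert pop.X.min() >= 1 and pop.X.max() <= 8

    def test_too_small_population_rejected(self):
        with pytest.raises(ValueError):
            rtgo.init_population(rtgo.sphere, SPACE_1D, 1, np.random.default_rng(0))


class TestScoreBars:
    @pytest.mark.parametrize("n,expected", [(100, 10), (5, 1), (2, 1), (10, 1), (15, 2), (1000, 100)])
    def test_ten_percent_rule(self, n, expected):
        assert rtgo.n_score_bars(n) == expected

    def test_rule_over_full_range(self):
        for n in range(2, 1001):
            assert rtgo.n_score_bars(n) == max(1, int(np.floor(0.1 * n + 0.5)))

    def test_best_members_selected_in_order(self):
        OF = np.array([3.0, 1, 2, 5, 4, 9, 8, 7, 6, 0])
        pop = rtgo.Population(X=np.arange(10.0)[:, None], OF=OF)
        bars = rtgo.select_score_bars(pop)
        # 10% of N=10 is a single bar: the objective-0 member
        assert bars.indices.tolist() == [9]
        assert bars.OF_SB.tolist() == [0.0]
        # two bars at N=20: best two in objective order, ties by lower index
        OF20 = np.concatenate([OF, np.full(10, 50.0)])
        OF20[15] = 0.0
        pop20 = rtgo.Population(X=np.arange(20.0)[:, None], OF=OF20)
        bars20 = rtgo.select_score_bars(pop20)
        assert bars20.indices.tolist() == [9, 15]
        assert bars20.OF_SB.tolist() == [0.0, 0.0]


class TestRingThrow:
    def test_zero_draw_is_no_displacement(self):
        cand = rtgo.ring_throw(np.array([2.0]), 5.0, np.array([1.0]), 1.0,
                               rng=None, r=np.array([0.0]))
        assert cand[0] == 2.0

    def test_throw_toward_better_bar(self):
        # x=2, sb=1, bar better, r=0.4 -> F=1, dx = 0.4*(1-2) = -0.4
        cand = rtgo.ring_throw(np.array([2.0]), 5.0, np.array([1.0]), 1.0,
                               rng=None, r=np.array([0.4]))
        assert cand[0] == pytest.approx(1.6, abs=1e-12)

    def test_throw_away_from_worse_bar(self):
        # x=2, sb=1, bar not better, r=0.6 -> F=2, dx = 0.6*(2-2*1) = 0
        cand = rtgo.ring_throw(np.array([2.0]), 1.0, np.array([1.0]), 1.0,
                               rng=None, r=np.array([0.6]))
        assert cand[0] == pytest.approx(2.0, abs=1e-12)

    def test_f_split_is_balanced(self):
        rng = np.random.default_rng(0)
        r = rng.random(100_000)
        F = np.floor(1.0 + r + 0.5)
        assert set(np.unique(F)) <= {1.0, 2.0}
        assert 0.49 <= (F == 2).mean() <= 0.51

    def test_candidates_clipped_to_bounds(self):
        rng = np.random.default_rng(3)
        space = rtgo.SearchSpace(lower=(-1.0, 0.0), upper=(1.0, 4.0), integral=(False, True))
        for _ in range(200):
            x = np.array([rng.uniform(-1, 1), rng.integers(0, 5)])
            sb = np.array([rng.uniform(-1, 1), rng.integers(0, 5)])
            cand = rtgo.ring_throw(x, rng.random(), sb, rng.random(), rng, space)
            assert -1 <= cand[0] <= 1 and 0 <= cand[1] <= 4
            assert cand[1] == round(cand[1])


class TestGreedyAcceptance:
    def test_strict_improvement_required(self):
        x, of = np.array([1.0]), 2.0
        better, of_b = rtgo.greedy_accept(x, of, np.array([0.5]), 1.0)
        assert better[0] == 0.5 and of_b == 1.0
        same, of_s = rtgo.greedy_accept(x, of, np.array([9.0]), 2.0)  # tie
        assert same[0] == 1.0 and of_s == 2.0


class TestOptimize:
    def test_trace_non_increasing_and_eval_count(self):
        for seed in range(5):
            res = rtgo.rtgo_optimize(rtgo.rastrigin, rtgo.SearchSpace((-5.0,) * 3, (5.0,) * 3),
                                     n=12, iterations=30, seed=seed)
            assert all(b <= a for a, b in zip(res.trace, res.trace[1:]))
            assert res.evaluations == 12 * 31

    def test_constant_objective_flat_trace(self):
        res = rtgo.rtgo_optimize(lambda x: 7.0, SPACE_1D, n=5, iterations=10, seed=0)
        assert res.trace == [7.0] * 10
        assert res.best_objective == 7.0

    def test_non_finite_objective_names_position(self):
        with pytest.raises(ValueError, match="non-finite"):
            rtgo.rtgo_optimize(lambda x: np.inf, SPACE_1D, n=3, iterations=2, seed=0)

    def test_positions_stay_in_bounds(self):
        space = rtgo.SearchSpace((-2.0, 0.0), (2.0, 1.0))
        res = rtgo.rtgo_optimize(rtgo.sphere, space, n=8, iterations=20, seed=1, keep_history=True)
        for X in res.history:
            assert (X >= np.array(space.lower)).all() and (X <= np.array(space.upper)).all()

    def test_seeded_reproducibility(self):
        a = rtgo.rtgo_optimize(rtgo.sphere, SPACE_1D, n=6, iterations=15, seed=4)
        b = rtgo.rtgo_optimize(rtgo.sphere, SPACE_1D, n=6, iterations=15, seed=4)
        assert a.trace == b.trace
        assert np.array_equal(a.best_position, b.best_position)


class TestFitness:
    def test_error_rate_arithmetic(self):
        assert rtgo.error_rate(0, 60) == 0.0
        assert rtgo.error_rate(60, 60) == 100.0
        assert rtgo.error_rate(3, 60) == 5.0

    def test_decode_hyperparams(self):
        hp = rtgo.decode_hyperparams(np.array([-3.0, 0.25, 16.4, 24.0]))
        assert hp["learning_rate"] == pytest.approx(1e-3)
        assert hp["coarse_loss_weight"] == 0.25
        assert hp["lstm_hidden"] == 16 and hp["batch_size"] == 24
        with pytest.raises(ValueError):
            rtgo.decode_hyperparams(np.zeros(3))
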