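"""Objective, optimizers, repeat estimation, chasing, ranking, truncation."""

import math

import numpy as np
import pytest

from kincal import synthetic
from kincal.data import ExperimentTable, ObservationMap
from kincal.estimation import (
    EstimationArchive,
    FitProblem,
    OptimizerConfig,
    ParameterSet,
    chaser,
    genetic_algorithm,
    hooke_jeeves,
    rank,
    repeat_estimation,
    sample_start,
    truncate,
)

BOUNDS_2D = [("a", 1e-7, 1e4), ("b", 1e-7, 1e4)]


def quadratic(target):
    target = np.asarray(target, dtype=float)

    def objective(values):
        z = np.log10([values[k] for k in sorted(values)])
        return float(np.sum((z - target) ** 2))

    return objective


class TestWeightedRss:
    def test_zero_at_generating_parameters(self, nf_problem, nf_truth):
        assert nf_problem.weighted_rss(nf_truth) == pytest.approx(0.0, abs=1e-10)

    def test_hand_arithmetic_with_sigma(self):
        # constant species at 3, two replicates at 5: residual 2 per point
        model = synthetic.decay_model().with_initial_amounts({"A": 3.0})
        model = model.with_parameters({"k": 1e-12})
        table = ExperimentTable([0.0], ["A"], np.full((1, 2, 1), 5.0))
        om = ObservationMap.uniform(["A"], 1.0)
        p1 = FitProblem(model, table, om, ["k"], sd_floor=1.0)
        p2 = FitProblem(model, table, om, ["k"], sd_floor=2.0)
        assert p1.weighted_rss({"k": 1e-12}) == pytest.approx(8.0)  # 2 * (2/1)^2
        assert p2.weighted_rss({"k": 1e-12}) == pytest.approx(2.0)  # 2 * (2/2)^2

    def test_unweighted_mode_uses_unit_sigma(self):
        model = synthetic.decay_model().with_initial_amounts({"A": 3.0})
        table = ExperimentTable([0.0], ["A"], np.full((1, 1, 1), 5.0))
        prob = FitProblem(model, table, ObservationMap.uniform(["A"], 1.0), ["k"],
                          weighting="none")
        assert prob.weighted_rss({"k": 1e-12}) == pytest.approx(4.0)

    def test_missing_points_skipped(self):
        model = synthetic.decay_model().with_initial_amounts({"A": 3.0})
        vals = np.array([[[5.0], [np.nan]]])
        table = ExperimentTable([0.0], ["A"], vals)
        prob = FitProblem(model, table, ObservationMap.uniform(["A"], 1.0), ["k"],
                          weighting="none", sd_floor=1.0)
        assert prob.weighted_rss({"k": 1e-12}) == pytest.approx(4.0)

    def test_matches_triple_loop_oracle(self, nf_problem, rng):
        lb, ub = nf_problem.bounds_array()
        for _ in range(20):
            z = np.log10(lb) + rng.random(3) * (np.log10(ub) - np.log10(lb))
            values = dict(zip(nf_problem.parameter_names, 10.0**z))
            fast = nf_problem.weighted_rss(values)
            pred = nf_problem.predictions(values)
            slow = 0.0
            for ti in range(nf_problem.data.times.size):
                for ri in range(nf_problem.data.n_replicates):
                    for oi in range(len(nf_problem.data.observables)):
                        y = nf_problem.data.values[ti, ri, oi]
                        if math.isnan(y):
                            continue
                        slow += (
                            (y - pred.iloc[ti, oi]) / nf_problem.summary.sd[ti, oi]
                        ) ** 2
            assert fast == pytest.approx(slow, rel=1e-12)

    def test_integration_failure_maps_to_inf(self):
        model = synthetic.decay_model()
        blow = model.with_parameters({"k": 1.0})
        # quadratic growth model that blows up in finite time
        from kincal.model import parse_model

        m = parse_model("species A = 10\nparam k = 1\ngrow: -> A; k*A*A")
        table = ExperimentTable([0.0, 5.0], ["A"], np.full((2, 2, 1), 1.0))
        prob = FitProblem(m, table, ObservationMap.uniform(["A"], 1.0), ["k"])
        assert prob.weighted_rss({"k": 1.0}) == math.inf


class TestSampleStart:
    def test_respects_bounds(self):
        free = [("a", 1e-3, 10.0)]
        draws = [sample_start(free, seed=i)["a"] for i in range(1000)]
        assert all(1e-3 <= d <= 10.0 for d in draws)

    def test_deterministic_for_seed(self):
        assert sample_start(BOUNDS_2D, seed=7) == sample_start(BOUNDS_2D, seed=7)

    def test_log_uniform_median(self):
        free = [("a", 1e-7, 1e4)]
        logs = [math.log10(sample_start(free, seed=i)["a"]) for i in range(4000)]
        assert np.median(logs) == pytest.approx(-1.5, abs=0.15)


class TestGeneticAlgorithm:
    def test_converges_on_quadratic_bowl(self):
        obj = quadratic([-2.0, 1.0])
        cfg = OptimizerConfig(population_size=30, generations=60, seed=0)
        result = genetic_algorithm(obj, BOUNDS_2D, cfg)
        assert result.rss < 1e-2

    def test_best_so_far_monotone(self):
        cfg = OptimizerConfig(population_size=10, generations=30, seed=1)
        result = genetic_algorithm(quadratic([0.0, 0.0]), BOUNDS_2D, cfg)
        assert all(b <= a + 1e-15 for a, b in zip(result.history, result.history[1:]))

    def test_seeded_determinism(self):
        cfg = OptimizerConfig(population_size=12, generations=15, seed=9)
        r1 = genetic_algorithm(quadratic([1.0, -1.0]), BOUNDS_2D, cfg)
        r2 = genetic_algorithm(quadratic([1.0, -1.0]), BOUNDS_2D, cfg)
        assert r1.values == r2.values and r1.rss == r2.rss

    def test_all_infinite_population_aborts(self):
        cfg = OptimizerConfig(population_size=5, generations=10, seed=0)
        with pytest.raises(RuntimeError, match="infinite"):
            genetic_algorithm(lambda v: math.inf, BOUNDS_2D, cfg)


class TestHookeJeeves:
    def test_reaches_analytic_optimum(self):
        obj = quadratic([-2.0, 1.0])
        cfg = OptimizerConfig(algorithm="hooke_jeeves", tolerance=1e-10,
                              iteration_limit=1000)
        res = hooke_jeeves(obj, BOUNDS_2D, {"a": 1.0, "b": 1.0}, cfg)
        assert abs(math.log10(res.values["a"]) + 2.0) < 1e-6
        assert abs(math.log10(res.values["b"]) - 1.0) < 1e-6

    def test_fixed_point_at_optimum(self):
        obj = quadratic([0.0, 0.0])
        cfg = OptimizerConfig(algorithm="hooke_jeeves", tolerance=1e-6,
                              iteration_limit=100)
        res = hooke_jeeves(obj, BOUNDS_2D, {"a": 1.0, "b": 1.0}, cfg)
        assert res.values["a"] == pytest.approx(1.0, rel=1e-5)
        assert res.values["b"] == pytest.approx(1.0, rel=1e-5)

    def test_never_worse_than_start(self, rng):
        obj = quadratic([0.5, -3.0])
        cfg = OptimizerConfig(algorithm="hooke_jeeves", tolerance=1e-3,
                              iteration_limit=10)
        for i in range(5):
            start = sample_start(BOUNDS_2D, seed=i)
            res = hooke_jeeves(obj, BOUNDS_2D, start, cfg)
            assert res.rss <= obj(start) + 1e-12


class TestRepeatEstimation:
    CFG = OptimizerConfig(population_size=8, generations=5)

    def test_archive_size_and_seeds(self):
        archive = repeat_estimation(BOUNDS_2D, n_runs=6, config=self.CFG, seed=10,
                                    objective=quadratic([0.0, 0.0]))
        assert len(archive) == 6
        assert [s.seed for s in archive] == [10 + i for i in range(6)]

    def test_result_independent_of_worker_count(self):
        obj = quadratic([1.0, -2.0])
        a1 = repeat_estimation(BOUNDS_2D, 8, self.CFG, seed=3, max_workers=1,
                               objective=obj)
        a4 = repeat_estimation(BOUNDS_2D, 8, self.CFG, seed=3, max_workers=4,
                               objective=obj)
        assert sorted(a1.rss) == sorted(a4.rss)

    def test_seed_prefix_nesting(self):
        obj = quadratic([2.0, 2.0])
        small = repeat_estimation(BOUNDS_2D, 4, self.CFG, seed=5, objective=obj)
        large = repeat_estimation(BOUNDS_2D, 8, self.CFG, seed=5, objective=obj)
        assert min(large.rss) <= min(small.rss)
        assert list(large.rss[:4]) == list(small.rss)


class TestChaser:
    def make_archive(self, n=6, seed=0):
        obj = quadratic([-1.0, 2.0])
        cfg = OptimizerConfig(population_size=8, generations=4)
        return rank(repeat_estimation(BOUNDS_2D, n, cfg, seed=seed, objective=obj)), obj

    def test_top_three_chased_and_flagged(self):
        archive, obj = self.make_archive()
        out = chaser(archive, top_k=3, objective=obj)
        chased = [s for s in out if s.chased]
        assert len(chased) == 3
        assert len(out) == len(archive) + 3

    def test_chased_rss_never_exceeds_source(self):
        archive, obj = self.make_archive()
        out = chaser(archive, top_k=5, objective=obj)
        sources = {s.run_id: s.rss for s in archive}
        for s in out:
            if s.chased:
                assert s.rss <= sources[s.source_run] + 1e-12

    def test_chasing_a_local_optimum_is_a_fixed_point(self):
        obj = quadratic([0.0, 0.0])
        opt = ParameterSet({"a": 1.0, "b": 1.0}, obj({"a": 1.0, "b": 1.0}), run_id=0)
        archive = rank(EstimationArchive(BOUNDS_2D, [opt]))
        out = chaser(archive, top_k=1, objective=obj)
        refined = [s for s in out if s.chased][0]
        assert refined.values["a"] == pytest.approx(1.0, rel=1e-6)

    def test_oversized_selection_clipped_with_warning(self):
        archive, obj = self.make_archive(n=2)
        with pytest.warns(UserWarning, match="clipping"):
            out = chaser(archive, top_k=10, objective=obj)
        assert sum(s.chased for s in out) == 2


class TestRankTruncate:
    def make_archive(self, rss_values):
        sets = [ParameterSet({"p": 1.0}, r, run_id=i) for i, r in enumerate(rss_values)]
        return EstimationArchive(None, sets)

    def test_rank_sorts_with_stable_ties(self):
        archive = rank(self.make_archive([3.0, 1.0, 1.0, 2.0]))
        assert [s.rss for s in archive] == [1.0, 1.0, 2.0, 3.0]
        assert [s.run_id for s in archive[:2]] == [1, 2]

    def test_top_ten_percent_of_300(self):
        archive = self.make_archive(list(np.linspace(1, 30, 300)))
        assert len(truncate(archive, "fraction", 0.10)) == 30

    def test_count_clipped_to_size(self):
        archive = self.make_archive([1.0, 2.0])
        assert len(truncate(archive, "count", 99)) == 2

    def test_rss_cutoff_at_minimum_keeps_best_only(self):
        archive = self.make_archive([5.0, 1.0, 3.0, 1.0])
        kept = truncate(archive, "rss_cutoff", 1.0)
        assert [s.rss for s in kept] == [1.0, 1.0]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            truncate(self.make_archive([1.0]), "fraction", 1.5)

    def test_csv_round_trip(self, tmp_path):
        archive = rank(self.make_archive([2.0, 1.0]))
        archive.to_csv(tmp_path / "a.csv")
        back = EstimationArchive.from_csv(tmp_path / "a.csv")
        assert [s.rss for s in back] == [1.0, 2.0]
        assert back.parameter_names == ["p"]


class TestFitResults:
    def test_fit_and_summary_on_motif(self, nf_problem, nf_truth):
        res = nf_problem.fit(
            n_runs=2, config=OptimizerConfig(population_size=10, generations=8), seed=0
        )
        assert len(res.archive) == 2
        text = res.summary()
        assert "Best RSS" in text and "kx" in text
        chased = res.chase(top_k=1)
        assert chased.rss <= res.rss
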