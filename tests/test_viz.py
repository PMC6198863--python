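"""Diagnostic-plot data: every figure's numbers are tested, not its pixels."""

import numpy as np
import pytest
import matplotlib.pyplot as plt

from kincal import synthetic
from kincal.data import ObservationMap
from kincal.estimation import EstimationArchive, FitProblem, ParameterSet, rank
from kincal.viz import (
    correlations,
    distributions,
    ensemble_timecourse,
    likelihood_ranks,
    plot_profiles,
    plot_selection,
)


@pytest.fixture(autouse=True)
def close_figures():
    yield
    plt.close("all")


def archive_from(values_list, rss=None, problem=None):
    sets = [
        ParameterSet(v, rss[i] if rss else 1.0, run_id=i)
        for i, v in enumerate(values_list)
    ]
    return rank(EstimationArchive(problem, sets))


@pytest.fixture(scope="module")
def decay_problem():
    model = synthetic.decay_model()
    table = synthetic.generate_data(
        model, observables=["A"], noise="gaussian_cv", cv=0.05,
        scale_factors=1.0, seed=1,
    )
    return FitProblem(model, table, ObservationMap.uniform(["A"], 1.0), ["k"])


class TestEnsemble:
    def test_single_set_gives_zero_width_band(self, decay_problem):
        archive = archive_from([{"k": 0.1}], problem=decay_problem)
        bands, _ = ensemble_timecourse(decay_problem, archive, select=1, n_boot=50)
        b = bands["A"]
        assert np.allclose(b.lower, b.center) and np.allclose(b.upper, b.center)

    def test_identical_sets_give_zero_width_band(self, decay_problem):
        archive = archive_from([{"k": 0.1}] * 5, problem=decay_problem)
        bands, _ = ensemble_timecourse(decay_problem, archive, select=5, n_boot=50)
        b = bands["A"]
        assert np.allclose(b.upper - b.lower, 0.0, atol=1e-12)

    def test_band_brackets_median_trajectory(self, decay_problem):
        ks = np.linspace(0.05, 0.2, 10)
        archive = archive_from([{"k": k} for k in ks], problem=decay_problem)
        bands, _ = ensemble_timecourse(decay_problem, archive, select=10,
                                       n_boot=400, seed=0)
        trajs = np.array([
            decay_problem.predictions({"k": k}, times=bands["A"].times)["A"]
            for k in ks
        ])
        med = np.median(trajs, axis=0)
        b = bands["A"]
        assert np.all(b.lower <= med + 1e-9) and np.all(med <= b.upper + 1e-9)


class TestLikelihoodRanks:
    def test_sorted_output_monotone(self):
        archive = archive_from([{"p": 1.0}] * 5, rss=[3, 1, 2, 5, 4])
        (ranks, rss), _ = likelihood_ranks(archive)
        assert list(ranks) == [1, 2, 3, 4, 5]
        assert np.all(np.diff(rss) >= 0)

    def test_single_global_minimum_is_flat(self):
        archive = archive_from([{"p": 1.0}] * 4, rss=[2.0] * 4)
        (_, rss), _ = likelihood_ranks(archive)
        assert np.ptp(rss) == 0.0

    def test_two_minima_show_two_plateaus(self):
        archive = archive_from([{"p": 1.0}] * 10, rss=[1.0] * 5 + [7.0] * 5)
        (_, rss), _ = likelihood_ranks(archive)
        steps = np.diff(rss)
        assert np.count_nonzero(steps) == 1  # exactly one jump between plateaus


class TestDistributions:
    def test_constant_parameter_has_zero_iqr(self):
        archive = archive_from([{"p": 2.0, "q": 10.0**i} for i in range(6)])
        out, _ = distributions(archive)
        assert out["summaries"]["p"]["iqr"] == 0.0
        assert out["summaries"]["q"]["iqr"] > 0

    def test_bimodal_parameter_shows_two_modes(self, rng):
        low = 10.0 ** rng.normal(-3, 0.05, 40)
        high = 10.0 ** rng.normal(1, 0.05, 40)
        archive = archive_from([{"p": v} for v in np.concatenate([low, high])])
        out, _ = distributions(archive, bins=24)
        counts, _ = out["histograms"]["p"]
        third = len(counts) // 3
        trough = counts[third:-third].min()
        assert counts[:third].max() > 2 * max(trough, 1)
        assert counts[-third:].max() > 2 * max(trough, 1)

    def test_truncation_changes_summaries(self):
        archive = archive_from(
            [{"p": 10.0**i} for i in range(10)], rss=list(range(10))
        )
        full, _ = distributions(archive)
        top, _ = distributions(archive, truncation=("fraction", 0.2))
        assert top["summaries"]["p"]["median"] < full["summaries"]["p"]["median"]

    def test_empty_after_truncation_rejected(self):
        archive = archive_from([{"p": 1.0}])
        with pytest.raises(ValueError):
            distributions(archive, truncation=("rss_cutoff", -1.0))


class TestCorrelations:
    def test_exact_log_linear_pair(self, rng):
        k1 = 10.0 ** rng.uniform(-2, 2, 30)
        archive = archive_from([{"k1": v, "k2": 0.5 / v} for v in k1])
        out, _ = correlations(archive, flag_threshold=0.9)
        assert out["matrix"].loc["k1", "k2"] == pytest.approx(-1.0)
        assert out["flagged"][0]["r2"] == pytest.approx(1.0)

    def test_independent_parameters_uncorrelated(self, rng):
        vals = 10.0 ** rng.uniform(-2, 2, size=(100, 2))
        archive = archive_from([{"a": v[0], "b": v[1]} for v in vals])
        out, _ = correlations(archive)
        assert abs(out["matrix"].loc["a", "b"]) < 0.3

    def test_matrix_symmetric_with_unit_diagonal(self, rng):
        vals = 10.0 ** rng.uniform(-1, 1, size=(20, 3))
        archive = archive_from([{"a": v[0], "b": v[1], "c": v[2]} for v in vals])
        out, _ = correlations(archive)
        m = out["matrix"].to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_zero_variance_parameter_masked(self, rng):
        vals = 10.0 ** rng.uniform(-1, 1, 10)
        archive = archive_from([{"a": v, "c": 3.0} for v in vals])
        out, _ = correlations(archive)
        assert np.isnan(out["matrix"].loc["a", "c"])

    def test_too_few_sets_rejected(self):
        archive = archive_from([{"a": 1.0}, {"a": 2.0}])
        with pytest.raises(ValueError, match="at least 3"):
            correlations(archive)


class TestProfileAndSelectionPlots:
    def make_report(self):
        from kincal.identifiability import profile_all

        model = synthetic.coupled_pair_model()
        table = synthetic.generate_data(
            model, observables=["A"], noise="none", scale_factors=1.0
        )
        problem = FitProblem(
            model, table, ObservationMap.uniform(["A"], 1.0), ["k1", "k2"]
        )
        values = {"k1": 0.2, "k2": 0.5}
        best = ParameterSet(values, problem.weighted_rss(values))
        return profile_all(problem, [best], n_points=6)[0]

    def test_one_panel_per_parameter_and_threshold_line(self):
        report = self.make_report()
        fig = plot_profiles(report)
        visible = [ax for ax in fig.axes if ax.get_visible() and ax.has_data()]
        assert len(visible) == 2
        thresholds = [
            line.get_ydata()[0]
            for ax in visible
            for line in ax.get_lines()
            if np.ptp(line.get_ydata()) == 0 and len(line.get_xdata()) == 2
        ]
        assert any(np.isclose(t, report.threshold) for t in thresholds)

    def test_coparameter_mode_renders(self):
        report = self.make_report()
        fig = plot_profiles(report, coparameter="k2")
        assert fig is not None

    def test_selection_plot(self, tmp_path):
        from kincal.selection import select
        from test_selection import fake_archive

        report = select([fake_archive([4.0, 6.0], name="m1"),
                         fake_archive([4.0, 6.0], name="m2")])
        out, _ = plot_selection(report, path=tmp_path / "sel")
        assert np.allclose(out["per_model"]["m1"], out["per_model"]["m2"])
        assert min(out["best"].values()) == out["best"][report.winner]
        for suffix in (".png", ".svg", ".csv"):
            assert (tmp_path / "sel").with_suffix(suffix).exists()
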