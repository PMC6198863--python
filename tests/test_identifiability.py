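"""Profile likelihoods, thresholds, classification and co-parameter traces."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, linregress

from kincal import synthetic
from kincal.data import ExperimentTable, ObservationMap
from kincal.estimation import FitProblem, OptimizerConfig, ParameterSet, hooke_jeeves
from kincal.identifiability import (
    IDENTIFIABLE,
    PRACTICAL,
    STRUCTURAL,
    ProfileCurve,
    ThresholdSpec,
    classify,
    confidence_threshold,
    coparameter_trace,
    profile_all,
    profile_likelihood,
)


def true_best(model, free, times, observables):
    table = synthetic.generate_data(
        model, times=times, observables=observables, noise="none", scale_factors=1.0
    )
    problem = FitProblem(model, table, ObservationMap.uniform(observables, 1.0), free)
    values = {name: model.parameters[name] for name in problem.parameter_names}
    return problem, ParameterSet(values, problem.weighted_rss(values))


@pytest.fixture(scope="module")
def decay_profile():
    problem, best = true_best(synthetic.decay_model(), ["k"], (0, 1, 2, 4, 8, 12), ["A"])
    curve = profile_likelihood(problem, best, "k", span_orders=2, n_points=10)
    return problem, best, curve


@pytest.fixture(scope="module")
def coupled_profile():
    problem, best = true_best(
        synthetic.coupled_pair_model(), ["k1", "k2"], (0, 1, 2, 4, 8, 12), ["A"]
    )
    curve = profile_likelihood(problem, best, "k1", span_orders=2, n_points=8)
    return problem, best, curve


class TestThreshold:
    def test_chi2_pointwise_closed_form(self):
        assert confidence_threshold(10.0) == pytest.approx(13.841, abs=1e-3)

    def test_alpha_to_zero_limit(self):
        spec = ThresholdSpec(alpha=1e-9)
        assert confidence_threshold(5.0, spec=spec) == pytest.approx(5.0, abs=1e-6)

    def test_f_based_approaches_chi2_for_large_n(self):
        # with best RSS ~ its expectation (n - p), the F form -> chi2 form
        n, p = 100_000, 3
        best = float(n - p)
        f_thr = confidence_threshold(best, n, p, ThresholdSpec(mode="f_based"))
        chi_thr = best + chi2.ppf(0.95, 1)
        assert f_thr == pytest.approx(chi_thr, rel=5e-4)

    def test_f_based_requires_enough_points(self):
        with pytest.raises(ValueError, match="n_points_total"):
            confidence_threshold(1.0, 3, 3, ThresholdSpec(mode="f_based"))


class TestProfileLikelihood:
    def test_reoptimization_at_best_value_recovers_best_rss(self, coupled_profile):
        _, best, curve = coupled_profile
        anchor = np.argmin(np.abs(curve.fixed_values - curve.best_value))
        assert curve.rss[anchor] <= best.rss + 1e-6

    def test_decay_profile_rises_monotonically_from_truth(self, decay_profile):
        _, _, curve = decay_profile
        i0 = int(np.argmin(curve.rss))
        right = curve.rss[i0:]
        left = curve.rss[: i0 + 1][::-1]
        assert np.all(np.diff(right) >= -1e-9)
        assert np.all(np.diff(left) >= -1e-9)

    def test_product_coupling_gives_flat_profile(self, coupled_profile):
        _, _, curve = coupled_profile
        assert curve.rss.max() - curve.rss.min() < 1e-3

    def test_unknown_parameter_rejected(self, decay_profile):
        problem, best, _ = decay_profile
        with pytest.raises(KeyError):
            profile_likelihood(problem, best, "nope")


class TestClassify:
    def parabola_curve(self, a=5.0, n=41, span=2.0):
        z = np.linspace(-span, span, n)
        rss = a * z**2
        return ProfileCurve(
            "p", 1.0, 0.0, 10.0**z, rss, pd.DataFrame(index=range(n))
        )

    def test_flat_curve_is_structural_with_infinite_bounds(self):
        n = 11
        curve = ProfileCurve(
            "p", 1.0, 1.0, np.logspace(-2, 2, n), np.full(n, 1.0),
            pd.DataFrame(index=range(n)),
        )
        verdict = classify(curve, threshold=4.841)
        assert verdict.classification == STRUCTURAL
        assert verdict.ci_lower == -math.inf and verdict.ci_upper == math.inf
        assert verdict.suspected

    def test_parabola_ci_matches_analytic_crossings(self):
        threshold = 3.841
        verdict = classify(self.parabola_curve(), threshold)
        z_cross = math.sqrt(threshold / 5.0)  # a z^2 = threshold
        assert verdict.classification == IDENTIFIABLE
        assert math.log10(verdict.ci_upper) == pytest.approx(z_cross, rel=0.01)
        assert math.log10(verdict.ci_lower) == pytest.approx(-z_cross, rel=0.01)

    def test_ci_stable_under_grid_refinement(self):
        coarse = classify(self.parabola_curve(n=21), 3.841)
        fine = classify(self.parabola_curve(n=201), 3.841)
        assert verdictratio(coarse.ci_upper, fine.ci_upper) < 0.02
        assert verdictratio(coarse.ci_lower, fine.ci_lower) < 0.02

    def test_one_sided_crossing_is_practical(self):
        z = np.linspace(-2, 2, 21)
        rss = np.where(z > 0, 5.0 * z**2, 0.05 * z**2)  # only upper side crosses
        curve = ProfileCurve("p", 1.0, 0.0, 10.0**z, rss,
                             pd.DataFrame(index=range(21)))
        verdict = classify(curve, 3.841)
        assert verdict.classification == PRACTICAL
        assert verdict.ci_lower == -math.inf
        assert math.isfinite(verdict.ci_upper)

    def test_threshold_below_best_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            classify(self.parabola_curve(), threshold=-1.0)

    def test_classification_invariant_to_rescaling_the_parameter(self):
        curve = self.parabola_curve()
        scaled = ProfileCurve(
            "p", 10.0, 0.0, 10.0 * curve.fixed_values, curve.rss,
            curve.coparameters,
        )
        v1 = classify(curve, 3.841)
        v2 = classify(scaled, 3.841)
        assert v1.classification == v2.classification
        assert v2.ci_upper / v1.ci_upper == pytest.approx(10.0, rel=0.01)


def verdictratio(a, b):
    return abs(math.log10(a) - math.log10(b))


class TestCoparameterTrace:
    def test_product_coupling_traces_log_linear(self, coupled_profile):
        _, _, curve = coupled_profile
        x, y = coparameter_trace(curve, "k2")
        fit = linregress(np.log10(x), np.log10(y))
        assert fit.slope == pytest.approx(-1.0, abs=0.01)
        assert fit.rvalue**2 > 0.999

    def test_trace_length_matches_scan(self, coupled_profile):
        _, _, curve = coupled_profile
        x, y = coparameter_trace(curve, "k2")
        assert x.size == y.size == curve.fixed_values.size

    def test_unknown_coparameter_rejected(self, coupled_profile):
        _, _, curve = coupled_profile
        with pytest.raises(KeyError):
            coparameter_trace(curve, "k1")

    def test_decoupled_parameter_trace_constant(self):
        from kincal.model import parse_model

        m = parse_model(
            "species A = 10\nspecies B = 5\nparam k1 = 0.2\nparam k2 = 0.4\n"
            "dA: A -> ; k1*A\ndB: B -> ; k2*B"
        )
        problem, best = true_best(m, ["k1", "k2"], (0, 1, 2, 4, 8, 12), ["A", "B"])
        curve = profile_likelihood(problem, best, "k1", span_orders=1, n_points=6)
        _, trace = coparameter_trace(curve, "k2")
        assert np.all(np.abs(np.log10(trace / 0.4)) < 0.05)


class TestProfileAll:
    def test_reports_per_starting_set_and_determinism(self):
        problem, best = true_best(
            synthetic.decay_model(), ["k"], (0, 1, 2, 4, 8, 12), ["A"]
        )
        reports = profile_all(problem, [best, best], n_points=6)
        assert len(reports) == 2
        assert list(reports[0].curves) == ["k"]
        assert reports[0].to_dict()["parameters"] == reports[1].to_dict()["parameters"]

    def test_report_serializes_to_json(self, tmp_path):
        problem, best = true_best(
            synthetic.decay_model(), ["k"], (0, 1, 2, 4, 8, 12), ["A"]
        )
        report = profile_all(problem, [best], n_points=6)[0]
        report.to_json(tmp_path / "r.json")
        import json

        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["parameters"]["k"]["classification"] == IDENTIFIABLE


class TestCoverage:
    def test_profile_ci_covers_true_rate(self):
        """95% profile CIs on a 1-parameter decay with unit Gaussian noise
        should cover the truth at roughly the nominal rate."""
        model = synthetic.decay_model()
        times = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 12.0])
        truth = model.simulate(times)["A"]
        rng = np.random.default_rng(2024)
        om = ObservationMap.uniform(["A"], 1.0)
        cfg = OptimizerConfig(algorithm="hooke_jeeves", tolerance=1e-8,
                              iteration_limit=200)
        hits = trials = 0
        for _ in range(60):
            y = truth[:, None] + rng.normal(0.0, 1.0, size=(6, 3))
            table = ExperimentTable(times, ["A"], y[:, :, None])
            problem = FitProblem(model, table, om, ["k"], weighting="none")
            fit = hooke_jeeves(problem.weighted_rss, problem, {"k": 0.1}, cfg)
            best = ParameterSet(fit.values, fit.rss)
            curve = profile_likelihood(problem, best, "k", span_orders=1.5,
                                       n_points=8)
            verdict = classify(curve, confidence_threshold(best.rss))
            if verdict.classification == IDENTIFIABLE:
                trials += 1
                hits += verdict.ci_lower <= 0.1 <= verdict.ci_upper
        assert trials >= 50
        assert 0.85 <= hits / trials <= 1.0
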