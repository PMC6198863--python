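"""Self-contained benchmark experiments on the bundled fixture models.

Each function runs one end-to-end exercise of the toolkit at reduced,
fixed problem sizes — optimizer convergence on an analytic objective,
parameter recovery on noise-free data, the identifiability-oracle
trio, generative-model recovery by information criteria, detection of
a product-coupled parameter pair, and the qPCR round trip — and
returns plain numbers.  They are deterministic functions of their seed
and double as worked examples of the API.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .data import ObservationMap, ddct_normalize
from .estimation import (
    FitProblem,
    OptimizerConfig,
    ParameterSet,
    chaser,
    genetic_algorithm,
    hooke_jeeves,
    rank,
)
from .identifiability import (
    IDENTIFIABLE,
    PRACTICAL,
    STRUCTURAL,
    profile_all,
)
from .selection import multi_model_fit, select
from . import synthetic

__all__ = [
    "quadratic_convergence",
    "rss_oracle_deviation",
    "parameter_recovery",
    "identifiability_oracle",
    "selection_recovery",
    "coupled_pair_correlation",
    "ddct_roundtrip_error",
]

#: reduced GA settings for the fixture-scale experiments
REDUCED_GA = OptimizerConfig(population_size=20, generations=25)
#: chaser settings used when only the archive's best set needs polishing
FAST_CHASE = OptimizerConfig(algorithm="hooke_jeeves", tolerance=1e-8,
                             iteration_limit=200)
#: full-strength chaser (demo-protocol settings)
DEEP_CHASE = OptimizerConfig(algorithm="hooke_jeeves", tolerance=1e-10,
                             iteration_limit=1000)


def _motif_problem(noise: str, cv: float, data_seed: int | None) -> FitProblem:
    nf, _, _ = synthetic.motif_models()
    table = synthetic.generate_data(
        nf, observables=("X", "F"), noise=noise, cv=cv, seed=data_seed
    )
    obs_map = ObservationMap.uniform(["X", "F"], synthetic.DEFAULT_SCALE_FACTOR)
    return FitProblem(nf, table, obs_map, ["kx", "kdx", "kf"],
                      sim_rtol=1e-6, sim_atol=1e-9)


def quadratic_convergence(seed: int = 0) -> dict:
    """GA (pop 50 x 100 generations) then pattern search on a bounded
    5-D quadratic bowl in log10 space; returns the gap to the analytic
    optimum (zero)."""
    free = [(f"x{i}", 1e-7, 1e4) for i in range(5)]
    target = np.array([-2.0, 0.0, 1.0, -4.0, 2.0])

    def objective(values):
        z = np.log10([values[f"x{i}"] for i in range(5)])
        return float(np.sum((z - target) ** 2))

    ga = genetic_algorithm(
        objective, free, OptimizerConfig(population_size=50, generations=100, seed=seed)
    )
    hj = hooke_jeeves(objective, free, ga.values, DEEP_CHASE)
    return {"ga_gap": ga.rss, "final_gap": hj.rss, "n": 5}


def rss_oracle_deviation(seed: int = 0, n_instances: int = 100) -> dict:
    """Largest relative deviation between the vectorized weighted-RSS
    objective and a naive triple-loop reference over random draws."""
    problem = _motif_problem("gaussian_cv", 0.1, data_seed=seed)
    rng = np.random.default_rng(seed)
    lb, ub = problem.bounds_array()
    worst = 0.0
    for _ in range(n_instances):
        z = np.log10(lb) + rng.random(problem.n_free) * (np.log10(ub) - np.log10(lb))
        values = dict(zip(problem.parameter_names, 10.0 ** z))
        fast = problem.weighted_rss(values)
        pred = problem.predictions(values)
        slow = 0.0
        for ti in range(problem.data.times.size):
            for ri in range(problem.data.n_replicates):
                for oi, obs in enumerate(problem.data.observables):
                    y = problem.data.values[ti, ri, oi]
                    if math.isnan(y):
                        continue
                    sigma = (problem.summary.sd[ti, oi]
                             if problem.weighting == "sd" else 1.0)
                    slow += ((y - pred.iloc[ti, oi]) / sigma) ** 2
        if math.isinf(fast) and math.isinf(slow):
            continue
        worst = max(worst, abs(fast - slow) / max(abs(slow), 1e-300))
    return {"max_rel_deviation": worst, "n": n_instances}


def parameter_recovery(seed: int = 0, n_runs: int = 20) -> dict:
    """Repeat estimation (reduced GA) + chaser on noise-free data from
    the negative-feedback motif; returns the worst relative parameter
    error in percent."""
    problem = _motif_problem("none", 0.0, data_seed=None)
    truth = {name: problem.model.parameters[name] for name in problem.parameter_names}
    results = problem.fit(n_runs=n_runs, config=REDUCED_GA, seed=seed).chase(
        top_k=3, config=DEEP_CHASE
    )
    errors = {
        name: abs(results.params[name] - value) / value
        for name, value in truth.items()
    }
    return {
        "max_rel_error_pct": 100.0 * max(errors.values()),
        "best_rss": results.rss,
        "n": n_runs,
    }


def _true_best(model, free, times, observables) -> tuple[FitProblem, ParameterSet]:
    table = synthetic.generate_data(
        model, times=times, observables=observables, noise="none", scale_factors=1.0
    )
    obs_map = ObservationMap.uniform(observables, 1.0)
    problem = FitProblem(model, table, obs_map, free)
    values = {name: model.parameters[name] for name in problem.parameter_names}
    return problem, ParameterSet(values, problem.weighted_rss(values))


def identifiability_oracle(n_points: int = 8) -> dict:
    """Classify three constructed cases: an identifiable decay rate, a
    product-coupled structural pair, and a saturation rate observed
    only before saturation (practical)."""
    prob_i, best_i = _true_best(
        synthetic.decay_model(), ["k"], (0, 1, 2, 4, 8, 12), ["A"]
    )
    rep_i = profile_all(prob_i, [best_i], n_points=n_points)[0]

    prob_ii, best_ii = _true_best(
        synthetic.coupled_pair_model(), ["k1", "k2"], (0, 1, 2, 4, 8, 12), ["A"]
    )
    rep_ii = profile_all(prob_ii, [best_ii], n_points=n_points)[0]

    prob_iii, best_iii = _true_best(
        synthetic.saturating_model(), ["k", "Xmax"],
        (0, 0.1, 0.2, 0.3, 0.4, 0.5), ["X"],
    )
    rep_iii = profile_all(prob_iii, [best_iii], n_points=n_points)[0]

    classes = {
        "identifiable_case": rep_i.verdicts["k"].classification,
        "structural_case": rep_ii.verdicts["k1"].classification,
        "practical_case": rep_iii.verdicts["k"].classification,
    }
    classes["n_correct"] = sum([
        classes["identifiable_case"] == IDENTIFIABLE,
        classes["structural_case"] == STRUCTURAL,
        classes["practical_case"] == PRACTICAL,
    ])
    return classes


def selection_recovery(
    seed: int = 0,
    n_repetitions: int = 20,
    n_runs: int = 3,
    cv: float = 0.1,
) -> dict:
    """Generative-model recovery: data simulated from the
    negative-feedback motif (6 times x 6 replicates, cv 0.1), all three
    motifs calibrated and ranked by AICc; counts how often the
    generating topology wins."""
    models = synthetic.motif_models()
    obs_map = ObservationMap.uniform(["X", "F"], synthetic.DEFAULT_SCALE_FACTOR)
    cfg = OptimizerConfig(population_size=16, generations=20)
    wins = 0
    for rep in range(n_repetitions):
        table = synthetic.generate_data(
            models[0], observables=("X", "F"), noise="gaussian_cv", cv=cv,
            seed=seed * n_repetitions + rep,
        )
        problems = [
            FitProblem(m, table, obs_map, ["kx", "kdx", "kf"],
                       sim_rtol=1e-6, sim_atol=1e-9)
            for m in models
        ]
        archives = multi_model_fit(
            problems, n_runs=n_runs, config=cfg, seed=seed + 1000 * rep
        )
        chase_cfg = OptimizerConfig(algorithm="hooke_jeeves", tolerance=1e-8,
                                    iteration_limit=100)
        archives = [
            rank(chaser(a, top_k=min(2, n_runs), local_config=chase_cfg))
            for a in archives
        ]
        report = select(archives, criteria=("aicc",))
        wins += report.winner == "negative_feedback"
    return {"wins": wins, "n": n_repetitions}


def coupled_pair_correlation(seed: int = 0, n_runs: int = 15) -> dict:
    """Chased repeat estimates of the product-coupled pair (k1, k2):
    squared Pearson correlation of their log10 estimates."""
    from .viz import correlations

    model = synthetic.coupled_pair_model()
    table = synthetic.generate_data(
        model, observables=["A"], noise="none", scale_factors=1.0
    )
    obs_map = ObservationMap.uniform(["A"], 1.0)
    problem = FitProblem(model, table, obs_map, ["k1", "k2"],
                         sim_rtol=1e-6, sim_atol=1e-9)
    results = problem.fit(
        n_runs=n_runs, config=OptimizerConfig(population_size=16, generations=15),
        seed=seed,
    )
    archive = rank(chaser(results.archive, top_k=n_runs, local_config=FAST_CHASE))
    chased_only = archive.replaced([s for s in archive if s.chased], ranked=True)
    out, fig = correlations(chased_only, flag_threshold=0.0)
    import matplotlib.pyplot as plt

    plt.close(fig)
    r = out["matrix"].loc["k1", "k2"]
    return {"r2": float(r**2), "n": n_runs}


def ddct_roundtrip_error(seed: int = 0) -> dict:
    """Synthesize a raw Ct plate from a baseline-normalized expression
    table and recover it through 2^-ddCt normalization (zero Ct noise)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = synthetic.generate_data(
            synthetic.smad_demo_models()[1],
            observables=("Smad7", "Ski"),
            noise="lognormal", cv=0.2, seed=seed,
        ).normalize_to_baseline()
    plate = synthetic.synthesize_qpcr_plate(table, ct_noise=0.0, seed=seed)
    recovered = ddct_normalize(plate)
    err = float(np.nanmax(np.abs(recovered.values - table.values)))
    return {"max_abs_error": err, "n": table.n_points()}
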