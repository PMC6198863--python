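"""Weighted least-squares calibration of kinetic models.

The objective is the standard-deviation-weighted residual sum of
squares over every replicate data point,

.. math::
    RSS(\\theta) = \\sum_{t,o,r}
        \\left(\\frac{y_{t,o,r} - X_o(t;\\theta)/X_{SF,o}}
                     {\\sigma_{t,o}}\\right)^2,

minimized by a real-coded genetic algorithm (global) and a Hooke &
Jeeves pattern search (local "chaser"), both operating in log10
parameter space because bounds span many decades (default 1e-7..1e4).
Repeat estimations from random starts build an
:class:`EstimationArchive`, which downstream modules rank, truncate,
profile and visualize.

The user-facing surface follows the model/results idiom:
``FitProblem(model, data, obs_map, free).fit(...)`` returns a
:class:`FitResults` with the archive, the best parameter set and
``summary()`` / ``chase()`` / ``profile()`` methods.
"""

from __future__ import annotations

import logging
import math
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ExperimentTable, ObservationMap, summarize_replicates
from .model import KineticModel, SimulationError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_LOWER_BOUND",
    "DEFAULT_UPPER_BOUND",
    "FitProblem",
    "FitResults",
    "OptimizerConfig",
    "ParameterSet",
    "EstimationArchive",
    "weighted_rss",
    "sample_start",
    "genetic_algorithm",
    "hooke_jeeves",
    "repeat_estimation",
    "chaser",
    "rank",
    "truncate",
]

#: default estimation boundaries (span 11 decades)
DEFAULT_LOWER_BOUND = 1e-7
DEFAULT_UPPER_BOUND = 1e4


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings for the global (GA) and local (Hooke & Jeeves) optimizers.

    The GA uses tournament selection (size 2), uniform crossover,
    per-gene Gaussian mutation in log10 space and elitism of one.  The
    pattern search explores each log10 coordinate with step halving and
    stops when the step drops below ``tolerance`` or after
    ``iteration_limit`` exploratory/pattern cycles.
    """

    algorithm: str = "genetic"
    population_size: int = 300
    generations: int = 500
    mutation_rate: float | None = None  # default 1/d per gene
    crossover_rate: float = 0.5
    mutation_sigma: float = 0.2  # decades
    tournament_size: int = 2
    tolerance: float = 1e-6
    iteration_limit: int = 50
    initial_step: float = 0.2  # decades
    seed: int | None = None

    def __post_init__(self):
        if self.algorithm not in ("genetic", "hooke_jeeves"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.generations < 1 or self.iteration_limit < 1:
            raise ValueError("generations and iteration_limit must be >= 1")


@dataclass(frozen=True)
class ParameterSet:
    """One candidate solution: parameter values, objective and provenance."""

    values: Mapping[str, float]
    rss: float
    run_id: int = 0
    seed: int | None = None
    algorithm: str = ""
    chased: bool = False
    source_run: int | None = None
    history: tuple = field(default=(), repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))
        if self.rss < 0 or math.isnan(self.rss):
            raise ValueError("rss must be >= 0 (or +inf for failures)")


class EstimationArchive:
    """A collection of parameter sets from repeat estimations."""

    def __init__(self, problem, parameter_sets: Sequence[ParameterSet], ranked=False,
                 failures: Sequence[str] = ()):
        self.problem = problem
        self.parameter_sets = list(parameter_sets)
        self.ranked = ranked
        self.failures = list(failures)

    def __len__(self) -> int:
        return len(self.parameter_sets)

    def __iter__(self):
        return iter(self.parameter_sets)

    def __getitem__(self, i) -> ParameterSet:
        return self.parameter_sets[i]

    @property
    def best(self) -> ParameterSet:
        return min(self.parameter_sets, key=lambda s: (s.rss, s.run_id))

    @property
    def rss(self) -> np.ndarray:
        return np.array([s.rss for s in self.parameter_sets])

    @property
    def parameter_names(self) -> list[str]:
        if not self.parameter_sets:
            return []
        return list(self.parameter_sets[0].values)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.parameter_sets:
            row = {
                "run_id": s.run_id,
                "seed": s.seed,
                "algorithm": s.algorithm,
                "chased": s.chased,
                "rss": s.rss,
            }
            row.update(s.values)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, problem=None) -> "EstimationArchive":
        df = pd.read_csv(path)
        meta = ["run_id", "seed", "algorithm", "chased", "rss"]
        params = [c for c in df.columns if c not in meta]
        sets = [
            ParameterSet(
                {p: row[p] for p in params},
                rss=row["rss"],
                run_id=int(row["run_id"]),
                seed=None if pd.isna(row["seed"]) else int(row["seed"]),
                algorithm=str(row["algorithm"]),
                chased=bool(row["chased"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(problem, sets)

    def replaced(self, parameter_sets, ranked=False) -> "EstimationArchive":
        return EstimationArchive(self.problem, parameter_sets, ranked, self.failures)


# ---------------------------------------------------------------------------
# FitProblem: the model-like object
# ---------------------------------------------------------------------------

class FitProblem:
    """A calibration problem: model + data + observation map + free parameters.

    Parameters
    ----------
    model : KineticModel
    data : ExperimentTable (arbitrary units)
    observation_map : ObservationMap linking observables to species and
        scale factors
    free_parameters : list of names or of (name, lower, upper) tuples;
        bounds default to 1e-7 and 1e4
    weighting : "sd" (divide residuals by the replicate standard
        deviation at each time/observable, floored) or "none"
    sim_rtol, sim_atol : integration tolerances used inside the
        objective.  Defaults match the simulation defaults; loosening
        them (e.g. 1e-6/1e-9) speeds up global search considerably, at
        the cost of ~1e-6 relative noise on the objective, because the
        optimizers evaluate the model at arbitrary points of an
        11-decade search box where tight tolerances are expensive.
    """

    def __init__(
        self,
        model: KineticModel,
        data: ExperimentTable,
        observation_map: ObservationMap,
        free_parameters: Sequence,
        weighting: str = "sd",
        sd_floor=None,
        sim_rtol: float = 1e-8,
        sim_atol: float = 1e-10,
    ):
        self.sim_rtol = sim_rtol
        self.sim_atol = sim_atol
        self.model = model
        self.data = data
        self.observation_map = observation_map
        self.weighting = weighting
        if weighting not in ("sd", "none"):
            raise ValueError("weighting must be 'sd' or 'none'")

        free: list[tuple[str, float, float]] = []
        for item in free_parameters:
            if isinstance(item, str):
                free.append((item, DEFAULT_LOWER_BOUND, DEFAULT_UPPER_BOUND))
            else:
                name, lb, ub = item
                free.append((name, float(lb), float(ub)))
        for name, lb, ub in free:
            if name not in model.parameters:
                raise ValueError(f"free parameter {name!r} not in model")
            if not (0 < lb < ub):
                raise ValueError(f"bounds for {name!r} must satisfy 0 < lb < ub")
        self.free_parameters = free

        for obs in data.observables:
            if obs not in observation_map:
                raise ValueError(f"data observable {obs!r} is not mapped to a species")
            species = observation_map.species_for(obs)
            if species not in model.species_names:
                raise ValueError(
                    f"observable {obs!r} maps to unknown species {species!r}"
                )

        self.summary = summarize_replicates(
            data, sd_floor=sd_floor, require_replication=(weighting == "sd")
        )
        # cached arrays for the fast objective path
        self._y = data.values  # (T, R, O)
        self._obs_index = list(data.observables)
        self._sf = np.array([observation_map.scale_factor(o) for o in self._obs_index])
        self._species = [observation_map.species_for(o) for o in self._obs_index]
        if weighting == "sd":
            self._sigma = self.summary.sd  # (T, O)
        else:
            self._sigma = np.ones((data.times.size, len(self._obs_index)))
        self._mask = np.isfinite(self._y)
        self._failures_logged = 0

    # -- sizes ---------------------------------------------------------
    @property
    def n_free(self) -> int:
        return len(self.free_parameters)

    def n_points(self) -> int:
        return self.data.n_points()

    @property
    def parameter_names(self) -> list[str]:
        return [name for name, _, _ in self.free_parameters]

    def bounds_array(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([b for _, b, _ in self.free_parameters])
        ub = np.array([b for _, _, b in self.free_parameters])
        return lb, ub

    # -- objective -----------------------------------------------------
    def predictions(self, values: Mapping[str, float] | None = None,
                    times=None) -> pd.DataFrame:
        """Simulate and map to data units at the given times (data times
        by default); columns are the data observables."""
        times = self.data.times if times is None else np.asarray(times, dtype=float)
        sim = self.model.simulate(
            times, overrides=dict(values or {}),
            rtol=self.sim_rtol, atol=self.sim_atol,
        )
        cols = {}
        for i, obs in enumerate(self._obs_index):
            cols[obs] = sim[self._species[i]] / self._sf[i]
        return pd.DataFrame(cols, index=pd.Index(times, name="time"))

    def weighted_rss(self, values: Mapping[str, float]) -> float:
        """The weighted RSS objective; +inf on integration failure."""
        try:
            pred = self.predictions(values).to_numpy()  # (T, O)
        except (SimulationError, FloatingPointError, OverflowError) as exc:
            # first failure per problem at WARNING, the rest at DEBUG:
            # global search legitimately visits non-simulable regions
            level = logging.DEBUG if self._failures_logged else logging.WARNING
            self._failures_logged += 1
            logger.log(level, "objective evaluation failed (%s); returning +inf", exc)
            return math.inf
        if not np.all(np.isfinite(pred)):
            return math.inf
        resid = (self._y - pred[:, None, :]) / self._sigma[:, None, :]
        return float(np.nansum(resid[self._mask] ** 2))

    __call__ = weighted_rss

    # -- fitting ---------------------------------------------------------
    def fit(
        self,
        n_runs: int = 1,
        config: OptimizerConfig | None = None,
        seed: int | None = None,
        max_workers: int = 1,
    ) -> "FitResults":
        """Run ``n_runs`` independent estimations and return ranked results."""
        archive = repeat_estimation(
            self, n_runs=n_runs, config=config, seed=seed, max_workers=max_workers
        )
        return FitResults(self, rank(archive))


# ---------------------------------------------------------------------------
# bounds plumbing shared by the optimizers
# ---------------------------------------------------------------------------

def _bounds_of(problem) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Accept a FitProblem or a plain list of (name, lb, ub) tuples."""
    free = getattr(problem, "free_parameters", problem)
    names = [name for name, _, _ in free]
    lb = np.array([float(b) for _, b, _ in free])
    ub = np.array([float(b) for _, _, b in free])
    if np.any(lb <= 0) or np.any(lb >= ub):
        raise ValueError("bounds must satisfy 0 < lb < ub")
    return names, np.log10(lb), np.log10(ub)


def _objective_of(problem, objective):
    if objective is not None:
        return objective
    if hasattr(problem, "weighted_rss"):
        return problem.weighted_rss
    raise TypeError("an explicit objective is required for plain bound lists")


def weighted_rss(problem: FitProblem, values: Mapping[str, float]) -> float:
    """Module-level alias for :meth:`FitProblem.weighted_rss`."""
    return problem.weighted_rss(values)


def sample_start(problem, seed: int | None = None) -> dict[str, float]:
    """Draw each free parameter log-uniformly between its bounds."""
    names, zlb, zub = _bounds_of(problem)
    rng = np.random.default_rng(seed)
    z = zlb + rng.random(len(names)) * (zub - zlb)
    return {n: 10.0 ** zi for n, zi in zip(names, z)}


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

def genetic_algorithm(
    objective: Callable | None = None,
    problem=None,
    config: OptimizerConfig | None = None,
) -> ParameterSet:
    """Real-coded genetic algorithm in log10 parameter space.

    Tournament selection (size ``config.tournament_size``), uniform
    crossover, per-gene Gaussian mutation (sigma in decades) and elitism
    of one.  The best-so-far objective is non-increasing by construction.
    """
    config = config or OptimizerConfig()
    names, zlb, zub = _bounds_of(problem)
    obj = _objective_of(problem, objective)
    d = len(names)
    rng = np.random.default_rng(config.seed)
    p_mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / max(d, 1)

    def evaluate(z: np.ndarray) -> float:
        val = obj({n: 10.0 ** zi for n, zi in zip(names, z)})
        return float(val) if not math.isnan(val) else math.inf

    pop = zlb + rng.random((config.population_size, d)) * (zub - zlb)
    fitness = np.array([evaluate(z) for z in pop])
    best_i = int(np.argmin(fitness))
    best_z, best_f = pop[best_i].copy(), fitness[best_i]
    history = [best_f]
    infinite_streak = 0

    for _gen in range(config.generations):
        if not np.any(np.isfinite(fitness)):
            infinite_streak += 1
            if infinite_streak >= 3:
                raise RuntimeError(
                    "genetic algorithm aborted: entire population had infinite "
                    "objective for 3 consecutive generations (model not simulable "
                    "anywhere in the search box?)"
                )
        else:
            infinite_streak = 0

        new_pop = np.empty_like(pop)
        new_pop[0] = best_z  # elitism
        for i in range(1, config.population_size):
            parents = []
            for _ in range(2):
                idx = rng.integers(0, config.population_size, size=config.tournament_size)
                parents.append(pop[idx[np.argmin(fitness[idx])]])
            mask = rng.random(d) < config.crossover_rate
            child = np.where(mask, parents[0], parents[1])
            mut = rng.random(d) < p_mut
            child = child + mut * rng.normal(0.0, config.mutation_sigma, size=d)
            new_pop[i] = np.clip(child, zlb, zub)
        pop = new_pop
        fitness = np.array([evaluate(z) for z in pop])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_f:
            best_z, best_f = pop[gen_best].copy(), fitness[gen_best]
        history.append(best_f)

    values = {n: 10.0 ** zi for n, zi in zip(names, best_z)}
    return ParameterSet(
        values, best_f, seed=config.seed, algorithm="genetic", history=tuple(history)
    )


def hooke_jeeves(
    objective: Callable | None = None,
    problem=None,
    start: Mapping[str, float] | None = None,
    config: OptimizerConfig | None = None,
) -> ParameterSet:
    """Hooke & Jeeves pattern search in log10 parameter space.

    Exploratory moves of +/- ``step`` decades per coordinate, pattern
    moves along successful directions, step halving on failure.
    Terminates when the step drops below ``config.tolerance`` or after
    ``config.iteration_limit`` cycles.  The returned objective is never
    worse than at ``start``.
    """
    config = config or OptimizerConfig(algorithm="hooke_jeeves")
    names, zlb, zub = _bounds_of(problem)
    obj = _objective_of(problem, objective)
    d = len(names)

    def evaluate(z: np.ndarray) -> float:
        val = obj({n: 10.0 ** zi for n, zi in zip(names, z)})
        return float(val) if not math.isnan(val) else math.inf

    if start is None:
        raise ValueError("hooke_jeeves requires a start point")
    z0 = np.clip(np.log10(np.array([start[n] for n in names], dtype=float)), zlb, zub) \
        if d else np.empty(0)
    f0 = evaluate(z0)
    if d == 0:
        return ParameterSet({}, f0, algorithm="hooke_jeeves")

    def explore(z: np.ndarray, fz: float, step: float) -> tuple[np.ndarray, float]:
        z = z.copy()
        for i in range(d):
            for delta in (step, -step):
                trial = z.copy()
                trial[i] = np.clip(z[i] + delta, zlb[i], zub[i])
                ft = evaluate(trial)
                if ft < fz:
                    z, fz = trial, ft
                    break
        return z, fz

    base, fbase = z0.copy(), f0
    step = float(config.initial_step)
    iterations = 0
    while step > config.tolerance and iterations < config.iteration_limit:
        iterations += 1
        x, fx = explore(base, fbase, step)
        if fx < fbase:
            # pattern moves: keep extrapolating along the successful direction
            while iterations < config.iteration_limit:
                iterations += 1
                pattern = np.clip(x + (x - base), zlb, zub)
                fp = evaluate(pattern)
                xe, fe = explore(pattern, fp, step)
                base, fbase = x, fx
                if fe < fx:
                    x, fx = xe, fe
                else:
                    break
            else:
                base, fbase = x, fx
            base, fbase = (x, fx) if fx < fbase else (base, fbase)
        else:
            step /= 2.0

    values = {n: 10.0 ** zi for n, zi in zip(names, base)}
    return ParameterSet(values, fbase, algorithm="hooke_jeeves")


# ---------------------------------------------------------------------------
# repeat estimation, chasing, ranking
# ---------------------------------------------------------------------------

def _single_run(problem, objective, config: OptimizerConfig, run_id: int,
                run_seed: int) -> ParameterSet:
    cfg = replace(config, seed=run_seed)
    if config.algorithm == "genetic":
        ps = genetic_algorithm(objective, problem, cfg)
    else:
        start = sample_start(problem, seed=run_seed)
        ps = hooke_jeeves(objective, problem, start, cfg)
    return replace(ps, run_id=run_id, seed=run_seed)


def repeat_estimation(
    problem,
    n_runs: int,
    config: OptimizerConfig | None = None,
    seed: int | None = None,
    max_workers: int = 1,
    objective: Callable | None = None,
) -> EstimationArchive:
    """``n_runs`` independent estimations from random starts.

    Run ``i`` uses seed ``base + i`` so the result is a deterministic
    function of the base seed, independent of ``max_workers`` (a local
    worker pool caps concurrent evaluations).
    """
    if n_runs < 1 or max_workers < 1:
        raise ValueError("n_runs and max_workers must be >= 1")
    config = config or OptimizerConfig()
    base = seed if seed is not None else (config.seed or 0)
    obj = _objective_of(problem, objective)

    results: list[ParameterSet | None] = [None] * n_runs
    failures: list[str] = []

    def task(i: int):
        return _single_run(problem, obj, config, i, base + i)

    if max_workers == 1:
        for i in range(n_runs):
            try:
                results[i] = task(i)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                failures.append(f"run {i}: {exc}")
                logger.warning("estimation run %d failed: %s", i, exc)
    else:
        with ThreadPoolExecutor(max_workers=max_workers) as pool:
            futures = {pool.submit(task, i): i for i in range(n_runs)}
            for fut, i in futures.items():
                try:
                    results[i] = fut.result()
                except Exception as exc:  # noqa: BLE001
                    failures.append(f"run {i}: {exc}")
                    logger.warning("estimation run %d failed: %s", i, exc)

    sets = [r for r in results if r is not None]
    if not sets:
        raise RuntimeError(f"all {n_runs} estimation runs failed: {failures}")
    return EstimationArchive(problem, sets, ranked=False, failures=failures)


def rank(archive: EstimationArchive) -> EstimationArchive:
    """Sort by RSS ascending, ties broken by run id."""
    if not archive.parameter_sets:
        raise ValueError("cannot rank an empty archive")
    ordered = sorted(archive.parameter_sets, key=lambda s: (s.rss, s.run_id))
    return archive.replaced(ordered, ranked=True)


def truncate(archive: EstimationArchive, mode: str, value) -> EstimationArchive:
    """Keep a subset of a ranked archive.

    mode="fraction": best ``value`` fraction (0 < value <= 1);
    mode="count": best ``value`` sets (clipped to the archive size);
    mode="rss_cutoff": all sets with RSS <= value.
    """
    if not archive.ranked:
        archive = rank(archive)
    n = len(archive)
    if mode == "fraction":
        if not (0 < value <= 1):
            raise ValueError("fraction must be in (0, 1]")
        keep = max(1, int(math.floor(value * n + 1e-9)))
        subset = archive.parameter_sets[:keep]
    elif mode == "count":
        keep = min(int(value), n)
        if keep < 1:
            raise ValueError("count must be >= 1")
        subset = archive.parameter_sets[:keep]
    elif mode == "rss_cutoff":
        subset = [s for s in archive.parameter_sets if s.rss <= value]
    else:
        raise ValueError(f"unknown truncation mode {mode!r}")
    return archive.replaced(subset, ranked=True)


def chaser(
    archive: EstimationArchive,
    top_k: int | None = None,
    top_fraction: float | None = None,
    local_config: OptimizerConfig | None = None,
    objective: Callable | None = None,
) -> EstimationArchive:
    """Refine the best global candidates with the local pattern search.

    Selected sets are driven to their local minima by Hooke & Jeeves and
    appended to the archive flagged ``chased``; each refined RSS is <=
    its source RSS.
    """
    if top_k is None and top_fraction is None:
        top_k = 3
    if not archive.ranked:
        archive = rank(archive)
    if top_fraction is not None:
        selected = truncate(archive, "fraction", top_fraction).parameter_sets
    else:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        if top_k > len(archive):
            warnings.warn(
                f"requested top_k={top_k} but archive has {len(archive)} sets; clipping"
            )
            top_k = len(archive)
        selected = archive.parameter_sets[:top_k]

    local_config = local_config or OptimizerConfig(
        algorithm="hooke_jeeves", tolerance=1e-10, iteration_limit=1000
    )
    obj = _objective_of(archive.problem, objective)
    next_id = max((s.run_id for s in archive.parameter_sets), default=-1) + 1
    chased_sets = []
    for j, src in enumerate(selected):
        refined = hooke_jeeves(obj, archive.problem, src.values, local_config)
        if refined.rss > src.rss:  # pattern search never worsens; belt and braces
            refined = replace(refined, values=dict(src.values), rss=src.rss)
        chased_sets.append(
            replace(
                refined,
                run_id=next_id + j,
                seed=src.seed,
                chased=True,
                source_run=src.run_id,
            )
        )
    return archive.replaced(archive.parameter_sets + chased_sets, ranked=False)


# ---------------------------------------------------------------------------
# FitResults: the results object
# ---------------------------------------------------------------------------

class FitResults:
    """Ranked repeat-estimation results for one :class:`FitProblem`."""

    def __init__(self, problem: FitProblem, archive: EstimationArchive):
        if not archive.ranked:
            archive = rank(archive)
        self.problem = problem
        self.archive = archive

    @property
    def best(self) -> ParameterSet:
        return self.archive[0]

    @property
    def params(self) -> dict[str, float]:
        return dict(self.best.values)

    @property
    def rss(self) -> float:
        return self.best.rss

    def aicc(self) -> float:
        from .selection import aicc

        return aicc(self.rss, self.problem.n_points(), self.problem.n_free)

    def bic(self) -> float:
        from .selection import bic

        return bic(self.rss, self.problem.n_points(), self.problem.n_free)

    def chase(self, top_k: int = 3, config: OptimizerConfig | None = None) -> "FitResults":
        """Refine the best ``top_k`` sets locally; returns new results."""
        return FitResults(self.problem, rank(chaser(self.archive, top_k=top_k,
                                                    local_config=config)))

    def truncated(self, mode: str = "fraction", value=0.1) -> "FitResults":
        return FitResults(self.problem, truncate(self.archive, mode, value))

    def profile(self, parameters=None, **kwargs):
        """Profile-likelihood identifiability analysis from the best set."""
        from .identifiability import profile_all

        return profile_all(self.problem, [self.best], parameters=parameters, **kwargs)[0]

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        df = self.archive.to_frame()
        names = self.problem.parameter_names
        lines = [
            "Kinetic model calibration results",
            "=" * 64,
            f"Model:            {self.problem.model.name}",
            f"Runs in archive:  {len(self.archive)} "
            f"({int(df['chased'].sum())} chased)",
            f"Data points (n):  {self.problem.n_points()}",
            f"Free params (k):  {self.problem.n_free}",
            f"Weighting:        {self.problem.weighting}",
            f"Best RSS:         {self.rss:.6g}",
        ]
        try:
            lines.append(f"AICc (best):      {self.aicc():.6g}")
            lines.append(f"BIC (best):       {self.bic():.6g}")
        except ValueError:
            lines.append("AICc/BIC:         undefined (n <= k + 1)")
        lines.append("-" * 64)
        lines.append(f"{'parameter':<24}{'best':>12}{'median':>12}{'IQR(log10)':>14}")
        for name in names:
            col = df[name].astype(float)
            q1, q3 = np.percentile(np.log10(col[col > 0]), [25, 75])
            lines.append(
                f"{name:<24}{self.best.values[name]:>12.4g}"
                f"{col.median():>12.4g}{q3 - q1:>14.3g}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    # -- plotting -------------------------------------------------------
    def plot_likelihood_ranks(self, **kwargs):
        from .viz import likelihood_ranks

        return likelihood_ranks(self.archive, **kwargs)

    def plot_ensemble(self, **kwargs):
        from .viz import ensemble_timecourse

        return ensemble_timecourse(self.problem, self.archive, **kwargs)

    def plot_distributions(self, **kwargs):
        from .viz import distributions

        return distributions(self.archive, **kwargs)

    def plot_correlations(self, **kwargs):
        from .viz import correlations

        return correlations(self.archive, **kwargs)

    def __repr__(self) -> str:
        return (
            f"<FitResults {self.problem.model.name!r}: best RSS {self.rss:.4g} "
            f"over {len(self.archive)} sets>"
        )
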