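"""Profile-likelihood identifiability analysis.

Starting from a (near-)optimal parameter set, each free parameter is
fixed in turn on a log10-spaced grid spanning several orders of
magnitude around its best value; all remaining free parameters are
re-optimized at every grid point (warm-started from the neighbouring
solution, sweeping outward in both directions).  The resulting curve of
re-optimized weighted RSS is compared with a likelihood-ratio
confidence threshold:

* crosses the threshold on both sides  -> identifiable, with the
  crossing points as confidence bounds;
* completely flat                      -> structurally non-identifiable
  (the parameter is algebraically compensated by others);
* anything else                        -> practically non-identifiable
  (data insufficient for a finite interval on at least one side).

Thresholds: ``chi2_pointwise`` uses best RSS + Q_{chi2,1}(alpha), valid
for sd-weighted RSS; ``f_based`` uses
best RSS * (1 + Q_{F,1,n-p}(alpha) / (n - p)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.stats import chi2, f as f_dist

from .estimation import (
    FitProblem,
    OptimizerConfig,
    ParameterSet,
    hooke_jeeves,
)

__all__ = [
    "IDENTIFIABLE",
    "PRACTICAL",
    "STRUCTURAL",
    "ProfileCurve",
    "ThresholdSpec",
    "IdentifiabilityReport",
    "profile_likelihood",
    "confidence_threshold",
    "classify",
    "coparameter_trace",
    "profile_all",
]

IDENTIFIABLE = "identifiable"
PRACTICAL = "practically_non_identifiable"
STRUCTURAL = "structurally_non_identifiable"

DEFAULT_PROFILE_CONFIG = OptimizerConfig(
    algorithm="hooke_jeeves", tolerance=1e-6, iteration_limit=50
)


@dataclass
class ProfileCurve:
    """Re-optimized RSS as one parameter is scanned on a log10 grid."""

    parameter: str
    best_value: float
    best_rss: float
    fixed_values: np.ndarray  # strictly increasing
    rss: np.ndarray
    coparameters: pd.DataFrame  # one column per other free parameter
    span_orders: float = 3.0
    n_points: int = 0

    def __post_init__(self):
        self.fixed_values = np.asarray(self.fixed_values, dtype=float)
        self.rss = np.asarray(self.rss, dtype=float)
        if np.any(np.diff(self.fixed_values) <= 0):
            raise ValueError("fixed values must be strictly increasing")
        if np.any(self.rss[np.isfinite(self.rss)] < 0):
            raise ValueError("RSS values must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"parameter": self.parameter, "fixed_value": self.fixed_values,
             "rss": self.rss}
        )
        return pd.concat([df, self.coparameters.reset_index(drop=True)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ThresholdSpec:
    """Confidence-threshold recipe for profile classification."""

    alpha: float = 0.95
    mode: str = "chi2_pointwise"

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.mode not in ("chi2_pointwise", "f_based"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")


@dataclass
class ParameterVerdict:
    classification: str
    ci_lower: float
    ci_upper: float
    best_value: float
    suspected: bool = False  # flat profiles are only *suspected* structural


@dataclass
class IdentifiabilityReport:
    """Per-parameter classification for one starting parameter set."""

    source_run: int
    threshold: float
    best_rss: float
    verdicts: dict[str, ParameterVerdict]
    curves: dict[str, ProfileCurve] = field(default_factory=dict)

    def classification_counts(self) -> dict[str, int]:
        counts = {IDENTIFIABLE: 0, PRACTICAL: 0, STRUCTURAL: 0}
        for v in self.verdicts.values():
            counts[v.classification] += 1
        return counts

    def to_dict(self) -> dict:
        return {
            "source_run": self.source_run,
            "threshold": self.threshold,
            "best_rss": self.best_rss,
            "parameters": {
                name: {
                    "classification": v.classification,
                    "ci_lower": v.ci_lower,
                    "ci_upper": v.ci_upper,
                    "best_value": v.best_value,
                    "suspected": v.suspected,
                }
                for name, v in self.verdicts.items()
            },
        }

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _reoptimize(problem: FitProblem, parameter: str, fixed_value: float,
                start: Mapping[str, float], config: OptimizerConfig):
    """Fix ``parameter`` and re-optimize the remaining free parameters."""
    other_free = [fp for fp in problem.free_parameters if fp[0] != parameter]

    def objective(values: Mapping[str, float]) -> float:
        merged = dict(values)
        merged[parameter] = fixed_value
        return problem.weighted_rss(merged)

    if not other_free:
        return objective({}), {}
    start_others = {name: start[name] for name, _, _ in other_free}
    result = hooke_jeeves(objective, other_free, start_others, config)
    return result.rss, dict(result.values)


def profile_likelihood(
    problem: FitProblem,
    best: ParameterSet,
    parameter: str,
    span_orders: float = 3.0,
    n_points: int = 20,
    local_config: OptimizerConfig | None = None,
) -> ProfileCurve:
    """Scan one parameter and re-optimize the others at every grid point.

    The grid is ``n_points`` log10-spaced values per direction over
    ``[best/10^span, best*10^span]`` intersected with the parameter's
    bounds.  Sweeps proceed outward from the best value, warm-starting
    each re-optimization from the neighbouring point's solution.
    """
    if parameter not in problem.parameter_names:
        raise KeyError(f"{parameter!r} is not a free parameter of the problem")
    if not math.isfinite(best.rss):
        raise ValueError("profile requires a finite best RSS")
    config = local_config or DEFAULT_PROFILE_CONFIG
    theta = float(best.values[parameter])
    lb, ub = next((l, u) for n, l, u in problem.free_parameters if n == parameter)

    z0 = math.log10(theta)
    zlo = max(z0 - span_orders, math.log10(lb))
    zhi = min(z0 + span_orders, math.log10(ub))
    up_grid = np.linspace(z0, zhi, n_points + 1)[1:] if zhi > z0 else np.empty(0)
    down_grid = np.linspace(z0, zlo, n_points + 1)[1:] if zlo < z0 else np.empty(0)

    records = []  # (fixed value, rss, coparams)
    other_names = [n for n in problem.parameter_names if n != parameter]

    # the anchor: re-optimization at the best value itself
    rss0, co0 = _reoptimize(problem, parameter, theta, best.values, config)
    records.append((theta, rss0, co0))

    for grid in (up_grid, down_grid):
        start = dict(best.values)
        start.update(co0)
        for z in grid:
            value = 10.0 ** z
            try:
                rss_i, co_i = _reoptimize(problem, parameter, value, start, config)
            except Exception as exc:  # noqa: BLE001 - recorded as failure point
                warnings.warn(f"profile point {parameter}={value:g} failed: {exc}")
                rss_i, co_i = math.inf, {n: start.get(n, np.nan) for n in other_names}
            records.append((value, rss_i, co_i))
            if co_i:
                start = dict(start)
                start.update(co_i)  # warm start for the next point outward

    records.sort(key=lambda r: r[0])
    fixed_values = np.array([r[0] for r in records])
    rss = np.array([r[1] for r in records])
    coparams = pd.DataFrame([r[2] for r in records], columns=other_names)
    return ProfileCurve(
        parameter=parameter,
        best_value=theta,
        best_rss=float(best.rss),
        fixed_values=fixed_values,
        rss=rss,
        coparameters=coparams,
        span_orders=span_orders,
        n_points=n_points,
    )


def confidence_threshold(
    best_rss: float,
    n_points_total: int | None = None,
    n_free: int | None = None,
    spec: ThresholdSpec | None = None,
) -> float:
    """RSS threshold above which the profile leaves the confidence region."""
    spec = spec or ThresholdSpec()
    if best_rss < 0:
        raise ValueError("best_rss must be >= 0")
    if spec.mode == "chi2_pointwise":
        return best_rss + chi2.ppf(spec.alpha, df=1)
    n, p = n_points_total, n_free
    if n is None or p is None or n <= p:
        raise ValueError("f_based threshold requires n_points_total > n_free")
    return best_rss * (1.0 + f_dist.ppf(spec.alpha, 1, n - p) / (n - p))


def classify(
    curve: ProfileCurve,
    threshold: float,
    flatness_tol: float = 1e-3,
) -> ParameterVerdict:
    """Classify one profile curve against a confidence threshold.

    Flat curves (relative RSS variation below ``flatness_tol``) are
    *suspected* structural non-identifiabilities — the scan only samples
    the parameter space.  Otherwise threshold crossings are located by
    monotone cubic-spline (PCHIP) interpolation of RSS against
    log10(parameter).
    """
    if curve.fixed_values.size < 5:
        raise ValueError("classification needs at least 5 scan points")
    if threshold <= curve.best_rss:
        raise ValueError("threshold must exceed the best RSS")

    finite = np.isfinite(curve.rss)
    rss = np.where(finite, curve.rss, np.nanmax(curve.rss[finite]) if finite.any() else 0)
    scale = max(1.0, curve.best_rss)
    if (rss.max() - rss.min()) < flatness_tol * scale:
        return ParameterVerdict(
            STRUCTURAL, -math.inf, math.inf, curve.best_value, suspected=True
        )

    z = np.log10(curve.fixed_values)
    spline = PchipInterpolator(z, rss, extrapolate=False)
    z_best = math.log10(curve.best_value)

    def crossing(side: str) -> float | None:
        if side == "upper":
            dense = np.linspace(z_best, z[-1], 512)
        else:
            dense = np.linspace(z_best, z[0], 512)
        vals = spline(dense)
        above = np.nonzero(vals > threshold)[0]
        if above.size == 0:
            return None
        j = above[0]
        if j == 0:
            return float(dense[0])
        lo, hi = sorted((dense[j - 1], dense[j]))
        try:
            return float(brentq(lambda s: spline(s) - threshold, lo, hi))
        except ValueError:
            return float(dense[j])

    up = crossing("upper")
    down = crossing("lower")
    if up is not None and down is not None:
        return ParameterVerdict(
            IDENTIFIABLE, 10.0 ** down, 10.0 ** up, curve.best_value
        )
    return ParameterVerdict(
        PRACTICAL,
        10.0 ** down if down is not None else -math.inf,
        10.0 ** up if up is not None else math.inf,
        curve.best_value,
    )


def coparameter_trace(curve: ProfileCurve, other_parameter: str):
    """Re-optimized values of another parameter along the scan.

    Plotting this trace instead of the RSS reveals compensatory
    relationships (e.g. a product coupling appears as a straight line of
    slope -1 in log-log space) that inform model reduction.
    """
    if other_parameter not in curve.coparameters.columns:
        raise KeyError(
            f"{other_parameter!r} was not a free co-parameter of this profile"
        )
    return curve.fixed_values, curve.coparameters[other_parameter].to_numpy()


def profile_all(
    problem: FitProblem,
    best_sets: Sequence[ParameterSet],
    parameters: Sequence[str] | None = None,
    span_orders: float = 3.0,
    n_points: int = 20,
    local_config: OptimizerConfig | None = None,
    threshold_spec: ThresholdSpec | None = None,
    flatness_tol: float = 1e-3,
) -> list[IdentifiabilityReport]:
    """Full identifiability report for each starting parameter set.

    Profiles are meaningful only from (near-)optimal sets, so callers
    typically pass chased parameter sets.  Discordant classifications
    across starting sets are flagged with a warning.
    """
    parameters = list(parameters or problem.parameter_names)
    spec = threshold_spec or ThresholdSpec()
    reports = []
    for ps in best_sets:
        curves: dict[str, ProfileCurve] = {}
        verdicts: dict[str, ParameterVerdict] = {}
        threshold = confidence_threshold(
            ps.rss, problem.n_points(), problem.n_free, spec
        )
        for name in parameters:
            curve = profile_likelihood(
                problem, ps, name, span_orders, n_points, local_config
            )
            curves[name] = curve
            verdicts[name] = classify(curve, threshold, flatness_tol)
        reports.append(
            IdentifiabilityReport(
                source_run=ps.run_id,
                threshold=threshold,
                best_rss=ps.rss,
                verdicts=verdicts,
                curves=curves,
            )
        )

    for name in parameters:
        classes = {r.verdicts[name].classification for r in reports}
        if len(classes) > 1:
            warnings.warn(
                f"parameter {name!r} classified discordantly across starting sets: "
                f"{sorted(classes)}"
            )
    return reports
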