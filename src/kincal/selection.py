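"""Information-criteria model selection over parameter-estimation archives.

Criteria use the RSS-based Gaussian forms

.. math::
    AIC = n \\ln(RSS/n) + 2k, \\qquad
    AICc = AIC + \\frac{2k(k+1)}{n-k-1}, \\qquad
    BIC = n \\ln(RSS/n) + k \\ln n,

where ``n`` counts all non-missing replicate data points and ``k`` the
free (estimated) parameters.  Lower is better.  Computing criteria from
the sd-weighted RSS assumes the replicate standard deviations are the
true error scales.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import EstimationArchive, FitProblem, OptimizerConfig, repeat_estimation, rank

__all__ = ["aicc", "aic", "bic", "multi_model_fit", "select", "SelectionReport"]


def aic(rss: float, n: int, k: int) -> float:
    """Akaike information criterion for a Gaussian RSS fit."""
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if rss == 0:
        warnings.warn("rss is exactly 0; criterion is -inf")
        return -math.inf
    return n * math.log(rss / n) + 2 * k


def aicc(rss: float, n: int, k: int) -> float:
    """AIC with the small-sample correction 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    base = aic(rss, n, k)
    return base + (2 * k * (k + 1)) / (n - k - 1)


def bic(rss: float, n: int, k: int) -> float:
    """Bayesian information criterion for a Gaussian RSS fit."""
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if rss == 0:
        warnings.warn("rss is exactly 0; criterion is -inf")
        return -math.inf
    return n * math.log(rss / n) + k * math.log(n)


@dataclass
class ModelSelectionEntry:
    name: str
    archive: EstimationArchive
    n: int
    k: int
    criteria: pd.DataFrame  # per-set aicc/bic columns
    best: dict[str, float]
    excluded: bool = False


@dataclass
class SelectionReport:
    """Ranked comparison of calibrated models by information criteria."""

    entries: list[ModelSelectionEntry]
    criterion: str  # the criterion used for the ranking
    ranking: list[str]  # model names, best first
    deltas: dict[str, float]  # delta criterion vs the winner

    @property
    def winner(self) -> str:
        return self.ranking[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"model": e.name, "n": e.n, "k": e.k, "excluded": e.excluded}
            for crit in e.criteria.columns:
                row[f"best_{crit}"] = e.best.get(crit, math.nan)
            row[f"delta_{self.criterion}"] = self.deltas.get(e.name, math.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def per_set_frame(self) -> pd.DataFrame:
        frames = []
        for e in self.entries:
            df = e.criteria.copy()
            df.insert(0, "model", e.name)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "ranking": self.ranking,
            "deltas": self.deltas,
            "models": {
                e.name: {"n": e.n, "k": e.k, "best": e.best, "excluded": e.excluded}
                for e in self.entries
            },
        }

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def multi_model_fit(
    problems: Sequence[FitProblem],
    n_runs: int,
    config: OptimizerConfig | None = None,
    seed: int | None = None,
    max_workers: int = 1,
) -> list[EstimationArchive]:
    """Calibrate several models against the same data set.

    Each model gets ``n_runs`` repeat estimations; model ``m`` uses base
    seed ``seed + m * n_runs`` so the per-run streams never overlap.
    Archives are returned in input order (ranked).
    """
    if len(problems) < 1:
        raise ValueError("at least one problem required")
    ref = problems[0].data
    for p in problems[1:]:
        if p.data is not ref and p.data != ref:
            raise ValueError("all problems must share the same experimental data")
    base = seed or 0
    archives = []
    for m, problem in enumerate(problems):
        archive = repeat_estimation(
            problem, n_runs=n_runs, config=config, seed=base + m * n_runs,
            max_workers=max_workers,
        )
        archives.append(rank(archive))
    return archives


def select(
    archives: Sequence[EstimationArchive],
    criteria: Sequence[str] = ("aicc", "bic"),
    names: Sequence[str] | None = None,
    ranking_criterion: str | None = None,
) -> SelectionReport:
    """Compute criteria for every parameter set and rank the models.

    Models whose data size violates ``n > k + 1`` are flagged and
    excluded from the AICc ranking rather than failing the whole
    comparison.
    """
    fns = {"aic": aic, "aicc": aicc, "bic": bic}
    for crit in criteria:
        if crit not in fns:
            raise ValueError(f"unknown criterion {crit!r}")
    ranking_criterion = ranking_criterion or criteria[0]

    entries = []
    for i, archive in enumerate(archives):
        if not archive.ranked:
            archive = rank(archive)
        problem = archive.problem
        name = (
            names[i] if names is not None
            else getattr(getattr(problem, "model", None), "name", f"model_{i}")
        )
        n, k = problem.n_points(), problem.n_free
        per_set: dict[str, list[float]] = {c: [] for c in criteria}
        excluded = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in archive:
                for crit in criteria:
                    try:
                        per_set[crit].append(fns[crit](s.rss, n, k))
                    except ValueError:
                        per_set[crit].append(math.nan)
                        excluded = True
        df = pd.DataFrame(per_set)
        best = {
            crit: float(np.nanmin(df[crit])) if df[crit].notna().any() else math.nan
            for crit in criteria
        }
        entries.append(ModelSelectionEntry(name, archive, n, k, df, best, excluded))

    rankable = [e for e in entries if not (e.excluded and ranking_criterion == "aicc")]
    if not rankable:
        raise ValueError("no model admits the requested ranking criterion")
    ordered = sorted(rankable, key=lambda e: e.best[ranking_criterion])
    ranking = [e.name for e in ordered]
    best_value = ordered[0].best[ranking_criterion]
    deltas = {e.name: e.best[ranking_criterion] - best_value for e in ordered}
    return SelectionReport(entries, ranking_criterion, ranking, deltas)
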