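"""Diagnostic plots for parameter-estimation ensembles.

Every plotting operation first computes plain numeric arrays (returned
alongside the figure) and only then renders them, so tests exercise the
numbers and figures stay a thin layer on top.  Figures are matplotlib;
call ``save_figure`` or pass ``path=`` to write PNG + SVG with the
plot-ready data as CSV alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import matplotlib

matplotlib.use("Agg")  # headless-safe; figures are written, not shown

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .estimation import EstimationArchive, FitProblem, truncate as _truncate

__all__ = [
    "ensemble_timecourse",
    "likelihood_ranks",
    "distributions",
    "correlations",
    "plot_profiles",
    "plot_selection",
    "save_figure",
]


def save_figure(fig, path, data: pd.DataFrame | None = None) -> None:
    """Write a figure as PNG and SVG, plus its plot-ready data as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path.with_suffix(".png"), dpi=150)
    fig.savefig(path.with_suffix(".svg"))
    if data is not None:
        data.to_csv(path.with_suffix(".csv"), index=False)


@dataclass
class EnsembleBand:
    observable: str
    times: np.ndarray
    center: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def ensemble_timecourse(
    problem: FitProblem,
    archive: EstimationArchive,
    select: int = 10,
    n_boot: int = 1000,
    estimator: Callable = np.mean,
    ci_level: float = 0.95,
    n_times: int = 60,
    seed: int | None = 0,
    path=None,
):
    """Bootstrap confidence bands over trajectories of the top parameter sets.

    The best ``select`` sets are inserted into the model in turn and
    simulated; at each time point the estimator (default: mean) is
    bootstrapped over parameter sets (``n_boot`` resamples, percentile
    interval).  Experimental replicates are overlaid on the figure.
    """
    selected = _truncate(archive, "count", select).parameter_sets
    if not selected:
        raise ValueError("no parameter sets selected for the ensemble")
    t_data = problem.data.times
    times = np.unique(np.concatenate(
        [np.linspace(t_data[0], t_data[-1], n_times), t_data]
    ))
    trajectories = []  # (n_sets, n_times, n_obs)
    for ps in selected:
        try:
            pred = problem.predictions(ps.values, times=times)
        except Exception as exc:  # noqa: BLE001 - drop the failing set
            import warnings

            warnings.warn(f"dropping parameter set {ps.run_id}: simulation failed ({exc})")
            continue
        trajectories.append(pred.to_numpy())
    if not trajectories:
        raise RuntimeError("every selected parameter set failed to simulate")
    traj = np.array(trajectories)

    rng = np.random.default_rng(seed)
    n_sets = traj.shape[0]
    center = estimator(traj, axis=0)
    if n_sets == 1:
        lower = upper = center
    else:
        idx = rng.integers(0, n_sets, size=(n_boot, n_sets))
        boot = estimator(traj[idx], axis=1)  # (n_boot, n_times, n_obs)
        q = (1 - ci_level) / 2
        lower = np.quantile(boot, q, axis=0)
        upper = np.quantile(boot, 1 - q, axis=0)

    observables = problem.data.observables
    bands = {
        obs: EnsembleBand(obs, times, center[:, i], lower[:, i], upper[:, i])
        for i, obs in enumerate(observables)
    }

    fig, axes = plt.subplots(
        1, len(observables), figsize=(4 * len(observables), 3.2), squeeze=False
    )
    for i, obs in enumerate(observables):
        ax = axes[0, i]
        b = bands[obs]
        ax.fill_between(b.times, b.lower, b.upper, alpha=0.3, color="C0",
                        label=f"{int(ci_level * 100)}% CI")
        ax.plot(b.times, b.center, color="C0", label="ensemble")
        y = problem.data.observable_values(obs)
        for r in range(y.shape[1]):
            ax.plot(t_data, y[:, r], ".", color="C3", ms=4,
                    label="data" if r == 0 else None)
        ax.set_xlabel("time (h)")
        ax.set_title(obs)
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        frames = []
        for obs, b in bands.items():
            frames.append(pd.DataFrame({
                "observable": obs, "time": b.times, "center": b.center,
                "lower": b.lower, "upper": b.upper,
            }))
        save_figure(fig, path, pd.concat(frames, ignore_index=True))
    return bands, fig


def likelihood_ranks(archive: EstimationArchive, log_scale: bool = True, path=None):
    """Waterfall plot: sorted RSS against rank of best fit.

    Plateaus indicate repeatedly found minima (a well-posed problem); a
    smooth curve indicates non-converged estimations.
    """
    if len(archive) == 0:
        raise ValueError("archive is empty")
    rss = np.sort(archive.rss)
    ranks = np.arange(1, rss.size + 1)
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(ranks, rss, "o-", ms=3)
    if log_scale and np.all(rss > 0):
        ax.set_yscale("log")
    ax.set_xlabel("rank of best fit")
    ax.set_ylabel("RSS")
    fig.tight_layout()
    if path is not None:
        save_figure(fig, path, pd.DataFrame({"rank": ranks, "rss": rss}))
    return (ranks, rss), fig


def distributions(
    archive: EstimationArchive,
    truncation: tuple[str, float] | None = None,
    bins: int = 20,
    path=None,
):
    """Box-plot quartiles and histogram bins of log10 parameter estimates."""
    if truncation is not None:
        archive = _truncate(archive, *truncation)
    if len(archive) == 0:
        raise ValueError("archive is empty after truncation")
    df = archive.to_frame()
    names = archive.parameter_names
    summaries = {}
    hists = {}
    for name in names:
        vals = np.log10(df[name].to_numpy(dtype=float))
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        summaries[name] = {
            "q1": q1, "median": q2, "q3": q3, "iqr": q3 - q1,
            "min": vals.min(), "max": vals.max(),
        }
        counts, edges = np.histogram(vals, bins=bins)
        hists[name] = (counts, edges)

    fig, (ax_box, ax_hist) = plt.subplots(1, 2, figsize=(9, 3.2))
    ax_box.boxplot(
        [np.log10(df[n].to_numpy(dtype=float)) for n in names], tick_labels=names
    )
    ax_box.set_ylabel("log10(estimate)")
    ax_box.tick_params(axis="x", rotation=45)
    for name in names:
        counts, edges = hists[name]
        ax_hist.stairs(counts, edges, label=name, alpha=0.7)
    ax_hist.set_xlabel("log10(estimate)")
    ax_hist.set_ylabel("count")
    ax_hist.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        save_figure(fig, path, pd.DataFrame(summaries).T.reset_index(names="parameter"))
    return {"summaries": summaries, "histograms": hists}, fig


def correlations(
    archive: EstimationArchive,
    truncation: tuple[str, float] | None = None,
    flag_threshold: float = 0.9,
    path=None,
):
    """Pearson correlations of log10 estimates, with flagged pairs.

    Pairs with ``|r| >= flag_threshold`` are listed with r^2 and p-value
    and get scatter data for follow-up; zero-variance parameters are
    masked (NaN row/column).
    """
    if truncation is not None:
        archive = _truncate(archive, *truncation)
    if len(archive) < 3:
        raise ValueError("correlation analysis needs at least 3 parameter sets")
    df = archive.to_frame()
    names = archive.parameter_names
    logs = np.log10(df[names].to_numpy(dtype=float))
    d = len(names)
    r = np.full((d, d), np.nan)
    p = np.full((d, d), np.nan)
    variances = logs.var(axis=0)
    for i in range(d):
        r[i, i] = 1.0 if variances[i] > 0 else np.nan
        p[i, i] = 0.0 if variances[i] > 0 else np.nan
        for j in range(i + 1, d):
            if variances[i] == 0 or variances[j] == 0:
                continue
            rij, pij = pearsonr(logs[:, i], logs[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    flagged = []
    for i in range(d):
        for j in range(i + 1, d):
            if np.isfinite(r[i, j]) and abs(r[i, j]) >= flag_threshold:
                flagged.append({
                    "pair": (names[i], names[j]),
                    "r": float(r[i, j]),
                    "r2": float(r[i, j] ** 2),
                    "p_value": float(p[i, j]),
                    "x": logs[:, i],
                    "y": logs[:, j],
                })

    n_panels = 1 + len(flagged)
    fig, axes = plt.subplots(1, n_panels, figsize=(4 * n_panels, 3.4), squeeze=False)
    ax = axes[0, 0]
    im = ax.imshow(r, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(d), names, rotation=90, fontsize=7)
    ax.set_yticks(range(d), names, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r (log10)")
    for k, fl in enumerate(flagged, start=1):
        axs = axes[0, k]
        axs.plot(fl["x"], fl["y"], "o", ms=3)
        axs.set_xlabel(f"log10 {fl['pair'][0]}")
        axs.set_ylabel(f"log10 {fl['pair'][1]}")
        axs.set_title(f"r2={fl['r2']:.3f}, p={fl['p_value']:.2g}", fontsize=8)
    fig.tight_layout()
    if path is not None:
        save_figure(fig, path, pd.DataFrame(r, index=names, columns=names).reset_index())
    result = {"matrix": pd.DataFrame(r, index=names, columns=names),
              "p_values": pd.DataFrame(p, index=names, columns=names),
              "flagged": flagged}
    return result, fig


def plot_profiles(
    reports,
    threshold: float | None = None,
    coparameter: str | None = None,
    path=None,
):
    """Grid of profile-likelihood panels, one per parameter.

    Multiple reports (starting sets) are overlaid.  Stars mark the best
    estimates, the dashed line the confidence threshold; with
    ``coparameter`` the y-axis shows that parameter's re-optimized trace
    instead of the RSS.
    """
    if not isinstance(reports, (list, tuple)):
        reports = [reports]
    names = list(reports[0].curves)
    ncol = min(3, len(names))
    nrow = math.ceil(len(names) / ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.6 * ncol, 2.8 * nrow),
                             squeeze=False)
    for k, name in enumerate(names):
        ax = axes[k // ncol, k % ncol]
        for ri, report in enumerate(reports):
            curve = report.curves[name]
            if coparameter is not None and coparameter != name:
                x, y = curve.fixed_values, curve.coparameters[coparameter].to_numpy()
                ax.set_ylabel(coparameter)
                ax.set_yscale("log")
            else:
                x, y = curve.fixed_values, curve.rss
                ax.set_ylabel("RSS")
            ax.plot(x, y, "o-", ms=3, label=f"set {report.source_run}")
            if coparameter is None:
                ax.plot([curve.best_value], [curve.best_rss], "k*", ms=9)
        thr = threshold if threshold is not None else reports[0].threshold
        if coparameter is None and thr is not None:
            ax.axhline(thr, color="green", ls=":", label="confidence level")
        ax.set_xscale("log")
        ax.set_xlabel(name)
        if k == 0:
            ax.legend(fontsize=6)
    for k in range(len(names), nrow * ncol):
        axes[k // ncol, k % ncol].axis("off")
    fig.tight_layout()
    if path is not None:
        frames = [r.curves[n].to_frame().assign(source_run=r.source_run)
                  for r in reports for n in names]
        save_figure(fig, path, pd.concat(frames, ignore_index=True))
    return fig


def plot_selection(report, path=None):
    """Violin plots of per-set criteria plus a best-value comparison."""
    per_set = report.per_set_frame()
    crit = report.criterion
    models = [e.name for e in report.entries]
    data = [per_set.loc[per_set["model"] == m, crit].dropna().to_numpy()
            for m in models]
    best = [e.best.get(crit, math.nan) for e in report.entries]

    fig, (ax_v, ax_b) = plt.subplots(1, 2, figsize=(9, 3.4))
    nonempty = [d for d in data if d.size]
    if nonempty:
        positions = [i for i, d in enumerate(data) if d.size]
        ax_v.violinplot([d for d in data if d.size], positions=positions,
                        showmedians=True)
    ax_v.set_xticks(range(len(models)), models, rotation=30)
    ax_v.set_ylabel(crit.upper())
    ax_v.set_title(f"{crit.upper()} distribution per model")
    ax_b.bar(models, best)
    ax_b.set_ylabel(f"best {crit.upper()}")
    ax_b.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    if path is not None:
        save_figure(fig, path, report.to_frame())
    return {"per_model": dict(zip(models, data)), "best": dict(zip(models, best))}, fig
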