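"""Experimental tables, qPCR normalization and observation mapping.

Measurements live in arbitrary units (relative expression from qPCR);
model species live in model units.  The observation function

.. math:: X_{Obs}(t) = X(t) / X_{SF}

links the two through a per-observable scale factor :math:`X_{SF}`.
Replicated time-course data are stored in an :class:`ExperimentTable`
(time x replicate x observable array); raw qPCR cycle-threshold plates
are normalized with the 2^-ddCt method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .model import TimeCourse

__all__ = [
    "QPCRPlate",
    "ExperimentTable",
    "ObservationMap",
    "ReplicateSummary",
    "ddct_normalize",
    "map_observation",
    "summarize_replicates",
    "read_experiment",
    "write_experiment",
]


@dataclass
class QPCRPlate:
    """Raw qPCR cycle-threshold (Ct) values.

    ``ct`` has one row per physical sample with ``time`` and
    ``replicate`` columns plus one column per gene.  ``calibrator``
    selects the baseline samples (default: all t = 0 samples).  NaN
    marks a missing measurement.
    """

    ct: pd.DataFrame
    reference_genes: list[str]
    calibrator: Callable[[pd.DataFrame], pd.Series] | None = None

    def __post_init__(self):
        for col in ("time", "replicate"):
            if col not in self.ct.columns:
                raise ValueError(f"Ct table must have a {col!r} column")
        missing = set(self.reference_genes) - set(self.genes)
        if missing:
            raise ValueError(f"reference genes absent from plate: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return [c for c in self.ct.columns if c not in ("time", "replicate")]

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.genes if g not in self.reference_genes]

    def calibrator_mask(self) -> pd.Series:
        if self.calibrator is not None:
            return self.calibrator(self.ct)
        return self.ct["time"] == self.ct["time"].min()


@dataclass
class ObservationMap:
    """Observable name -> (model species, scale factor X_SF > 0)."""

    mapping: dict[str, tuple[str, float]]

    def __post_init__(self):
        for obs, (species, sf) in self.mapping.items():
            if not np.isfinite(sf) or sf <= 0:
                raise ValueError(f"scale factor for {obs!r} must be > 0, got {sf}")

    @classmethod
    def uniform(cls, observables, scale_factor: float = 100.0) -> "ObservationMap":
        """Map each observable to the species of the same name."""
        return cls({obs: (obs, float(scale_factor)) for obs in observables})

    def __getitem__(self, obs: str) -> tuple[str, float]:
        return self.mapping[obs]

    def __contains__(self, obs: str) -> bool:
        return obs in self.mapping

    def __iter__(self):
        return iter(self.mapping)

    def species_for(self, obs: str) -> str:
        return self.mapping[obs][0]

    def scale_factor(self, obs: str) -> float:
        return self.mapping[obs][1]


class ExperimentTable:
    """Replicated time-course measurements in arbitrary units.

    Parameters
    ----------
    times : array of time points (hours), strictly increasing
    observables : observable names
    values : array of shape (n_times, n_replicates, n_observables);
        NaN marks a missing measurement.
    provenance : free-text note on where the data came from
    """

    def __init__(self, times, observables, values, provenance: str = ""):
        self.times = np.asarray(times, dtype=float)
        self.observables = list(observables)
        self.values = np.asarray(values, dtype=float)
        self.provenance = provenance
        if self.values.ndim != 3 or self.values.shape[0] != self.times.size or (
            self.values.shape[2] != len(self.observables)
        ):
            raise ValueError(
                "values must have shape (n_times, n_replicates, n_observables)"
            )
        if self.values.shape[1] < 1:
            raise ValueError("at least one replicate required")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            order = np.argsort(self.times)
            self.times = self.times[order]
            self.values = self.values[order]
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values) < 0:
                warnings.warn("negative values present in experiment table")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def n_points(self) -> int:
        """Number of non-missing data points (enters information criteria)."""
        return int(np.isfinite(self.values).sum())

    def observable_values(self, obs: str) -> np.ndarray:
        return self.values[:, :, self.observables.index(obs)]

    def baseline_means(self) -> dict[str, float]:
        """Replicate mean of each observable at the first time point."""
        return {
            obs: float(np.nanmean(self.values[0, :, i]))
            for i, obs in enumerate(self.observables)
        }

    def subset(self, observables) -> "ExperimentTable":
        """A view-copy restricted to the given observables, in order."""
        missing = [o for o in observables if o not in self.observables]
        if missing:
            raise KeyError(f"observables not in table: {missing}")
        idx = [self.observables.index(o) for o in observables]
        return ExperimentTable(
            self.times, list(observables), self.values[:, :, idx], self.provenance
        )

    def normalize_to_baseline(self) -> "ExperimentTable":
        """Divide each observable by its geometric mean over t=0 replicates.

        After this, the t=0 geometric mean of every observable is one —
        the convention under which a synthesized qPCR plate round-trips
        exactly through 2^-ddCt normalization.
        """
        vals = self.values.copy()
        for i in range(len(self.observables)):
            base = self.values[0, :, i]
            base = base[np.isfinite(base) & (base > 0)]
            if base.size == 0:
                raise ValueError(
                    f"observable {self.observables[i]!r} has no positive t=0 values"
                )
            vals[:, :, i] /= np.exp(np.mean(np.log(base)))
        return ExperimentTable(
            self.times, self.observables, vals, self.provenance + " [baseline-normalized]"
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times}
        for i, obs in enumerate(self.observables):
            for r in range(self.n_replicates):
                cols[f"{obs}:{r + 1}"] = self.values[:, r, i]
        return pd.DataFrame(cols)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExperimentTable):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and self.observables == other.observables
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    def __repr__(self) -> str:
        return (
            f"<ExperimentTable {len(self.times)} times x {self.n_replicates} reps x "
            f"{len(self.observables)} observables>"
        )


@dataclass
class ReplicateSummary:
    """Per time/observable replicate mean and (floored) sample sd."""

    times: np.ndarray
    observables: list[str]
    mean: np.ndarray  # (n_times, n_observables)
    sd: np.ndarray  # (n_times, n_observables), floored
    sd_floor: np.ndarray  # per-observable floor actually applied
    floored: np.ndarray  # boolean mask where flooring kicked in

    def sd_for(self, obs: str) -> np.ndarray:
        return self.sd[:, self.observables.index(obs)]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def ddct_normalize(plate: QPCRPlate) -> ExperimentTable:
    """Relative expression by the 2^-ddCt method.

    Per sample, each target gene's Ct is referenced to the arithmetic
    mean Ct of the reference genes (equivalent to normalizing linear
    expression to the reference genes' geometric mean); the resulting
    dCt is then referenced to the mean dCt of the calibrator samples
    (all t=0 samples by default) and exponentiated base 2.

    Samples missing any reference-gene Ct are dropped with a warning.
    """
    ct = plate.ct.copy()
    refs = ct[plate.reference_genes]
    bad = refs.isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} sample(s) with missing reference-gene Ct"
        )
        ct = ct.loc[~bad]
    if ct.empty:
        raise ValueError("no samples left after dropping missing reference Ct")

    ref_mean = ct[plate.reference_genes].mean(axis=1)
    targets = plate.target_genes
    dct = ct[targets].sub(ref_mean, axis=0)

    calib_mask = (
        plate.calibrator(ct) if plate.calibrator is not None
        else ct["time"] == ct["time"].min()
    )
    if not calib_mask.any():
        raise ValueError("calibrator selects no samples")
    ddct = dct - dct.loc[calib_mask].mean(axis=0)
    expression = 2.0 ** (-ddct)

    expression["time"] = ct["time"].values
    expression["replicate"] = ct["replicate"].values
    times = np.sort(expression["time"].unique())
    n_rep = int(expression.groupby("time")["replicate"].count().max())
    values = np.full((times.size, n_rep, len(targets)), np.nan)
    for ti, t in enumerate(times):
        block = expression[expression["time"] == t]
        for ri, (_, row) in enumerate(block.iterrows()):
            values[ti, ri, :] = row[targets].to_numpy(dtype=float)
    return ExperimentTable(times, targets, values, provenance="2^-ddCt normalized")


def map_observation(sim: TimeCourse, obs_map: ObservationMap) -> pd.DataFrame:
    """Apply the observation function X_Obs = X / X_SF to a simulation."""
    out = {"time": sim.times}
    for obs in obs_map:
        species, sf = obs_map[obs]
        if species not in sim.labels:
            raise KeyError(f"species {species!r} (observable {obs!r}) not in simulation")
        out[obs] = sim[species] / sf
    return pd.DataFrame(out).set_index("time")


def summarize_replicates(
    table: ExperimentTable,
    sd_floor: float | Mapping[str, float] | None = None,
    sd_floor_fraction: float = 0.05,
    require_replication: bool = True,
) -> ReplicateSummary:
    """Replicate mean and sample sd (ddof=1) per time/observable.

    Standard deviations below the floor are replaced by it so that sd
    weights stay finite when replicates coincide.  The default floor is
    ``sd_floor_fraction`` (5%) of each observable's mean over all times
    and replicates.
    """
    if table.n_replicates < 2 and require_replication:
        raise ValueError(
            "sd weighting needs >= 2 replicates; use weighting='none' "
            "for single-replicate data"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        mean = np.nanmean(table.values, axis=1)
        if table.n_replicates >= 2:
            sd = np.nanstd(table.values, axis=1, ddof=1)
        else:
            sd = np.zeros_like(mean)

    n_obs = len(table.observables)
    if sd_floor is None:
        overall = np.nanmean(np.abs(table.values), axis=(0, 1))
        floor = sd_floor_fraction * overall
        floor = np.where(floor > 0, floor, 1e-12)
    elif isinstance(sd_floor, Mapping):
        floor = np.array([float(sd_floor[o]) for o in table.observables])
    else:
        floor = np.full(n_obs, float(sd_floor))
    if np.any(floor <= 0):
        raise ValueError("sd floor must be > 0")

    floored = ~(sd > floor)  # includes NaN sd
    sd = np.where(floored, floor[None, :], sd)
    return ReplicateSummary(
        times=table.times,
        observables=list(table.observables),
        mean=mean,
        sd=sd,
        sd_floor=floor,
        floored=floored,
    )


def write_experiment(table: ExperimentTable, path) -> None:
    """Write the CSV dialect: ``time`` column plus ``observable:rep`` columns."""
    table.to_frame().to_csv(path, index=False)


def read_experiment(path) -> ExperimentTable:
    """Read the CSV dialect written by :func:`write_experiment`.

    Rows are sorted by time; replicate columns are grouped by the
    ``name:rep`` prefix.  Non-numeric cells are reported with their
    row and column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing required 'time' column")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric value {df[col][row]!r} at row {row}, column {col!r}"
            )
        df[col] = converted
    df = df.sort_values("time").reset_index(drop=True)

    groups: dict[str, list[str]] = {}
    for col in df.columns:
        if col == "time":
            continue
        obs = col.split(":", 1)[0]
        groups.setdefault(obs, []).append(col)
    observables = list(groups)
    n_rep = max(len(cols) for cols in groups.values())
    values = np.full((len(df), n_rep, len(observables)), np.nan)
    for i, obs in enumerate(observables):
        for r, col in enumerate(groups[obs]):
            values[:, r, i] = df[col].to_numpy(dtype=float)
    return ExperimentTable(
        df["time"].to_numpy(dtype=float), observables, values, provenance=str(path)
    )
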