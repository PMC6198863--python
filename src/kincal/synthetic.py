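"""Fixture models and synthetic data emulating the TGF-beta study design.

The generator reproduces the study conditions: observables sampled at
0, 1, 2, 4, 8 and 12 h with 6 biological replicates; measurements in
arbitrary units linked to model units by scale factors (default 100);
protein profiles derived from mRNA with a 30-minute lag and a 100-fold
magnitude; optional synthesis of raw qPCR Ct plates by inverting the
2^-ddCt transform.

Fixture models are small reaction networks with committed "true"
parameter values (the values stored in each returned model), so every
pipeline stage is testable without downloads:

* :func:`motif_models` — negative-feedback, positive-feedback and
  feed-forward motifs sharing an input stimulus ``S`` and observables
  ``X`` (output) and ``F`` (regulator);
* :func:`smad_demo_models` — three reduced Smad7/Ski variants differing
  in how the Smad7 negative feedback consumes its targets;
* :func:`coupled_pair_model`, :func:`decay_model`,
  :func:`saturating_model` — constructed identifiability oracles.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np

from .data import ExperimentTable, QPCRPlate
from .model import KineticModel, parse_model

__all__ = [
    "motif_models",
    "smad_demo_models",
    "coupled_pair_model",
    "decay_model",
    "saturating_model",
    "generate_data",
    "synthesize_qpcr_plate",
    "DEFAULT_TIMES",
    "DEFAULT_REPLICATES",
    "DEFAULT_SCALE_FACTOR",
    "PROTEIN_LAG_H",
    "PROTEIN_MAGNITUDE",
]

#: treatment time points (hours)
DEFAULT_TIMES = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0)
#: biological replicates per time point
DEFAULT_REPLICATES = 6
#: scale factor linking model units to arbitrary data units
DEFAULT_SCALE_FACTOR = 100.0
#: protein appears this many hours after the mRNA...
PROTEIN_LAG_H = 0.5
#: ...and at this multiple of its magnitude
PROTEIN_MAGNITUDE = 100.0


_NEGATIVE_FEEDBACK = """
model negative_feedback
  const species S = 1
  species X = 0.1
  species F = 0.1
  param kx = 2.0
  param kdx = 0.6
  param kf = 0.4
  param kdf = 0.3
  param Ki = 1.0
  tx_X: -> X; kx*S/(1 + F/Ki)
  deg_X: X -> ; kdx*X
  tx_F: -> F; kf*X
  deg_F: F -> ; kdf*F
end
"""

_POSITIVE_FEEDBACK = """
model positive_feedback
  const species S = 1
  species X = 0.1
  species F = 0.1
  param kx = 2.0
  param kdx = 0.6
  param kf = 0.4
  param kdf = 0.3
  param kp = 0.1
  tx_X: -> X; kx*S + kp*F
  deg_X: X -> ; kdx*X
  tx_F: -> F; kf*X
  deg_F: F -> ; kdf*F
end
"""

_FEED_FORWARD = """
model feed_forward
  const species S = 1
  species X = 0.1
  species F = 0.1
  param kx = 2.0
  param kdx = 0.6
  param kf = 0.4
  param kdf = 0.3
  tx_X: -> X; kx*S*F
  deg_X: X -> ; kdx*X
  tx_F: -> F; kf*S
  deg_F: F -> ; kdf*F
end
"""


def motif_models() -> tuple[KineticModel, KineticModel, KineticModel]:
    """Negative-feedback, positive-feedback and feed-forward motifs.

    All three share the constant stimulus ``S``, the output ``X`` and
    the internal regulator ``F``, so a single observation map fits each
    of them; they differ only in the regulatory topology.  Under a step
    input the negative-feedback output overshoots and declines; the
    other two respond monotonically.
    """
    return (
        parse_model(_NEGATIVE_FEEDBACK),
        parse_model(_POSITIVE_FEEDBACK),
        parse_model(_FEED_FORWARD),
    )


def _smad_variant(name: str, feedback_consumes: bool, ski_second_order: bool) -> str:
    fb = (
        "fb: D + Smad7 -> ; Feedback_k*D*Smad7"
        if feedback_consumes
        else "fb: D -> ; Feedback_k*D*Smad7"
    )
    ski_deg = (
        "SkiDeg: Ski -> ; SkiDeg_k*Ski**2"
        if ski_second_order
        else "SkiDeg: Ski -> ; SkiDeg_k*Ski"
    )
    return f"""
model {name}
  species D = 1.0
  species Smad7 = 0.1
  species Ski = 0.1
  param Smad7Transcription_V = 2.0
  param Smad7Transcription_km = 0.5
  param Smad7Transcription_I50 = 0.5
  param Smad7Deg_k = 0.8
  param SkiTranscription_k = 0.3
  param SkiDeg_k = 0.2
  param Feedback_k = 0.5
  Smad7Transcription: -> Smad7; Smad7Transcription_V*D/(Smad7Transcription_km + D)*Smad7Transcription_I50/(Smad7Transcription_I50 + Ski)
  Smad7Deg: Smad7 -> ; Smad7Deg_k*Smad7
  SkiTranscription: -> Ski; SkiTranscription_k*D
  {ski_deg}
  {fb}
end
"""


def smad_demo_models() -> tuple[KineticModel, KineticModel, KineticModel]:
    """Three reduced Smad7/Ski negative-feedback variants.

    A driver species ``D`` (the active transcriptional signal) induces
    Smad7 and Ski; Ski inhibits Smad7 transcription through a
    saturating term carrying the ``km`` and ``I50`` parameters; Smad7
    feeds back by degrading the driver.  Variant 1: Smad7 catalyses the
    driver's degradation without being consumed.  Variant 2: Smad7 is
    consumed by the feedback reaction.  Variant 3: as variant 2, with
    second-order mass-action Ski degradation.
    """
    return (
        parse_model(_smad_variant("smad_variant_1", False, False)),
        parse_model(_smad_variant("smad_variant_2", True, False)),
        parse_model(_smad_variant("smad_variant_3", True, True)),
    )


def coupled_pair_model() -> KineticModel:
    """Decay model whose two rate parameters enter only as a product.

    ``A -> 0`` at rate ``k1*k2*A``: any (k1, k2) with the same product
    fits identically, the canonical structural non-identifiability.
    """
    return parse_model(
        """
model coupled_pair
  species A = 10.0
  param k1 = 0.2
  param k2 = 0.5
  deg: A -> ; k1*k2*A
end
"""
    )


def decay_model() -> KineticModel:
    """One-parameter exponential decay (fully identifiable benchmark)."""
    return parse_model(
        """
model decay
  species A = 10.0
  param k = 0.1
  deg: A -> ; k*A
end
"""
    )


def saturating_model() -> KineticModel:
    """Exponential saturation toward a plateau, X' = k (Xmax - X).

    Observed only before saturation, ``Xmax`` and ``k`` trade off almost
    perfectly (the signal is ~ ``Xmax*k*t``), producing a practical
    non-identifiability; observed into the plateau both are
    identifiable.
    """
    return parse_model(
        """
model saturating
  species X = 0.0
  param k = 0.1
  param Xmax = 10.0
  growth: -> X; k*(Xmax - X)
end
"""
    )


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------

def generate_data(
    model: KineticModel,
    times: Sequence[float] = DEFAULT_TIMES,
    observables: Sequence[str] | None = None,
    replicates: int = DEFAULT_REPLICATES,
    noise: str = "gaussian_cv",
    cv: float = 0.1,
    scale_factors: float | Mapping[str, float] = DEFAULT_SCALE_FACTOR,
    protein_rule: tuple[float, float] | None = None,
    noise_on_protein: bool = True,
    parameter_overrides: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> ExperimentTable:
    """Simulate the model and emit a replicated experiment table.

    The simulated truth is mapped into arbitrary units by dividing each
    observable by its scale factor, then replicated with measurement
    noise: ``gaussian_cv`` adds N(0, cv*signal) (clipped at zero with a
    warning count), ``lognormal`` multiplies by exp(N(0, cv)), ``none``
    copies the truth.  With ``protein_rule=(lag_h, magnitude)`` each
    observable ``Obs`` additionally yields a derived ``ObsProtein``
    column equal to ``magnitude * Obs(t - lag)`` (the t=0 level is held
    before the lag has elapsed).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if noise not in ("none", "gaussian_cv", "lognormal"):
        raise ValueError(f"unknown noise model {noise!r}")
    times = np.asarray(sorted(times), dtype=float)
    observables = list(observables) if observables is not None else [
        s for s in model.state_names
    ]
    if isinstance(scale_factors, Mapping):
        sf = {obs: float(scale_factors[obs]) for obs in observables}
    else:
        sf = {obs: float(scale_factors) for obs in observables}

    lag, magnitude = protein_rule if protein_rule is not None else (None, None)
    sim_times = np.unique(
        np.concatenate([times, np.clip(times - lag, times[0], None)])
        if lag is not None
        else times
    )
    sim = model.simulate(sim_times, overrides=dict(parameter_overrides or {}))

    def truth_at(obs: str, at: np.ndarray) -> np.ndarray:
        col = sim[obs]
        idx = np.searchsorted(sim.times, at)
        return col[idx] / sf[obs]

    columns: dict[str, np.ndarray] = {obs: truth_at(obs, times) for obs in observables}
    noisy_flag: dict[str, bool] = {obs: True for obs in observables}
    if lag is not None:
        lagged = np.clip(times - lag, times[0], None)
        for obs in observables:
            columns[f"{obs}Protein"] = magnitude * truth_at(obs, lagged)
            noisy_flag[f"{obs}Protein"] = noise_on_protein

    all_obs = list(columns)
    rng = np.random.default_rng(seed)
    values = np.empty((times.size, replicates, len(all_obs)))
    clipped = 0
    for i, obs in enumerate(all_obs):
        truth = columns[obs][:, None]
        if noise == "none" or not noisy_flag[obs]:
            block = np.tile(truth, (1, replicates))
        elif noise == "gaussian_cv":
            block = truth + rng.normal(0.0, 1.0, (times.size, replicates)) * cv * truth
            neg = block < 0
            clipped += int(neg.sum())
            block = np.where(neg, 0.0, block)
        else:  # lognormal
            block = truth * np.exp(rng.normal(0.0, cv, (times.size, replicates)))
        values[:, :, i] = block
    if clipped:
        warnings.warn(f"clipped {clipped} negative value(s) to 0")

    return ExperimentTable(
        times,
        all_obs,
        values,
        provenance=f"synthetic from model {model.name!r} (noise={noise}, cv={cv})",
    )


def synthesize_qpcr_plate(
    table: ExperimentTable,
    reference_genes: Sequence[str] = ("B2M", "PPIA", "GAPDH", "ACTB"),
    reference_ct: Sequence[float] = (18.0, 19.0, 20.0, 21.0),
    ct_noise: float = 0.0,
    sample_shift_sd: float = 0.0,
    seed: int | None = None,
) -> QPCRPlate:
    """Invert the 2^-ddCt transform to fabricate a raw Ct plate.

    Target Ct values are ``mean(reference Ct) - log2(expression)`` so
    that 2^-ddCt normalization of the plate recovers the expression
    table exactly (when ``ct_noise`` is zero and the table's t=0
    geometric means are one; see
    :meth:`kincal.data.ExperimentTable.normalize_to_baseline`).
    ``sample_shift_sd`` adds a per-sample loading shift common to every
    gene of the sample, which ddCt normalization removes.
    """
    import pandas as pd

    if len(reference_genes) != len(reference_ct):
        raise ValueError("one reference Ct per reference gene required")
    if np.nanmin(table.values) <= 0:
        raise ValueError("expression values must be > 0 to synthesize Ct values")
    rng = np.random.default_rng(seed)
    ref_mean = float(np.mean(reference_ct))
    rows = []
    for ti, t in enumerate(table.times):
        for r in range(table.n_replicates):
            shift = rng.normal(0.0, sample_shift_sd) if sample_shift_sd > 0 else 0.0
            row = {"time": t, "replicate": r + 1}
            for g, g_ct in zip(reference_genes, reference_ct):
                row[g] = g_ct + shift + (
                    rng.normal(0.0, ct_noise) if ct_noise > 0 else 0.0
                )
            for oi, obs in enumerate(table.observables):
                expr = table.values[ti, r, oi]
                row[obs] = ref_mean + shift - np.log2(expr) + (
                    rng.normal(0.0, ct_noise) if ct_noise > 0 else 0.0
                )
            rows.append(row)
    return QPCRPlate(pd.DataFrame(rows), list(reference_genes))
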