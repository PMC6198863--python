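"""Deterministic kinetic reaction-network models.

A :class:`KineticModel` is a set of species (state variables, optionally
fixed/boundary), a map of kinetic parameters and a list of reactions
whose rate laws are algebraic expressions.  The induced ODE system is

.. math:: \\frac{dx_i}{dt} = \\sum_j n_{ij}\\, v_j(x, \\theta)

with stoichiometric coefficients :math:`n_{ij}` and rate laws
:math:`v_j`.  Models can be written in a small Antimony-inspired text
format (see :func:`parse_model`), simulated with a stiff-capable
adaptive integrator, and exported to SBML.

Units: the model lives in a single compartment of size one, so amounts
and concentrations coincide; time is in hours throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._expr import (
    ExpressionError,
    check_identifier,
    expression_symbols,
    make_rate_function,
)

__all__ = [
    "Species",
    "Reaction",
    "KineticModel",
    "TimeCourse",
    "ModelError",
    "ModelSyntaxError",
    "UndeclaredSymbolError",
    "SimulationError",
    "parse_model",
    "build_odes",
    "simulate",
    "set_scaled_initials",
]


class ModelError(ValueError):
    """Invalid model definition."""


class ModelSyntaxError(ModelError):
    """Syntax error in the model text format, carrying the line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class UndeclaredSymbolError(ModelError):
    """A rate expression refers to a symbol that is not declared."""

    def __init__(self, symbol: str, where: str):
        super().__init__(f"undeclared symbol {symbol!r} in {where}")
        self.symbol = symbol


class SimulationError(RuntimeError):
    """Integration failure, reporting the failing time and parameters."""


@dataclass(frozen=True)
class Species:
    """A chemical species; ``fixed`` species are boundary conditions."""

    name: str
    initial_amount: float
    fixed: bool = False

    def __post_init__(self):
        check_identifier(self.name, "species")
        if not np.isfinite(self.initial_amount) or self.initial_amount < 0:
            raise ModelError(
                f"species {self.name!r}: initial amount must be finite and >= 0"
            )


@dataclass(frozen=True)
class Reaction:
    """A reaction with integer stoichiometries and an algebraic rate law.

    ``modifiers`` are species that appear in the rate law without being
    consumed or produced (catalysts, inhibitors).
    """

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_expression: str
    modifiers: tuple[str, ...] = ()

    def __post_init__(self):
        check_identifier(self.name, "reaction")
        for side in (self.reactants, self.products):
            for sp, stoich in side:
                if not (isinstance(stoich, int) and stoich > 0):
                    raise ModelError(
                        f"reaction {self.name!r}: stoichiometry of {sp!r} "
                        f"must be a positive integer, got {stoich!r}"
                    )

    @property
    def symbols(self) -> set[str]:
        return expression_symbols(self.rate_expression)


@dataclass(frozen=True)
class TimeCourse:
    """Trajectories of every species (dynamic and fixed) at given times."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_species)
    labels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (self.times.size, len(self.labels)):
            raise ValueError("TimeCourse shape mismatch")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("TimeCourse times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeCourse values must be finite")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=list(self.labels)).assign(
            time=self.times
        )[["time", *self.labels]]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class _Compiled:
    """Cached ODE machinery for one model structure."""

    def __init__(self, model: "KineticModel"):
        self.state_names = [s.name for s in model.species if not s.fixed]
        self.fixed = {s.name: s.initial_amount for s in model.species if s.fixed}
        self.parameter_names = list(model.parameters)
        index = {n: i for i, n in enumerate(self.state_names)}
        n_state, n_rxn = len(self.state_names), len(model.reactions)
        stoich = np.zeros((n_state, n_rxn))
        for j, rxn in enumerate(model.reactions):
            for sp, k in rxn.reactants:
                if sp in index:
                    stoich[index[sp], j] -= k
            for sp, k in rxn.products:
                if sp in index:
                    stoich[index[sp], j] += k
        self.stoich = stoich
        self.rates = make_rate_function(
            [r.rate_expression for r in model.reactions],
            self.state_names,
            self.fixed,
            self.parameter_names,
        )

    def rhs(self, t: float, y: np.ndarray, p: np.ndarray) -> np.ndarray:
        return self.stoich @ np.asarray(self.rates(t, y, p))


class KineticModel:
    """A named reaction network with species, parameters and reactions."""

    def __init__(
        self,
        name: str,
        species: Sequence[Species],
        parameters: Mapping[str, float],
        reactions: Sequence[Reaction],
    ):
        check_identifier(name, "model")
        self.name = name
        self.species = tuple(species)
        self.parameters = dict(parameters)
        self.reactions = tuple(reactions)
        self._compiled: _Compiled | None = None
        self._validate()

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        sp_names = [s.name for s in self.species]
        if len(set(sp_names)) != len(sp_names):
            raise ModelError("species names must be unique")
        for p in self.parameters:
            check_identifier(p, "parameter")
            if p in sp_names:
                raise ModelError(f"name {p!r} used for both a parameter and a species")
        declared = set(sp_names) | set(self.parameters)
        rxn_names = [r.name for r in self.reactions]
        if len(set(rxn_names)) != len(rxn_names):
            raise ModelError("reaction names must be unique")
        for rxn in self.reactions:
            for sp, _ in (*rxn.reactants, *rxn.products):
                if sp not in sp_names:
                    raise UndeclaredSymbolError(sp, f"reaction {rxn.name!r}")
            for sym in rxn.symbols:
                if sym not in declared:
                    raise UndeclaredSymbolError(
                        sym, f"rate expression of reaction {rxn.name!r}"
                    )
            for mod in rxn.modifiers:
                if mod not in sp_names:
                    raise UndeclaredSymbolError(mod, f"modifiers of {rxn.name!r}")

    # -- basic introspection ------------------------------------------
    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species if not s.fixed)

    @property
    def initial_amounts(self) -> dict[str, float]:
        return {s.name: s.initial_amount for s in self.species}

    def species_by_name(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    # -- copies with modifications ------------------------------------
    def with_parameters(self, updates: Mapping[str, float]) -> "KineticModel":
        unknown = set(updates) - set(self.parameters)
        if unknown:
            raise ModelError(f"unknown parameters: {sorted(unknown)}")
        params = {**self.parameters, **updates}
        out = KineticModel(self.name, self.species, params, self.reactions)
        out._compiled = self._compiled  # structure unchanged
        return out

    def with_initial_amounts(self, updates: Mapping[str, float]) -> "KineticModel":
        names = set(self.species_names)
        unknown = set(updates) - names
        if unknown:
            raise ModelError(f"unknown species: {sorted(unknown)}")
        species = tuple(
            replace(s, initial_amount=float(updates[s.name]))
            if s.name in updates
            else s
            for s in self.species
        )
        return KineticModel(self.name, species, self.parameters, self.reactions)

    def copy(self) -> "KineticModel":
        out = KineticModel(self.name, self.species, self.parameters, self.reactions)
        out._compiled = self._compiled
        return out

    # -- equality (structural) -----------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, KineticModel):
            return NotImplemented
        return (
            self.name == other.name
            and self.species == other.species
            and self.parameters == other.parameters
            and self.reactions == other.reactions
        )

    def __repr__(self) -> str:
        return (
            f"<KineticModel {self.name!r}: {len(self.species)} species, "
            f"{len(self.parameters)} parameters, {len(self.reactions)} reactions>"
        )

    # -- ODE machinery -------------------------------------------------
    def compiled(self) -> _Compiled:
        if self._compiled is None:
            self._compiled = _Compiled(self)
        return self._compiled

    def simulate(
        self,
        times: Sequence[float],
        overrides: Mapping[str, float] | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
        method: str = "LSODA",
    ) -> TimeCourse:
        return simulate(self, times, overrides, rtol=rtol, atol=atol, method=method)

    # -- serialization -------------------------------------------------
    def to_text(self) -> str:
        lines = [f"model {self.name}"]
        for s in self.species:
            prefix = "const species" if s.fixed else "species"
            lines.append(f"  {prefix} {s.name} = {s.initial_amount!r}")
        for p, v in self.parameters.items():
            lines.append(f"  param {p} = {v!r}")
        for r in self.reactions:
            lhs = " + ".join(_term(sp, k) for sp, k in r.reactants)
            rhs = " + ".join(_term(sp, k) for sp, k in r.products)
            lines.append(f"  {r.name}: {lhs} -> {rhs}; {r.rate_expression}")
        lines.append("end")
        return "\n".join(lines) + "\n"

    def to_sbml(self, path=None) -> str:
        from .sbml import write_sbml

        return write_sbml(self, path)


def _term(sp: str, k: int) -> str:
    return sp if k == 1 else f"{k} {sp}"


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------

_DECL_RE = re.compile(
    r"^(?P<const>const\s+)?(?P<kind>species|param(?:eter)?)\s+"
    r"(?P<name>[A-Za-z_]\w*)\s*=\s*(?P<value>\S+)$"
)
_CONST_SHORT_RE = re.compile(r"^const\s+(?P<name>[A-Za-z_]\w*)\s*=\s*(?P<value>\S+)$")
_RXN_RE = re.compile(
    r"^(?:(?P<name>[A-Za-z_]\w*)\s*:)?\s*(?P<lhs>[^->;]*)->(?P<rhs>[^;]*);(?P<rate>.+)$"
)
_SIDE_TERM_RE = re.compile(r"^(?:(?P<stoich>\d+)\s*)?(?P<name>[A-Za-z_]\w*)$")


def _parse_side(text: str, lineno: int) -> tuple[tuple[str, int], ...]:
    text = text.strip()
    if not text:
        return ()
    out = []
    for term in text.split("+"):
        m = _SIDE_TERM_RE.match(term.strip())
        if m is None:
            raise ModelSyntaxError(f"cannot parse reaction term {term.strip()!r}", lineno)
        out.append((m.group("name"), int(m.group("stoich") or 1)))
    return tuple(out)


def parse_model(text: str, name: str = "model") -> KineticModel:
    """Parse the plain-text model format into a :class:`KineticModel`.

    The format is line based::

        model decay
          species A = 10
          species B = 0
          const species S = 1       // fixed (boundary) species
          param k1 = 0.1
          r1: A -> B; k1*A
        end

    Reaction names are optional; an anonymous reaction ``A -> B; k1*A``
    is named ``r<index>``.  ``#`` and ``//`` start comments.  Species
    appearing in a rate law but not among the reactants/products are
    recorded as modifiers of that reaction.
    """
    species: list[Species] = []
    parameters: dict[str, float] = {}
    raw_reactions: list[tuple[int, str | None, str, str, str]] = []
    model_name = name
    seen: set[str] = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = re.split(r"//|#", raw, maxsplit=1)[0].strip()
        if not line or line == "end":
            continue
        if line.startswith("model "):
            model_name = line.split(None, 1)[1].strip()
            continue
        m = _DECL_RE.match(line) or _CONST_SHORT_RE.match(line)
        if m is not None:
            nm = m.group("name")
            if nm in seen:
                raise ModelSyntaxError(f"duplicate declaration of {nm!r}", lineno)
            seen.add(nm)
            try:
                value = float(m.group("value"))
            except ValueError:
                raise ModelSyntaxError(
                    f"cannot parse numeric value {m.group('value')!r}", lineno
                ) from None
            kind = m.groupdict().get("kind") or "species"
            fixed = bool(m.groupdict().get("const"))
            try:
                if kind.startswith("param"):
                    check_identifier(nm, "parameter")
                    parameters[nm] = value
                else:
                    species.append(Species(nm, value, fixed=fixed))
            except (ExpressionError, ModelError) as exc:
                raise ModelSyntaxError(str(exc), lineno) from None
            continue
        m = _RXN_RE.match(line)
        if m is not None:
            raw_reactions.append(
                (lineno, m.group("name"), m.group("lhs"), m.group("rhs"), m.group("rate"))
            )
            continue
        raise ModelSyntaxError(f"cannot parse line {line!r}", lineno)

    sp_names = {s.name for s in species}
    reactions: list[Reaction] = []
    for i, (lineno, rname, lhs, rhs, rate) in enumerate(raw_reactions, start=1):
        rname = rname or f"r{i}"
        reactants = _parse_side(lhs, lineno)
        products = _parse_side(rhs, lineno)
        rate = rate.strip()
        try:
            symbols = expression_symbols(rate)
        except ExpressionError as exc:
            raise ModelSyntaxError(str(exc), lineno) from None
        participants = {sp for sp, _ in (*reactants, *products)}
        modifiers = tuple(sorted(symbols & sp_names - participants))
        try:
            reactions.append(Reaction(rname, reactants, products, rate, modifiers))
        except ModelError as exc:
            raise ModelSyntaxError(str(exc), lineno) from None

    return KineticModel(model_name, species, parameters, reactions)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_odes(model: KineticModel) -> Callable:
    """Return ``f(t, state, parameters) -> derivatives`` for the model.

    ``state`` is ordered as ``model.state_names`` (fixed species are held
    constant and excluded); ``parameters`` may be a mapping or a vector
    ordered as ``model.parameters``.
    """
    compiled = model.compiled()
    order = compiled.parameter_names

    def f(t, state, parameters):
        if isinstance(parameters, Mapping):
            p = np.array([parameters[n] for n in order], dtype=float)
        else:
            p = np.asarray(parameters, dtype=float)
        return compiled.rhs(t, np.asarray(state, dtype=float), p)

    f.state_names = tuple(compiled.state_names)
    f.parameter_names = tuple(order)
    return f


def simulate(
    model: KineticModel,
    times: Sequence[float],
    overrides: Mapping[str, float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> TimeCourse:
    """Integrate the model ODEs and evaluate at the requested times.

    ``overrides`` may rename existing parameters or species initial
    amounts; the model itself is never mutated.  Fixed species are
    reported as constant columns so the output has one column per
    species (dynamic first, fixed last — the declaration order).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")

    compiled = model.compiled()
    params = dict(model.parameters)
    initials = model.initial_amounts
    fixed = dict(compiled.fixed)
    if overrides:
        for key, value in overrides.items():
            if key in params:
                params[key] = float(value)
            elif key in initials:
                initials[key] = float(value)
                if key in fixed:
                    fixed[key] = float(value)
            else:
                raise ModelError(f"override target {key!r} is neither parameter nor species")

    p = np.array([params[n] for n in compiled.parameter_names], dtype=float)
    y0 = np.array([initials[n] for n in compiled.state_names], dtype=float)

    if fixed != compiled.fixed:
        # fixed-species override requires re-binding the baked-in constants
        rates = make_rate_function(
            [r.rate_expression for r in model.reactions],
            compiled.state_names,
            fixed,
            compiled.parameter_names,
        )
        stoich = compiled.stoich

        def rhs(t, y):
            return stoich @ np.asarray(rates(t, y, p))
    else:
        def rhs(t, y):
            return compiled.rhs(t, y, p)

    # abort quickly on diverging trajectories (e.g. finite-time blow-up)
    # instead of letting the integrator grind its step size to nothing
    cap = max(1e12, 1e9 * max(np.max(np.abs(y0)), 1.0))

    class _Diverged(Exception):
        pass

    def guarded(t, y):
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > cap:
            raise _Diverged(t)
        try:
            return rhs(t, y)
        except OverflowError:
            raise _Diverged(t) from None

    if times.size == 1 or times[-1] == times[0]:
        states = np.tile(y0, (times.size, 1))
    else:
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                sol = solve_ivp(
                    guarded,
                    (times[0], times[-1]),
                    y0,
                    method=method,
                    t_eval=times,
                    rtol=rtol,
                    atol=atol,
                )
        except _Diverged as exc:
            raise SimulationError(
                f"integration of model {model.name!r} diverged near "
                f"t={exc.args[0]:g} with parameters {params}"
            ) from None
        if not sol.success:
            t_fail = sol.t[-1] if sol.t.size else times[0]
            raise SimulationError(
                f"integration of model {model.name!r} failed near t={t_fail:g} "
                f"with parameters {params}"
            )
        states = sol.y.T

    labels = tuple(compiled.state_names) + tuple(fixed)
    fixed_block = np.tile(np.array(list(fixed.values())), (times.size, 1))
    values = (
        np.hstack([states, fixed_block]) if fixed else states
    )
    return TimeCourse(times, values, labels)


def set_scaled_initials(
    model: KineticModel,
    data_means_at_t0: Mapping[str, float],
    observation_map,
) -> KineticModel:
    """Scale empirical baseline means into model initial amounts.

    For each observable the mapped species' initial amount becomes
    ``mean_at_t0 * scale_factor``, linking arbitrary data units to model
    units.  ``observation_map`` is any mapping observable →
    ``(species, scale_factor)`` (e.g. :class:`kincal.data.ObservationMap`).
    """
    entries = getattr(observation_map, "mapping", observation_map)
    updates: dict[str, float] = {}
    for obs, mean in data_means_at_t0.items():
        if obs not in entries:
            raise ModelError(f"observable {obs!r} has no entry in the observation map")
        species, sf = entries[obs]
        if sf <= 0:
            raise ModelError(f"scale factor for {obs!r} must be > 0")
        updates[species] = float(mean) * float(sf)
    return model.with_initial_amounts(updates)
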