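"""SBML Level 3 Version 1 export of kinetic models via libsbml.

Only the constructs the model format supports are emitted: one
compartment of size 1, species with initial amounts (fixed species
become boundary-condition constants), global parameters and reactions
with kinetic laws.
"""

from __future__ import annotations

import libsbml

from .model import KineticModel, ModelError

__all__ = ["write_sbml", "read_sbml_summary"]


def _check(status, what: str) -> None:
    if status not in (None, libsbml.LIBSBML_OPERATION_SUCCESS):
        raise ModelError(f"SBML export failed while setting {what} (status {status})")


def write_sbml(model: KineticModel, path=None) -> str:
    """Serialize ``model`` to an SBML L3V1 document string (and file)."""
    document = libsbml.SBMLDocument(3, 1)
    sbml_model = document.createModel()
    _check(sbml_model.setId(model.name), "model id")
    hour = sbml_model.createUnitDefinition()
    _check(hour.setId("hour"), "unit definition id")
    unit = hour.createUnit()
    _check(unit.setKind(libsbml.UNIT_KIND_SECOND), "unit kind")
    _check(unit.setMultiplier(3600.0), "unit multiplier")
    _check(unit.setScale(0), "unit scale")
    _check(unit.setExponent(1), "unit exponent")
    _check(sbml_model.setTimeUnits("hour"), "time units")

    comp = sbml_model.createCompartment()
    _check(comp.setId("cell"), "compartment id")
    _check(comp.setSize(1.0), "compartment size")
    _check(comp.setConstant(True), "compartment constant")
    _check(comp.setSpatialDimensions(3), "compartment dimensions")

    for sp in model.species:
        s = sbml_model.createSpecies()
        _check(s.setId(sp.name), "species id")
        _check(s.setCompartment("cell"), "species compartment")
        _check(s.setInitialAmount(float(sp.initial_amount)), "initial amount")
        _check(s.setBoundaryCondition(sp.fixed), "boundary condition")
        _check(s.setConstant(bool(sp.fixed)), "species constant")
        _check(s.setHasOnlySubstanceUnits(True), "substance units flag")

    for name, value in model.parameters.items():
        p = sbml_model.createParameter()
        _check(p.setId(name), "parameter id")
        _check(p.setValue(float(value)), "parameter value")
        _check(p.setConstant(True), "parameter constant")

    for rxn in model.reactions:
        r = sbml_model.createReaction()
        _check(r.setId(rxn.name), "reaction id")
        _check(r.setReversible(False), "reversible flag")
        _check(r.setFast(False), "fast flag")
        for sp, stoich in rxn.reactants:
            ref = r.createReactant()
            _check(ref.setSpecies(sp), "reactant species")
            _check(ref.setStoichiometry(float(stoich)), "reactant stoichiometry")
            _check(ref.setConstant(True), "reactant constant")
        for sp, stoich in rxn.products:
            ref = r.createProduct()
            _check(ref.setSpecies(sp), "product species")
            _check(ref.setStoichiometry(float(stoich)), "product stoichiometry")
            _check(ref.setConstant(True), "product constant")
        for sp in rxn.modifiers:
            ref = r.createModifier()
            _check(ref.setSpecies(sp), "modifier species")
        law = r.createKineticLaw()
        # L3 formula syntax writes powers as ^, not Python's **
        math_ast = libsbml.parseL3Formula(rxn.rate_expression.replace("**", "^"))
        if math_ast is None:
            raise ModelError(
                f"rate expression of {rxn.name!r} is not expressible in SBML: "
                f"{rxn.rate_expression!r}"
            )
        _check(law.setMath(math_ast), "kinetic law")

    text = libsbml.writeSBMLToString(document)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_sbml_summary(text_or_path: str) -> dict:
    """Read an SBML document and summarize species/parameters/reactions.

    A light-weight convenience for round-trip checks; full SBML import
    is intentionally out of scope.
    """
    if "<sbml" in text_or_path:
        document = libsbml.readSBMLFromString(text_or_path)
    else:
        document = libsbml.readSBMLFromFile(text_or_path)
    if document.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ModelError("SBML document has read errors")
    m = document.getModel()
    return {
        "id": m.getId(),
        "species": {
            m.getSpecies(i).getId(): m.getSpecies(i).getInitialAmount()
            for i in range(m.getNumSpecies())
        },
        "parameters": {
            m.getParameter(i).getId(): m.getParameter(i).getValue()
            for i in range(m.getNumParameters())
        },
        "n_reactions": m.getNumReactions(),
    }
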