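"""SBML Level 3 (core, version 1) export and re-import of the network.

The exported document carries the 7 species with their initial amounts, the
11 rate constants (plus the Hill constant S when used), and the 14
reactions with kinetic laws written in the same form the simulators
evaluate: mass action for first-order steps, the combinatorial
k3*X*(X-1)/2 for homodimerisation, o1*tetO*TetR2 for operator binding, and
for transcription either the switch gate (a piecewise on operator
occupancy, the S == 0 limit) or the literal Hill term k1*tetO/(S+tetO).
"""

from __future__ import annotations

import re

import libsbml

from .network import (
    BIMOLECULAR,
    DIMERISATION,
    FIRST_ORDER,
    GATED_SOURCE,
    RATE_SYMBOLS,
    SPECIES,
    Reaction,
    ReactionNetwork,
    RateParameters,
    SpeciesState,
)


class SBMLError(RuntimeError):
    """libsbml reported a failure while building or reading a document."""


def _check(value, message):
    if value is None:
        raise SBMLError(f"{message}: libsbml returned None")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise SBMLError(f"{message}: {libsbml.OperationReturnValue_toString(value)}")
    return value


def _kinetic_formula(rxn: Reaction, S: float) -> str:
    r = rxn.rate_symbol
    if rxn.kind == GATED_SOURCE:
        if S > 0:
            return f"{r} * tetO / (S + tetO)"
        return f"piecewise({r}, geq(tetO, 1), 0)"
    if rxn.kind == FIRST_ORDER:
        (sp,) = rxn.reactants.keys()
        return f"{r} * {sp}"
    if rxn.kind == DIMERISATION:
        (sp,) = rxn.reactants.keys()
        return f"{r} * {sp} * ({sp} - 1) / 2"
    a, b = rxn.reactants.keys()
    return f"{r} * {a} * {b}"


def export_sbml(network: ReactionNetwork, params: RateParameters,
                init: SpeciesState, model_id: str = "goodwin_tetR_tetO") -> str:
    """Serialise network + rates + initial amounts to an SBML L3V1 string."""
    doc = libsbml.SBMLDocument(3, 1)
    model = _check(doc.createModel(), "create model")
    model.setId(model_id)
    model.setTimeUnits("second")  # nominal; all rates are per minute by convention

    comp = _check(model.createCompartment(), "create compartment")
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    comp.setSpatialDimensions(3)

    init_arr = init.as_array()
    for i, name in enumerate(SPECIES):
        sp = _check(model.createSpecies(), f"create species {name}")
        sp.setId(name)
        sp.setCompartment("cell")
        sp.setInitialAmount(float(init_arr[i]))
        sp.setHasOnlySubstanceUnits(True)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    for sym in RATE_SYMBOLS:
        p = _check(model.createParameter(), f"create parameter {sym}")
        p.setId(sym)
        p.setValue(getattr(params, sym))
        p.setConstant(True)
    if params.S > 0:
        p = _check(model.createParameter(), "create parameter S")
        p.setId("S")
        p.setValue(params.S)
        p.setConstant(True)

    for rxn in network.reactions:
        r = _check(model.createReaction(), f"create reaction {rxn.rid}")
        r.setId(rxn.rid)
        r.setReversible(False)
        r.setFast(False)
        for sp, n in rxn.reactants.items():
            ref = _check(r.createReactant(), f"{rxn.rid} reactant {sp}")
            ref.setSpecies(sp)
            ref.setStoichiometry(float(n))
            ref.setConstant(True)
        for sp, n in rxn.products.items():
            ref = _check(r.createProduct(), f"{rxn.rid} product {sp}")
            ref.setSpecies(sp)
            ref.setStoichiometry(float(n))
            ref.setConstant(True)
        if rxn.kind == GATED_SOURCE:
            mod = _check(r.createModifier(), f"{rxn.rid} modifier tetO")
            mod.setSpecies("tetO")
        kl = _check(r.createKineticLaw(), f"{rxn.rid} kinetic law")
        math = libsbml.parseL3Formula(_kinetic_formula(rxn, params.S))
        _check(math, f"{rxn.rid} formula parse")
        kl.setMath(math)

    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:  # pragma: no cover
        raise SBMLError(doc.getErrorLog().toString())
    return libsbml.writeSBMLToString(doc)


def _rate_symbol_of(formula: str) -> str:
    tokens = set(re.findall(r"[A-Za-z_]\w*", formula))
    hits = [sym for sym in RATE_SYMBOLS if sym in tokens]
    if len(hits) != 1:
        raise SBMLError(f"cannot identify a unique rate symbol in {formula!r}")
    return hits[0]


def parse_sbml(text: str):
    """Rebuild (network, params, init) from an exported document.

    The propensity kind of each reaction is recovered from its reactant
    pattern (no reactants -> gated source; a single reactant with
    stoichiometry 2 -> homodimerisation; two distinct reactants ->
    bimolecular; else first order), and the rate symbol from the unique
    rate constant appearing in the kinetic-law formula.
    """
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise SBMLError(doc.getErrorLog().toString())
    model = doc.getModel()
    if model is None:
        raise SBMLError("document has no model")

    init_counts = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        init_counts[sp.getId()] = int(round(sp.getInitialAmount()))
    missing = set(SPECIES) - set(init_counts)
    if missing:
        raise SBMLError(f"missing species {sorted(missing)}")
    init = SpeciesState(**{s: init_counts[s] for s in SPECIES})

    values = {}
    for i in range(model.getNumParameters()):
        p = model.getParameter(i)
        values[p.getId()] = p.getValue()
    params = RateParameters(
        **{sym: values[sym] for sym in RATE_SYMBOLS}, S=values.get("S", 0.0)
    )

    reactions = []
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        reactants = {
            r.getReactant(j).getSpecies(): int(round(r.getReactant(j).getStoichiometry()))
            for j in range(r.getNumReactants())
        }
        products = {
            r.getProduct(j).getSpecies(): int(round(r.getProduct(j).getStoichiometry()))
            for j in range(r.getNumProducts())
        }
        formula = libsbml.formulaToL3String(r.getKineticLaw().getMath())
        if not reactants:
            kind = GATED_SOURCE
        elif len(reactants) == 1 and next(iter(reactants.values())) == 2:
            kind = DIMERISATION
        elif len(reactants) == 2:
            kind = BIMOLECULAR
        else:
            kind = FIRST_ORDER
        reactions.append(
            Reaction(r.getId(), reactants, products, kind, _rate_symbol_of(formula))
        )
    return ReactionNetwork(tuple(reactions)), params, init


def kinetic_law_formula(text: str, rid: str) -> str:
    """Infix formula of one reaction's kinetic law (for independent checks)."""
    doc = libsbml.readSBMLFromString(text)
    rxn = doc.getModel().getReaction(rid)
    if rxn is None:
        raise SBMLError(f"no reaction {rid!r}")
    return libsbml.formulaToL3String(rxn.getKineticLaw().getMath())
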