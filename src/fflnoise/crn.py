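"""Compile a catalog entry into a concrete mass-action reaction network.

Every protein node of a motif is a conserved pool of ``total`` molecules
switching between an inactive and an active form (one-step scheme) or
through an additional intermediate form (two-step scheme, the mass-action
stand-in for multisite modification / Goldbeter-Koshland kinetics).

Regulation is catalytic: an active regulator accelerates the conversion of
its target without being consumed.  Activators catalyze the forward
(activating) conversion, inhibitors the reverse one.  Regulator activities
are normalized — by the pool total for protein regulators and by a reference
input level for S — so that regulated and basal rates stay comparable and no
pool saturates across the input staircase.  At an OR gate regulators act
through independent reactions (additive propensities); at an AND gate a
single reaction carries the product of the normalized activities, attenuated
by ``and_factor`` per extra regulator (the "halving" convention).

Propensities are monomials ``c * prod(x_s)`` over the reaction's reactant
and catalyst copy numbers, which is what the LNA, SSA and CME engines all
consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Literal, Sequence

import numpy as np

from .catalog import CatalogEntry, GateType, Sign, get_entry
from .input_signal import InputMechanism, calibrate_input

Scheme = Literal["one-step", "two-step"]

#: Layer of each node name prefix, mapping to its basal rate constant.
_NODE_LAYER = {"X": "X", "X1": "X", "X2": "X", "Y": "Y", "Y1": "Y", "Y2": "Y", "Z": "Z"}


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic constants shared by every model in a comparison.

    k1, k2, k3
        Basal (regulator-independent) activation rate constants of the X, Y
        and Z layers, per time.
    kp, kpp
        Catalytic rate constants of the first and second regulated
        modification step, per time and per unit of normalized regulator
        activity.  ``kpp`` only enters the two-step scheme.
    ka
        Constitutive inactivation rate constant, everywhere.
    total
        Conserved molecule count of every protein pool (arbitrary units).
    and_factor
        Attenuation per extra regulator joined through an AND gate.
    s_ref
        Normalization scale for the input S: the regulated rate seen by X is
        ``kp * S / s_ref``.
    """

    k1: float = 1.0
    k2: float = 1.0
    k3: float = 1.0
    kp: float = 10.0
    kpp: float = 40.0
    ka: float = 5.0
    total: float = 60.0
    and_factor: float = 0.5
    s_ref: float = 6.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "kp", "kpp", "ka", "total", "and_factor", "s_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")

    def layer_rate(self, layer: str) -> float:
        return {"X": self.k1, "Y": self.k2, "Z": self.k3}[layer]


@dataclass(frozen=True)
class SpeciesDef:
    """A chemical species: the input, or one form of a protein node."""

    name: str
    layer: str  # "input", "X", "Y" or "Z"
    form: str  # "free", "inactive", "intermediate" or "active"
    node: str = ""  # protein node this form belongs to ("" for the input)


@dataclass(frozen=True)
class Reaction:
    """One mass-action channel.

    ``reactants``/``products`` carry the net state change; ``modifiers`` are
    catalysts that enter the propensity but are not consumed.  The
    propensity at state x is ``rate * prod(x[s] for s in reactants + modifiers)``.
    """

    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    modifiers: tuple[str, ...]
    rate: float

    @property
    def monomial(self) -> tuple[str, ...]:
        return self.reactants + self.modifiers


@dataclass(frozen=True)
class CRNModel:
    """A compiled reaction network, ready for the moment and jump engines."""

    model_id: str
    scheme: Scheme
    species: tuple[SpeciesDef, ...]
    reactions: tuple[Reaction, ...]
    params: ParameterSet
    input_mech: InputMechanism
    birth_reaction: str = "S_birth"

    # -- structural views ---------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def protein_nodes(self) -> list[str]:
        seen: list[str] = []
        for s in self.species:
            if s.node and s.node not in seen:
                seen.append(s.node)
        return seen

    def node_forms(self, node: str) -> list[str]:
        return [s.name for s in self.species if s.node == node]

    def active_name(self, node: str) -> str:
        return f"{node}_a"

    @property
    def birth_index(self) -> int:
        return [r.name for r in self.reactions].index(self.birth_reaction)

    def rate_vector(self, basal_rate: float | None = None) -> np.ndarray:
        """Reaction rate constants; optionally override the input birth rate
        (the plateau-dependent knob of the staircase protocol)."""
        rates = np.array([r.rate for r in self.reactions], dtype=float)
        if basal_rate is not None:
            rates[self.birth_index] = basal_rate
        return rates

    def default_initial_state(self, s0: float | None = None) -> np.ndarray:
        """All pools fully inactive; S at its mechanism's stationary mean."""
        x = np.zeros(self.n_species)
        x[self.species_index("S")] = self.input_mech.stationary_mean if s0 is None else s0
        for node in self.protein_nodes:
            x[self.species_index(f"{node}_i")] = self.params.total
        return x


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


def build_model(
    entry: CatalogEntry | str,
    scheme: Scheme = "one-step",
    params: ParameterSet | None = None,
    input_mech: InputMechanism | None = None,
) -> CRNModel:
    """Compile a catalog entry (or its model id) into a :class:`CRNModel`.

    The input submodel (basal + autocatalytic production, first-order decay)
    is attached to every compiled network; its basal rate is the knob the
    staircase protocol drives.
    """
    if isinstance(entry, str):
        entry = get_entry(entry)
    if scheme not in ("one-step", "two-step"):
        raise ValueError(f"unknown scheme {scheme!r}")
    params = params or ParameterSet()
    mech = input_mech or calibrate_input()
    topo = entry.topology

    species: list[SpeciesDef] = [SpeciesDef("S", "input", "free")]
    for node in topo.nodes:
        if node == "S":
            continue
        layer = _NODE_LAYER[node]
        species.append(SpeciesDef(f"{node}_i", layer, "inactive", node))
        if scheme == "two-step":
            species.append(SpeciesDef(f"{node}_m", layer, "intermediate", node))
        species.append(SpeciesDef(f"{node}_a", layer, "active", node))

    reactions: list[Reaction] = [
        Reaction("S_birth", (), ("S",), (), mech.basal_rate),
        Reaction("S_auto", ("S",), ("S", "S"), (), mech.autocatalytic_rate),
        Reaction("S_decay", ("S",), (), (), mech.decay_rate),
    ]

    for node in topo.nodes:
        if node == "S":
            continue
        layer = _NODE_LAYER[node]
        regulators = topo.regulators_of(node)
        gate = entry.gates.get(node, "OR")
        reactions.extend(
            _node_reactions(node, layer, regulators, gate, scheme, params)
        )

    return CRNModel(
        model_id=entry.model_id,
        scheme=scheme,
        species=tuple(species),
        reactions=tuple(reactions),
        params=params,
        input_mech=mech,
    )


def _regulator_activity(reg: str, params: ParameterSet) -> tuple[str, float]:
    """(species carrying the regulator's activity, its normalization)."""
    if reg == "S":
        return "S", params.s_ref
    return f"{reg}_a", params.total


def _node_reactions(
    node: str,
    layer: str,
    regulators: Sequence[tuple[str, Sign]],
    gate: GateType,
    scheme: Scheme,
    p: ParameterSet,
) -> list[Reaction]:
    k = p.layer_rate(layer)
    inact, act = f"{node}_i", f"{node}_a"
    interm = f"{node}_m"
    rxns: list[Reaction] = []

    # Forward/backward conversion steps of this node, as (source, sink, basal
    # forward constant) per step.  The regulated constant is kp on the first
    # step and kpp on the second.
    if scheme == "one-step":
        fwd_steps = [(inact, act, k, p.kp)]
        rev_steps = [(act, inact, p.ka, p.kp)]
    else:
        fwd_steps = [(inact, interm, k, p.kp), (interm, act, k, p.kpp)]
        rev_steps = [(act, interm, p.ka, p.kp), (interm, inact, p.ka, p.kpp)]

    for i, (src, dst, basal, _) in enumerate(fwd_steps):
        rxns.append(Reaction(f"{node}_act{i}", (src,), (dst,), (), basal))
    for i, (src, dst, basal, _) in enumerate(rev_steps):
        rxns.append(Reaction(f"{node}_deact{i}", (src,), (dst,), (), basal))

    activators = [r for r, s in regulators if s == "+"]
    inhibitors = [r for r, s in regulators if s == "-"]

    for signed, steps in ((activators, fwd_steps), (inhibitors, rev_steps)):
        if not signed:
            continue
        use_and = gate == "AND" and len(regulators) >= 2
        if use_and:
            # AND: all same-sign regulators join one channel per step, with
            # the product of normalized activities attenuated per extra input.
            carriers, norm = [], 1.0
            for reg in signed:
                c, w = _regulator_activity(reg, p)
                carriers.append(c)
                norm *= w
            atten = p.and_factor ** (len(signed) - 1)
            for i, (src, dst, _, kcat) in enumerate(steps):
                rxns.append(
                    Reaction(
                        f"{node}_{'act' if steps is fwd_steps else 'deact'}{i}_AND",
                        (src,),
                        (dst,),
                        tuple(carriers),
                        atten * kcat / norm,
                    )
                )
        else:
            for reg in signed:
                c, w = _regulator_activity(reg, p)
                for i, (src, dst, _, kcat) in enumerate(steps):
                    rxns.append(
                        Reaction(
                            f"{node}_{'act' if steps is fwd_steps else 'deact'}{i}_by_{reg}",
                            (src,),
                            (dst,),
                            (c,),
                            kcat / w,
                        )
                    )
    return rxns


# ---------------------------------------------------------------------------
# structure: stoichiometry, propensities, conservation
# ---------------------------------------------------------------------------


def stoichiometry(crn: CRNModel) -> np.ndarray:
    """Net-change matrix (species x reactions), integer valued."""
    S = np.zeros((crn.n_species, crn.n_reactions), dtype=np.int64)
    idx = {name: i for i, name in enumerate(crn.species_names)}
    for j, rxn in enumerate(crn.reactions):
        for r in rxn.reactants:
            S[idx[r], j] -= 1
        for pr in rxn.products:
            S[idx[pr], j] += 1
    return S


def monomial_matrix(crn: CRNModel) -> np.ndarray:
    """Exponent matrix E (reactions x species): propensity_j = rate_j * prod_s x_s^E[j,s]."""
    E = np.zeros((crn.n_reactions, crn.n_species), dtype=np.int64)
    idx = {name: i for i, name in enumerate(crn.species_names)}
    for j, rxn in enumerate(crn.reactions):
        for s in rxn.monomial:
            E[j, idx[s]] += 1
    if (E > 1).any():  # pragma: no cover - no such reaction is ever built
        raise RuntimeError("propensity monomials are expected to be multilinear")
    return E


def propensities(
    crn: CRNModel, state: np.ndarray, rates: np.ndarray | None = None
) -> np.ndarray:
    """Mass-action propensity of every reaction at an (integer or real) state."""
    x = np.asarray(state, dtype=float)
    if x.shape != (crn.n_species,):
        raise ValueError("state length must match the number of species")
    if (x < 0).any():
        raise ValueError("negative copy numbers")
    if rates is None:
        rates = crn.rate_vector()
    E = monomial_matrix(crn)
    a = rates.copy()
    for j in range(crn.n_reactions):
        for i in np.nonzero(E[j])[0]:
            a[j] *= x[i]
    return a


def conservation_laws(crn: CRNModel) -> list[tuple[tuple[str, ...], float]]:
    """One conserved pool per protein node: its forms sum to ``total``.

    The returned indicator vectors are verified to annihilate the
    stoichiometry matrix exactly; the input S is never conserved.
    """
    S = stoichiometry(crn)
    idx = {name: i for i, name in enumerate(crn.species_names)}
    laws = []
    for node in crn.protein_nodes:
        forms = tuple(crn.node_forms(node))
        v = np.zeros(crn.n_species)
        v[[idx[f] for f in forms]] = 1.0
        if not np.all(v @ S == 0):  # pragma: no cover - structural guarantee
            raise RuntimeError(f"pool of node {node} is not conserved")
        laws.append((forms, crn.params.total))
    return laws


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def export_model(crn: CRNModel, format: str = "json") -> str:
    """Serialize a model to round-trippable JSON or to SBML Level 3."""
    if format == "json":
        doc = {
            "model_id": crn.model_id,
            "scheme": crn.scheme,
            "params": asdict(crn.params),
            "input_mech": asdict(crn.input_mech),
            "species": [asdict(s) for s in crn.species],
            "reactions": [
                {
                    "name": r.name,
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "modifiers": list(r.modifiers),
                    "rate": r.rate,
                }
                for r in crn.reactions
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)
    if format == "sbml":
        return _to_sbml(crn)
    raise ValueError(f"unknown export format {format!r}")


def import_model(doc: str) -> CRNModel:
    """Inverse of :func:`export_model` for the JSON format."""
    d = json.loads(doc)
    return CRNModel(
        model_id=d["model_id"],
        scheme=d["scheme"],
        species=tuple(SpeciesDef(**s) for s in d["species"]),
        reactions=tuple(
            Reaction(
                r["name"],
                tuple(r["reactants"]),
                tuple(r["products"]),
                tuple(r["modifiers"]),
                r["rate"],
            )
            for r in d["reactions"]
        ),
        params=ParameterSet(**d["params"]),
        input_mech=InputMechanism(**d["input_mech"]),
    )


def _to_sbml(crn: CRNModel) -> str:
    """Minimal SBML L3V2 document with mass-action kinetic laws."""
    from lxml import etree

    ns = "http://www.sbml.org/sbml/level3/version2/core"
    sbml = etree.Element("sbml", nsmap={None: ns}, level="3", version="2")
    model = etree.SubElement(sbml, "model", id=crn.model_id.replace("-", "_"))
    comps = etree.SubElement(model, "listOfCompartments")
    etree.SubElement(
        comps, "compartment", id="cell", size="1", constant="true", spatialDimensions="3"
    )
    sp_list = etree.SubElement(model, "listOfSpecies")
    for s in crn.species:
        init = crn.params.total if s.form == "inactive" else (
            crn.input_mech.stationary_mean if s.name == "S" else 0.0
        )
        etree.SubElement(
            sp_list,
            "species",
            id=s.name,
            compartment="cell",
            initialAmount=repr(float(init)),
            hasOnlySubstanceUnits="true",
            boundaryCondition="false",
            constant="false",
        )
    rx_list = etree.SubElement(model, "listOfReactions")
    mathns = "http://www.w3.org/1998/Math/MathML"
    for rxn in crn.reactions:
        rx = etree.SubElement(rx_list, "reaction", id=rxn.name, reversible="false")
        if rxn.reactants:
            lst = etree.SubElement(rx, "listOfReactants")
            for name in rxn.reactants:
                etree.SubElement(
                    lst, "speciesReference", species=name, stoichiometry="1", constant="true"
                )
        if rxn.products:
            lst = etree.SubElement(rx, "listOfProducts")
            for name in rxn.products:
                etree.SubElement(
                    lst, "speciesReference", species=name, stoichiometry="1", constant="true"
                )
        if rxn.modifiers:
            lst = etree.SubElement(rx, "listOfModifiers")
            for name in rxn.modifiers:
                etree.SubElement(lst, "modifierSpeciesReference", species=name)
        kl = etree.SubElement(rx, "kineticLaw")
        math = etree.SubElement(kl, f"{{{mathns}}}math", nsmap={None: mathns})
        apply_ = etree.SubElement(math, f"{{{mathns}}}apply")
        etree.SubElement(apply_, f"{{{mathns}}}times")
        cn = etree.SubElement(apply_, f"{{{mathns}}}cn")
        cn.text = repr(float(rxn.rate))
        for name in rxn.monomial:
            ci = etree.SubElement(apply_, f"{{{mathns}}}ci")
            ci.text = name
    return etree.tostring(
        sbml, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


def input_only_model(mech: InputMechanism | None = None) -> CRNModel:
    """The bare input submodel (S alone) — the calibration oracle."""
    mech = mech or calibrate_input()
    return CRNModel(
        model_id="input-only",
        scheme="one-step",
        species=(SpeciesDef("S", "input", "free"),),
        reactions=(
            Reaction("S_birth", (), ("S",), (), mech.basal_rate),
            Reaction("S_auto", ("S",), ("S", "S"), (), mech.autocatalytic_rate),
            Reaction("S_decay", ("S",), (), (), mech.decay_rate),
        ),
        params=ParameterSet(),
        input_mech=mech,
    )


def unregulated_node_model(
    params: ParameterSet | None = None,
    input_mech: InputMechanism | None = None,
    layer: str = "X",
) -> CRNModel:
    """A single unregulated two-state pool (plus a decoupled input S).

    Its molecules switch independently, so the stationary active count is
    exactly binomial(total, k_layer / (k_layer + ka)) — a closed-form oracle
    for all three engines.
    """
    params = params or ParameterSet()
    mech = input_mech or calibrate_input()
    k = params.layer_rate(layer)
    return CRNModel(
        model_id="unregulated-node",
        scheme="one-step",
        species=(
            SpeciesDef("S", "input", "free"),
            SpeciesDef("N_i", layer, "inactive", "N"),
            SpeciesDef("N_a", layer, "active", "N"),
        ),
        reactions=(
            Reaction("S_birth", (), ("S",), (), mech.basal_rate),
            Reaction("S_auto", ("S",), ("S", "S"), (), mech.autocatalytic_rate),
            Reaction("S_decay", ("S",), (), (), mech.decay_rate),
            Reaction("N_act0", ("N_i",), ("N_a",), (), k),
            Reaction("N_deact0", ("N_a",), ("N_i",), (), params.ka),
        ),
        params=params,
        input_mech=mech,
    )


def with_input_mechanism(crn: CRNModel, mech: InputMechanism) -> CRNModel:
    """Copy of the model with the three input-submodel rates replaced."""
    new_rates = {
        "S_birth": mech.basal_rate,
        "S_auto": mech.autocatalytic_rate,
        "S_decay": mech.decay_rate,
    }
    reactions = tuple(
        replace(r, rate=new_rates.get(r.name, r.rate)) for r in crn.reactions
    )
    return replace(crn, reactions=reactions, input_mech=mech)
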