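"""Enumeration of feed-forward loop (FFL) motif topologies and gate assignments.

A feed-forward loop is a three-node motif in which a node X regulates an
output Z both directly and indirectly through an intermediate Y.  Every edge
carries a sign (activation ``+`` or inhibition ``-``); the loop is *coherent*
when the sign of the direct arm equals the product of the two indirect-arm
signs, and *incoherent* otherwise.  The eight sign assignments are labelled
c1-c4 (coherent) and i1-i4 (incoherent) following the standard Mangan-Alon
numbering.

Beyond isolated FFLs and plain three-node chains, this module enumerates the
two ways a pair of FFLs can share nodes:

* ``minp`` (multi-input): one input S drives two X nodes that converge on a
  shared Y and a shared Z.
* ``mint`` (multi-intermediate): a single X drives two Y nodes that converge
  on a shared Z, alongside the direct X->Z arm.

Nodes that receive two or more regulators integrate them through a logic
gate.  When all incoming signs agree, both AND (joint, multiplicative) and
OR (independent, additive) gates are admissible; with mixed signs only the
independent OR-like form is meaningful, and it is labelled OR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

Sign = Literal["+", "-"]
GateType = Literal["AND", "OR"]

SIGNS: tuple[Sign, Sign] = ("+", "-")

#: Sign triples (s_xy, s_yz, s_xz) for the eight FFL types.  c1, c4 and i4
#: are pinned by their textbook descriptions (all-activating; doubly
#: inhibitory long arm with activating direct arm; inhibited intermediate
#: with two activating inputs to Z); the remaining labels follow the
#: Mangan-Alon convention.
FFL_TABLE: dict[str, tuple[Sign, Sign, Sign]] = {
    "c1": ("+", "+", "+"),
    "c2": ("-", "+", "-"),
    "c3": ("+", "-", "-"),
    "c4": ("-", "-", "+"),
    "i1": ("+", "-", "+"),
    "i2": ("-", "-", "-"),
    "i3": ("+", "+", "-"),
    "i4": ("-", "+", "+"),
}

_SIGNS_TO_TYPE = {v: k for k, v in FFL_TABLE.items()}

#: Sign pairs (s_xy, s_yz) for the four linear chain models; chain-1 is the
#: all-activating MAPK-like cascade.
CHAIN_TABLE: dict[str, tuple[Sign, Sign]] = {
    "chain-1": ("+", "+"),
    "chain-2": ("+", "-"),
    "chain-3": ("-", "+"),
    "chain-4": ("-", "-"),
}


def sign_product(*signs: Sign) -> Sign:
    """Multiply signs: like signs give ``+``, unlike give ``-``."""
    neg = sum(1 for s in signs if s == "-")
    return "-" if neg % 2 else "+"


def classify_ffl(s_xy: Sign, s_yz: Sign, s_xz: Sign) -> str:
    """Return the FFL type label (``c1``..``c4``, ``i1``..``i4``).

    The loop is coherent exactly when ``s_xy * s_yz == s_xz``.
    """
    for s in (s_xy, s_yz, s_xz):
        if s not in SIGNS:
            raise ValueError(f"invalid sign {s!r}")
    return _SIGNS_TO_TYPE[(s_xy, s_yz, s_xz)]


def is_coherent(ffl_type: str) -> bool:
    return ffl_type.startswith("c")


def gate_options(input_signs: Sequence[Sign]) -> list[GateType]:
    """Admissible gates at a node with the given incoming regulator signs.

    Both gates exist only when every regulator acts with the same sign;
    regulators of mixed sign can only act independently, which is closer to
    an OR gate and labelled as such.  A gate requires at least two inputs.
    """
    if len(input_signs) < 2:
        raise ValueError("a logic gate requires at least two regulators")
    if len(set(input_signs)) == 1:
        return ["AND", "OR"]
    return ["OR"]


@dataclass(frozen=True)
class Topology:
    """A signed, directed motif wiring diagram.

    ``edges`` are ``(source, target, sign)`` triples over the node names
    ``S``, ``X``/``X1``/``X2``, ``Y``/``Y1``/``Y2`` and ``Z``.
    ``branch_types`` holds one FFL type label for an isolated loop and the
    two branch labels (canonically ordered) for a coupled one.
    """

    family: Literal["isolated", "chain", "minp", "mint"]
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, Sign], ...]
    branch_types: tuple[str, ...]
    coherence_class: str

    def edge_sign(self, source: str, target: str) -> Sign:
        for s, t, sign in self.edges:
            if (s, t) == (source, target):
                return sign
        raise KeyError(f"no edge {source}->{target}")

    def regulators_of(self, node: str) -> list[tuple[str, Sign]]:
        return [(s, sign) for s, t, sign in self.edges if t == node]


@dataclass(frozen=True)
class CatalogEntry:
    """A topology together with a concrete gate assignment and its label."""

    topology: Topology
    gates: dict[str, GateType] = field(compare=False)
    model_id: str

    def to_json_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "family": self.topology.family,
            "branch_types": list(self.topology.branch_types),
            "coherence_class": self.topology.coherence_class,
            "edges": [list(e) for e in self.topology.edges],
            "gates": dict(self.gates),
        }


def _coherence_class(branch_types: Sequence[str]) -> str:
    flags = {is_coherent(t) for t in branch_types}
    if flags == {True}:
        return "purely coherent"
    if flags == {False}:
        return "purely incoherent"
    return "mixed"


def _branch_sort_key(label: str) -> tuple[str, int]:
    # 'c' sorts before 'i'; then ascending type number, e.g. c1i4, c4i1.
    return (label[0], int(label[1:]))


def _gate_suffix(gates: dict[str, GateType], family: str) -> str:
    if family == "minp":
        upper, lower = gates["Y"], gates["Z"]
        if upper == lower:
            return upper
        return f"u{upper}-l{lower}"
    # single gated node (Z)
    return gates["Z"]


def model_id_for(topology: Topology, gates: dict[str, GateType]) -> str:
    """Deterministic label such as ``c1-OR``, ``chain-1`` or ``c4i1-minp-uAND-lOR``."""
    if topology.family == "chain":
        return topology.branch_types[0]
    if topology.family == "isolated":
        return f"{topology.branch_types[0]}-{_gate_suffix(gates, 'isolated')}"
    pair = "".join(topology.branch_types)
    return f"{pair}-{topology.family}-{_gate_suffix(gates, topology.family)}"


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def _isolated_topology(s_xy: Sign, s_yz: Sign, s_xz: Sign) -> Topology:
    t = classify_ffl(s_xy, s_yz, s_xz)
    return Topology(
        family="isolated",
        nodes=("S", "X", "Y", "Z"),
        edges=(
            ("S", "X", "+"),
            ("X", "Y", s_xy),
            ("Y", "Z", s_yz),
            ("X", "Z", s_xz),
        ),
        branch_types=(t,),
        coherence_class=_coherence_class((t,)),
    )


def enumerate_isolated() -> list[CatalogEntry]:
    """All gated isolated FFL models (8 sign topologies, 12 gated models)."""
    entries = []
    for label in sorted(FFL_TABLE, key=_branch_sort_key):
        s_xy, s_yz, s_xz = FFL_TABLE[label]
        topo = _isolated_topology(s_xy, s_yz, s_xz)
        for gate in gate_options([s_yz, s_xz]):
            gates = {"Z": gate}
            entries.append(
                CatalogEntry(topo, gates, model_id_for(topo, gates))
            )
    return entries


def enumerate_chains() -> list[CatalogEntry]:
    """The four S->X->Y->Z cascades; no node has more than one regulator."""
    entries = []
    for label, (s_xy, s_yz) in CHAIN_TABLE.items():
        topo = Topology(
            family="chain",
            nodes=("S", "X", "Y", "Z"),
            edges=(("S", "X", "+"), ("X", "Y", s_xy), ("Y", "Z", s_yz)),
            branch_types=(label,),
            coherence_class="n/a",
        )
        entries.append(CatalogEntry(topo, {}, model_id_for(topo, {})))
    return entries


def _minp_topology(
    branch_a: tuple[Sign, Sign], branch_b: tuple[Sign, Sign], s_yz: Sign
) -> Topology:
    """Branches are (s_xi_y, s_xi_z); the Y->Z edge is shared.

    Branch order is canonicalized by FFL-type label so that swapping the two
    X nodes never produces a new topology.
    """
    typed = sorted(
        ((classify_ffl(u, s_yz, l), (u, l)) for u, l in (branch_a, branch_b)),
        key=lambda p: _branch_sort_key(p[0]),
    )
    types = tuple(t for t, _ in typed)
    (u1, l1), (u2, l2) = (b for _, b in typed)
    return Topology(
        family="minp",
        nodes=("S", "X1", "X2", "Y", "Z"),
        edges=(
            ("S", "X1", "+"),
            ("S", "X2", "+"),
            ("X1", "Y", u1),
            ("X2", "Y", u2),
            ("X1", "Z", l1),
            ("X2", "Z", l2),
            ("Y", "Z", s_yz),
        ),
        branch_types=types,
        coherence_class=_coherence_class(types),
    )


def _mint_topology(
    branch_a: tuple[Sign, Sign], branch_b: tuple[Sign, Sign], s_xz: Sign
) -> Topology:
    """Branches are (s_x_yi, s_yi_z); the direct X->Z edge is shared."""
    typed = sorted(
        ((classify_ffl(u, l, s_xz), (u, l)) for u, l in (branch_a, branch_b)),
        key=lambda p: _branch_sort_key(p[0]),
    )
    types = tuple(t for t, _ in typed)
    (u1, l1), (u2, l2) = (b for _, b in typed)
    return Topology(
        family="mint",
        nodes=("S", "X", "Y1", "Y2", "Z"),
        edges=(
            ("S", "X", "+"),
            ("X", "Y1", u1),
            ("X", "Y2", u2),
            ("Y1", "Z", l1),
            ("Y2", "Z", l2),
            ("X", "Z", s_xz),
        ),
        branch_types=types,
        coherence_class=_coherence_class(types),
    )


def _coupled_topologies(family: str) -> list[Topology]:
    builder = _minp_topology if family == "minp" else _mint_topology
    seen: dict[tuple, Topology] = {}
    branches = [(u, l) for u in SIGNS for l in SIGNS]
    for shared in SIGNS:
        for a in branches:
            for b in branches:
                topo = builder(a, b, shared)
                seen.setdefault(topo.edges, topo)
    return list(seen.values())


def enumerate_mint() -> list[CatalogEntry]:
    """Multi-intermediate coupled FFLs: 20 topologies, 26 gated models.

    Z receives three regulators (Y1, Y2 and the direct X arm); both gates
    exist only when all three incoming signs agree.
    """
    entries = []
    for topo in sorted(
        _coupled_topologies("mint"), key=lambda t: (t.branch_types, t.edges)
    ):
        z_signs = [sign for _, t, sign in topo.edges if t == "Z"]
        for gate in gate_options(z_signs):
            gates = {"Z": gate}
            entries.append(CatalogEntry(topo, gates, model_id_for(topo, gates)))
    _check_unique(entries)
    return entries


DropRule = Callable[[list["CatalogEntry"]], list["CatalogEntry"]]

#: Registry of exclusion policies applied after the naive gate-product
#: enumeration of minp models.  ``none`` keeps all 42 models produced by the
#: per-level gate-admissibility rule (the same rule that yields the verified
#: mint count of 26).  The registry is the hook for hand-curated exclusion
#: lists; see docs/methods.md for why no sign-symmetric rule can produce an
#: odd model count.
DROP_RULES: dict[str, DropRule] = {"none": lambda entries: list(entries)}


def register_drop_rule(name: str, rule: DropRule) -> None:
    """Register a named minp exclusion policy (e.g. a curated id list)."""
    DROP_RULES[name] = rule


def exclusion_list_rule(excluded_ids: Iterable[str]) -> DropRule:
    """Build a drop rule that removes the given model ids."""
    excluded = set(excluded_ids)

    def rule(entries: list[CatalogEntry]) -> list[CatalogEntry]:
        return [e for e in entries if e.model_id not in excluded]

    return rule


def enumerate_minp(drop_rule: str = "none") -> list[CatalogEntry]:
    """Multi-input coupled FFLs: 20 topologies, 42 gated models under the
    naive per-level admissibility rule.

    The upper gate sits at Y (inputs X1, X2) and the lower gate at Z
    (inputs X1, X2 and Y); each level independently admits {AND, OR} when
    its incoming signs agree and the single OR-like gate otherwise.
    ``drop_rule`` selects a registered post-hoc exclusion policy.
    """
    if drop_rule not in DROP_RULES:
        raise ValueError(
            f"unknown drop rule {drop_rule!r}; registered: {sorted(DROP_RULES)}"
        )
    entries = []
    for topo in sorted(
        _coupled_topologies("minp"), key=lambda t: (t.branch_types, t.edges)
    ):
        y_signs = [sign for _, t, sign in topo.edges if t == "Y"]
        z_signs = [sign for _, t, sign in topo.edges if t == "Z"]
        for upper in gate_options(y_signs):
            for lower in gate_options(z_signs):
                gates = {"Y": upper, "Z": lower}
                entries.append(
                    CatalogEntry(topo, gates, model_id_for(topo, gates))
                )
    entries = DROP_RULES[drop_rule](entries)
    _check_unique(entries)
    return entries


def full_catalog(drop_rule: str = "none") -> list[CatalogEntry]:
    """Every studied model: isolated FFLs, chains, minp and mint couplings."""
    return (
        enumerate_isolated()
        + enumerate_chains()
        + enumerate_minp(drop_rule)
        + enumerate_mint()
    )


def get_entry(model_id: str, drop_rule: str = "none") -> CatalogEntry:
    """Look a model up by its label, e.g. ``c1c1-minp-OR``."""
    for entry in full_catalog(drop_rule):
        if entry.model_id == model_id:
            return entry
    raise KeyError(f"no catalog entry named {model_id!r}")


def _check_unique(entries: list[CatalogEntry]) -> None:
    ids = [e.model_id for e in entries]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise RuntimeError(f"duplicate model ids in catalog: {sorted(dupes)}")


def export_catalog_jsonl(entries: Iterable[CatalogEntry]) -> str:
    """Serialize entries as JSON lines in stable (catalog) order."""
    return "\n".join(json.dumps(e.to_json_dict(), sort_keys=True) for e in entries)
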