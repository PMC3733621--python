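"""Metabolic network representation and I/O.

A :class:`Network` is an ordered collection of metabolites and reactions
together with the stoichiometric matrix ``S`` restricted to *internal*
metabolites.  Boundary metabolites (extracellular pools, biomass sinks) are
declared but excluded from steady-state mass balances, which keeps the
system open: drain and exchange fluxes terminate on them.

Three on-disk dialects are supported: a hand-editable TSV (one reaction per
row with a human-readable equation string), an equivalent JSON form, and
SBML Level 3 Version 1 with package-specific annotations carrying the
lumping exponent, kinetic class and reference flux.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ROLES = ("internal", "boundary", "biomass-sink")
KINETIC_CLASSES = (
    "mass_action_irreversible",
    "mass_action_reversible",
    "amino_acid_drain",
    "generic_drain",
    "fixed_exchange",
)


class NetworkError(ValueError):
    """Malformed network definition (parse or validation failure)."""


# ---------------------------------------------------------------------------
# gene-protein-reaction rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAssociation:
    """Boolean gene association: a leaf gene or an AND/OR node over children.

    ``op`` is ``None`` for a leaf (then ``gene`` is set), otherwise
    ``"and"``/``"or"`` with ``children`` holding sub-associations.
    """

    op: str | None = None
    gene: str | None = None
    children: tuple["GeneAssociation", ...] = ()

    def genes(self) -> set[str]:
        if self.op is None:
            return {self.gene} if self.gene else set()
        out: set[str] = set()
        for ch in self.children:
            out |= ch.genes()
        return out

    def to_string(self) -> str:
        if self.op is None:
            return self.gene or ""
        sep = f" {self.op} "
        parts = []
        for ch in self.children:
            s = ch.to_string()
            if ch.op is not None and ch.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GeneAssociation | None:
    """Parse a GPR string like ``"(G1 or G2) and G3"`` into an expression tree.

    Connectives ``and``/``or`` are case-insensitive; any other token is a
    gene id.  Empty/whitespace input returns ``None`` (no association).
    """
    if text is None or not text.strip():
        return None
    tokens = _GPR_TOKEN.findall(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> GeneAssociation:
        node = parse_and()
        children = [node]
        while peek() is not None and peek().lower() == "or":
            nonlocal pos
            pos += 1
            children.append(parse_and())
        if len(children) == 1:
            return node
        return GeneAssociation(op="or", children=tuple(children))

    def parse_and() -> GeneAssociation:
        node = parse_atom()
        children = [node]
        while peek() is not None and peek().lower() == "and":
            nonlocal pos
            pos += 1
            children.append(parse_atom())
        if len(children) == 1:
            return node
        return GeneAssociation(op="and", children=tuple(children))

    def parse_atom() -> GeneAssociation:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise NetworkError(f"GPR ends after a connective: {text!r}")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise NetworkError(f"unbalanced parentheses in GPR: {text!r}")
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise NetworkError(f"unexpected token {tok!r} in GPR: {text!r}")
        pos += 1
        return GeneAssociation(gene=tok)

    tree = parse_or()
    if pos != len(tokens):
        raise NetworkError(f"trailing tokens in GPR: {text!r}")
    return tree


# ---------------------------------------------------------------------------
# metabolites, reactions, network
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    role: str = "internal"
    reference_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise NetworkError(f"metabolite {self.id}: unknown role {self.role!r}")

    @property
    def internal(self) -> bool:
        return self.role == "internal"


@dataclass
class Reaction:
    """One reaction: signed stoichiometry, reversibility, lumping and kinetics.

    ``stoich`` maps metabolite id to a signed coefficient (negative =
    consumed, positive = produced).  ``gamma`` counts irreversible steps in a
    lumped reaction (1 for an individual reaction); a lumped reaction with at
    least one irreversible step is itself irreversible.  ``kinetic_orders``
    holds the exponent of each participating metabolite in the rate law; by
    default 2.0 where the |coefficient| is exactly 2.0 and 1.0 otherwise.
    """

    id: str
    stoich: dict[str, float]
    reversible: bool = False
    gamma: int = 1
    lumped: bool = False
    gpr: GeneAssociation | None = None
    kinetic_class: str = "mass_action_irreversible"
    kinetic_orders: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if self.kinetic_class not in KINETIC_CLASSES:
            raise NetworkError(
                f"reaction {self.id}: unknown kinetic class {self.kinetic_class!r}"
            )
        if self.gamma < 1:
            raise NetworkError(f"reaction {self.id}: gamma must be >= 1")
        for met, coeff in self.stoich.items():
            if met not in self.kinetic_orders:
                self.kinetic_orders[met] = 2.0 if abs(coeff) == 2.0 else 1.0

    @property
    def substrates(self) -> list[str]:
        return [m for m, c in self.stoich.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoich.items() if c > 0]

    def gpr_string(self) -> str:
        return self.gpr.to_string() if self.gpr is not None else ""


class Network:
    """Ordered metabolites and reactions with the internal stoichiometric matrix."""

    def __init__(self, metabolites: Iterable[Metabolite], reactions: Iterable[Reaction]):
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise NetworkError(f"duplicate reaction ids: {dup}")
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        for r in self.reactions:
            for met in r.stoich:
                if met not in self._met_index:
                    raise NetworkError(
                        f"reaction {r.id} references undeclared metabolite {met!r}"
                    )

    # -- lookup ------------------------------------------------------------

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.internal]

    @property
    def internal_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.internal]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def stoichiometric_matrix(self) -> np.ndarray:
        """S over internal metabolites (rows) by reactions (columns)."""
        internal = self.internal_ids
        row = {m: i for i, m in enumerate(internal)}
        S = np.zeros((len(internal), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoich.items():
                i = row.get(met)
                if i is not None:
                    S[i, j] = coeff
        return S

    @property
    def S(self) -> np.ndarray:
        return self.stoichiometric_matrix()

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= r.gpr.genes()
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<Network {len(self.internal_ids)} internal metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes())} genes>"
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_network(network: Network) -> list[str]:
    """Return a list of invariant violations; empty iff the network is valid."""
    report: list[str] = []
    used: set[str] = set()
    for r in network.reactions:
        used |= set(r.stoich)
        if r.gamma > 1 and not r.lumped:
            report.append(
                f"reaction {r.id}: gamma={r.gamma} > 1 but not flagged lumped"
            )
        if not r.stoich:
            report.append(f"reaction {r.id}: empty stoichiometry")
        for met, order in r.kinetic_orders.items():
            if order <= 0:
                report.append(f"reaction {r.id}: nonpositive kinetic order for {met}")
    for m in network.internal_metabolites:
        if m.id not in used:
            report.append(f"internal metabolite {m.id} appears in no reaction")
    return report


# ---------------------------------------------------------------------------
# equation strings and the TSV/JSON dialect
# ---------------------------------------------------------------------------

_ARROWS = ("<->", "->")


def format_equation(reaction: Reaction) -> str:
    def side(terms: list[tuple[str, float]]) -> str:
        parts = []
        for met, coeff in terms:
            c = abs(coeff)
            if c == 1:
                parts.append(met)
            elif c == int(c):
                parts.append(f"{int(c)} {met}")
            else:
                parts.append(f"{c:g} {met}")
        return " + ".join(parts)

    subs = [(m, reaction.stoich[m]) for m in reaction.stoich if reaction.stoich[m] < 0]
    prods = [(m, reaction.stoich[m]) for m in reaction.stoich if reaction.stoich[m] > 0]
    arrow = "<->" if reaction.reversible else "->"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``"A + 2 B -> C"`` into a stoichiometry map and reversibility."""
    arrow = None
    for a in _ARROWS:
        if a in text:
            arrow = a
            break
    if arrow is None:
        raise NetworkError(f"equation lacks an arrow ('->' or '<->'): {text!r}")
    lhs, rhs = text.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise NetworkError(f"empty term in equation: {text!r}")
            bits = term.split()
            if len(bits) == 1:
                met, coeff = bits[0], 1.0
            elif len(bits) == 2:
                try:
                    coeff = float(bits[0])
                except ValueError as exc:
                    raise NetworkError(
                        f"bad coefficient {bits[0]!r} in equation: {text!r}"
                    ) from exc
                met = bits[1]
            else:
                raise NetworkError(f"cannot parse term {term!r} in equation: {text!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add(lhs, -1.0)
    add(rhs, +1.0)
    return stoich, arrow == "<->"


TSV_COLUMNS = ["id", "equation", "gamma", "gpr", "class", "name"]
MET_TSV_COLUMNS = ["id", "role", "name"]


def write_network(network: Network, path: str, dialect: str = "tsv") -> None:
    """Serialize a network in the tabular (tsv), json or sbml dialect."""
    if dialect == "tsv":
        _write_tsv(network, path)
    elif dialect == "json":
        _write_json(network, path)
    elif dialect == "sbml":
        write_sbml(network, None, path)
    else:
        raise NetworkError(f"unknown dialect {dialect!r}")


def _write_tsv(network: Network, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# metabolites\n")
        fh.write("\t".join(MET_TSV_COLUMNS) + "\n")
        for m in network.metabolites:
            fh.write(f"{m.id}\t{m.role}\t{m.name}\n")
        fh.write("# reactions\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in network.reactions:
            fh.write(
                "\t".join(
                    [
                        r.id,
                        format_equation(r),
                        str(r.gamma),
                        r.gpr_string(),
                        r.kinetic_class,
                        r.name,
                    ]
                )
                + "\n"
            )


def _reaction_from_record(
    rid: str, equation: str, gamma: str | int, gpr: str, klass: str, name: str = ""
) -> Reaction:
    stoich, reversible = parse_equation(equation)
    g = int(gamma) if str(gamma).strip() else 1
    return Reaction(
        id=rid,
        stoich=stoich,
        reversible=reversible,
        gamma=g,
        lumped=g > 1,
        gpr=parse_gpr(gpr),
        kinetic_class=klass.strip()
        or ("mass_action_reversible" if reversible else "mass_action_irreversible"),
        name=name,
    )


def _read_tsv(path: str) -> Network:
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    section = None
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                tag = line.lstrip("#").strip().lower()
                if tag in ("metabolites", "reactions"):
                    section = tag
                    header = None
                continue
            if section is None:
                raise NetworkError(f"{path}:{lineno}: content before a section header")
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                expected = MET_TSV_COLUMNS if section == "metabolites" else TSV_COLUMNS
                missing = [c for c in expected[:2] if c not in header]
                if missing:
                    raise NetworkError(
                        f"{path}:{lineno}: missing columns {missing} in {section}"
                    )
                unknown = [c for c in header if c not in expected]
                if unknown:
                    logger.warning("%s: ignoring unknown columns %s", path, unknown)
                continue
            rec = dict(zip(header, cells))
            try:
                if section == "metabolites":
                    mets.append(
                        Metabolite(
                            id=rec["id"],
                            role=rec.get("role", "internal") or "internal",
                            name=rec.get("name", ""),
                        )
                    )
                else:
                    rxns.append(
                        _reaction_from_record(
                            rec["id"],
                            rec["equation"],
                            rec.get("gamma", "1") or "1",
                            rec.get("gpr", ""),
                            rec.get("class", ""),
                            rec.get("name", ""),
                        )
                    )
            except (KeyError, NetworkError) as exc:
                raise NetworkError(f"{path}:{lineno}: {exc}") from exc
    return Network(mets, rxns)


def _write_json(network: Network, path: str) -> None:
    doc = {
        "metabolites": [
            {"id": m.id, "role": m.role, "name": m.name} for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "equation": format_equation(r),
                "gamma": r.gamma,
                "gpr": r.gpr_string(),
                "class": r.kinetic_class,
                "name": r.name,
            }
            for r in network.reactions
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def _read_json(path: str) -> Network:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    mets = [
        Metabolite(id=m["id"], role=m.get("role", "internal"), name=m.get("name", ""))
        for m in doc["metabolites"]
    ]
    rxns = [
        _reaction_from_record(
            r["id"],
            r["equation"],
            r.get("gamma", 1),
            r.get("gpr", ""),
            r.get("class", ""),
            r.get("name", ""),
        )
        for r in doc["reactions"]
    ]
    return Network(mets, rxns)


def read_network(path: str, dialect: str = "tsv") -> Network:
    """Read a network file in the tsv, json or sbml dialect and validate it."""
    if dialect == "tsv":
        net = _read_tsv(path)
    elif dialect == "json":
        net = _read_json(path)
    elif dialect == "sbml":
        net, _ = read_sbml(path)
    else:
        raise NetworkError(f"unknown dialect {dialect!r}")
    problems = validate_network(net)
    if problems:
        raise NetworkError("invalid network: " + "; ".join(problems))
    return net


# ---------------------------------------------------------------------------
# SBML L3V1
# ---------------------------------------------------------------------------

_ANNOT_NS = "https://gemkin.invalid/sbml/annotations"


def write_sbml(network: Network, v_ref: Mapping[str, float] | None, path: str) -> None:
    """Export SBML Level 3 Version 1; gamma/class/reference flux go in annotations.

    Rate laws are emitted as MathML kinetic laws referencing normalized
    species; re-import recovers stoichiometry, reversibility and the
    annotations exactly.
    """
    import libsbml

    if not network.reactions:
        raise NetworkError("no reactions: refusing to write an empty SBML model")

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel("gemkin_model")
    comp = model.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)

    for m in network.metabolites:
        sp = model.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name or m.id)
        sp.setCompartment("cell")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(not m.internal)
        sp.setConstant(False)
        sp.setInitialConcentration(m.reference_concentration or 1.0)
        sp.appendAnnotation(
            f'<gemkin:meta xmlns:gemkin="{_ANNOT_NS}" role="{m.role}"/>'
        )

    from .ratelaws import sbml_rate_formula  # local import to avoid a cycle

    for r in network.reactions:
        rx = model.createReaction()
        rx.setId(r.id)
        rx.setName(r.name or r.id)
        rx.setReversible(r.reversible)
        rx.setFast(False)
        for met, coeff in r.stoich.items():
            if coeff < 0:
                ref = rx.createReactant()
            else:
                ref = rx.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        v = None if v_ref is None else float(v_ref.get(r.id, 0.0))
        attrs = [
            f'gamma="{r.gamma}"',
            f'kinetic_class="{r.kinetic_class}"',
            f'lumped="{str(r.lumped).lower()}"',
        ]
        if v is not None:
            attrs.append(f'reference_flux="{v!r}"')
        if r.gpr is not None:
            attrs.append(f'gpr="{r.gpr.to_string()}"')
        rx.appendAnnotation(
            f'<gemkin:kinetics xmlns:gemkin="{_ANNOT_NS}" {" ".join(attrs)}/>'
        )
        formula = sbml_rate_formula(r, v if v is not None else 1.0)
        ast = libsbml.parseL3Formula(formula)
        if ast is not None:
            kl = rx.createKineticLaw()
            kl.setMath(ast)

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise NetworkError(f"cannot write SBML to {path}")


def _parse_annotation_attrs(node) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if node is None:
        return attrs
    stack = [node]
    while stack:
        cur = stack.pop()
        xa = cur.getAttributes()
        for i in range(xa.getLength()):
            attrs[xa.getName(i)] = xa.getValue(i)
        for i in range(cur.getNumChildren()):
            stack.append(cur.getChild(i))
    return attrs


def read_sbml(path: str) -> tuple[Network, dict[str, float]]:
    """Import an SBML file; returns the network and any annotated reference fluxes."""
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise NetworkError(f"SBML parse errors in {path}: {msgs}")
    model = doc.getModel()
    if model is None:
        raise NetworkError(f"no model in SBML file {path}")

    mets = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        attrs = _parse_annotation_attrs(sp.getAnnotation())
        role = attrs.get("role")
        if role not in ROLES:
            role = "boundary" if sp.getBoundaryCondition() else "internal"
        mets.append(Metabolite(id=sp.getId(), name=sp.getName(), role=role))

    rxns = []
    v_ref: dict[str, float] = {}
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        attrs = _parse_annotation_attrs(rx.getAnnotation())
        gamma = int(attrs.get("gamma", "1"))
        klass = attrs.get(
            "kinetic_class",
            "mass_action_reversible" if rx.getReversible() else "mass_action_irreversible",
        )
        if "reference_flux" in attrs:
            v_ref[rx.getId()] = float(attrs["reference_flux"])
        rxns.append(
            Reaction(
                id=rx.getId(),
                stoich=stoich,
                reversible=rx.getReversible(),
                gamma=gamma,
                lumped=attrs.get("lumped", "false") == "true" or gamma > 1,
                gpr=parse_gpr(attrs.get("gpr", "")),
                kinetic_class=klass,
                name=rx.getName(),
            )
        )
    return Network(mets, rxns), v_ref
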