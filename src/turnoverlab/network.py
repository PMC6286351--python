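"""Metabolic network container and I/O.

The network is the substrate of every flux computation in this package: a
stoichiometric matrix ``S``, per-reaction flux bounds (mmol·gDW⁻¹·h⁻¹),
gene–protein–reaction (GPR) boolean rules, per-gene molecular weights
(g·mmol⁻¹, numerically equal to kDa) and per-metabolite elemental formulas.
Elemental balance is validated for C, N, S and P only — the elements the
growth-environment sampler cares about; H and O may appear in formulas (they
identify water and protons) but are not balanced.

Two dialects are supported: SBML Level 3 + FBC (read through COBRApy) and a
small canonical JSON dialect used for fixtures, documented in
:func:`MetabolicNetwork.to_json`.
"""

from __future__ import annotations

import ast
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "BALANCED_ELEMENTS",
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "FluxVector",
    "parse_gpr",
    "gpr_genes",
    "gpr_to_string",
    "gpr_alternatives",
    "NetworkValidationError",
]

#: Elements checked by the mass-balance validator.
BALANCED_ELEMENTS = ("C", "N", "S", "P")


class NetworkValidationError(ValueError):
    """Raised when a network violates its structural invariants."""


# ---------------------------------------------------------------------------
# GPR trees
# ---------------------------------------------------------------------------
# A GPR is a nested tuple tree: ("gene", "b0008"), ("and", [children]) or
# ("or", [children]).  Strings are parsed through cobra's GPR class, which
# handles parentheses and case-insensitive and/or.


def parse_gpr(rule: str | None):
    """Parse a GPR rule string into a tuple tree; ``None``/"" -> ``None``."""
    if rule is None or not str(rule).strip():
        return None
    from cobra.core.gene import GPR

    gpr = GPR.from_string(str(rule))
    if gpr.body is None:
        return None
    return _from_ast(gpr.body)


def _from_ast(node):
    if isinstance(node, ast.Name):
        return ("gene", node.id)
    if isinstance(node, ast.BoolOp):
        op = "and" if isinstance(node.op, ast.And) else "or"
        return (op, [_from_ast(v) for v in node.values])
    if isinstance(node, ast.Expression):
        return _from_ast(node.body)
    raise ValueError(f"unsupported GPR node: {ast.dump(node)}")


def gpr_genes(tree) -> set[str]:
    """All gene ids referenced by a GPR tree."""
    if tree is None:
        return set()
    kind = tree[0]
    if kind == "gene":
        return {tree[1]}
    out: set[str] = set()
    for child in tree[1]:
        out |= gpr_genes(child)
    return out


def gpr_to_string(tree) -> str:
    if tree is None:
        return ""
    kind = tree[0]
    if kind == "gene":
        return tree[1]
    sep = f" {kind} "
    parts = []
    for child in tree[1]:
        s = gpr_to_string(child)
        if child[0] != "gene" and child[0] != kind:
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)


def gpr_alternatives(tree) -> list[frozenset[str]]:
    """Expand a GPR tree to disjunctive normal form.

    Returns the list of alternative enzyme complexes: each element is the set
    of genes that must be jointly present (an AND-complex); the alternatives
    are the OR-isozymes.  A single-gene rule yields one singleton set.
    """
    if tree is None:
        return []
    kind = tree[0]
    if kind == "gene":
        return [frozenset([tree[1]])]
    if kind == "or":
        out: list[frozenset[str]] = []
        for child in tree[1]:
            for alt in gpr_alternatives(child):
                if alt not in out:
                    out.append(alt)
        return out
    # AND: cartesian product of children's alternatives
    alts: list[frozenset[str]] = [frozenset()]
    for child in tree[1]:
        child_alts = gpr_alternatives(child)
        alts = [a | c for a in alts for c in child_alts]
    dedup: list[frozenset[str]] = []
    for a in alts:
        if a not in dedup:
            dedup.append(a)
    return dedup


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    formula: dict[str, int] = field(default_factory=dict)

    def atoms(self, element: str) -> int:
        return int(self.formula.get(element, 0))

    @property
    def is_water(self) -> bool:
        f = {k: v for k, v in self.formula.items() if v}
        return f == {"H": 2, "O": 1}

    @property
    def is_proton(self) -> bool:
        f = {k: v for k, v in self.formula.items() if v}
        return f == {"H": 1}


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: tuple | None = None
    membrane: bool = False
    ec_class: int | None = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def genes(self) -> set[str]:
        return gpr_genes(self.gpr)


@dataclass
class FluxVector:
    """A steady-state flux distribution (mmol·gDW⁻¹·h⁻¹) plus its objective."""

    fluxes: dict[str, float]
    objective_value: float

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def abs_sum(self) -> float:
        return float(sum(abs(v) for v in self.fluxes.values()))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction_id\tflux\n")
            for rid, v in self.fluxes.items():
                fh.write(f"{rid}\t{v:.12g}\n")


class MetabolicNetwork:
    """A small genome-scale-model-style metabolic network.

    Parameters
    ----------
    metabolites, reactions
        Iterables of :class:`Metabolite` / :class:`Reaction`; order is
        preserved and defines the rows/columns of the stoichiometric matrix.
    biomass_reaction
        Id of the growth objective reaction.
    gene_mw
        Gene id -> molecular weight in g·mmol⁻¹ (kDa).
    oxygen_exchange
        Id of the O2 exchange reaction, if any (used by environment sampling).
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_reaction: str,
        gene_mw: Mapping[str, float] | None = None,
        oxygen_exchange: str | None = None,
    ):
        self.metabolites: dict[str, Metabolite] = {m.id: m for m in metabolites}
        self.reactions: dict[str, Reaction] = {r.id: r for r in reactions}
        self.biomass_reaction = biomass_reaction
        self.gene_mw: dict[str, float] = dict(gene_mw or {})
        self.oxygen_exchange = oxygen_exchange

    # -- structure ---------------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            out |= r.genes()
        return out

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S (metabolites x reactions) plus row/column id lists."""
        mets = self.metabolite_ids
        rxns = self.reaction_ids
        midx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rxns)))
        for j, rid in enumerate(rxns):
            for met, coef in self.reactions[rid].stoichiometry.items():
                S[midx[met], j] = coef
        return S, mets, rxns

    def bounds(self) -> list[tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions.values()]

    def exchange_reactions(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def exchange_elements(self, rid: str) -> set[str]:
        """Elements of C/N/S/P supplied by an exchange reaction's metabolite."""
        r = self.reactions[rid]
        if not r.is_exchange:
            raise ValueError(f"{rid} is not an exchange reaction")
        met = self.metabolites[next(iter(r.stoichiometry))]
        return {e for e in BALANCED_ELEMENTS if met.atoms(e) > 0}

    def carbon_atoms(self, rid: str) -> int:
        r = self.reactions[rid]
        met = self.metabolites[next(iter(r.stoichiometry))]
        return met.atoms("C")

    def reactions_for_gene(self, gene: str) -> list[str]:
        return [r.id for r in self.reactions.values() if gene in r.genes()]

    # -- mutation helpers --------------------------------------------------

    def copy(self) -> "MetabolicNetwork":
        mets = [Metabolite(m.id, dict(m.formula)) for m in self.metabolites.values()]
        rxns = [
            Reaction(
                r.id,
                dict(r.stoichiometry),
                r.lower_bound,
                r.upper_bound,
                r.gpr,
                r.membrane,
                r.ec_class,
            )
            for r in self.reactions.values()
        ]
        return MetabolicNetwork(
            mets, rxns, self.biomass_reaction, dict(self.gene_mw), self.oxygen_exchange
        )

    def with_exchange_bounds(self, lower: Mapping[str, float]) -> "MetabolicNetwork":
        """Copy with every exchange lower bound closed to 0, then ``lower`` applied."""
        net = self.copy()
        for rid in net.exchange_reactions():
            net.reactions[rid].lower_bound = 0.0
        for rid, lb in lower.items():
            net.reactions[rid].lower_bound = float(lb)
        return net

    # -- validation --------------------------------------------------------

    def validate(self, balance_tol: float = 1e-9) -> None:
        """Check structural invariants; raise :class:`NetworkValidationError`.

        Checks: biomass exists; lb <= ub; metabolite references resolve;
        every GPR gene has a molecular weight; every non-exchange reaction is
        elementally balanced for C, N, S, P.
        """
        if self.biomass_reaction not in self.reactions:
            raise NetworkValidationError(
                f"biomass reaction {self.biomass_reaction!r} not in network"
            )
        for r in self.reactions.values():
            if r.lower_bound > r.upper_bound:
                raise NetworkValidationError(f"{r.id}: lower bound exceeds upper bound")
            for met in r.stoichiometry:
                if met not in self.metabolites:
                    raise NetworkValidationError(f"{r.id}: unknown metabolite {met!r}")
            for g in r.genes():
                if g not in self.gene_mw:
                    raise NetworkValidationError(
                        f"{r.id}: gene {g!r} has no molecular weight"
                    )
            if not r.is_exchange:
                for element in BALANCED_ELEMENTS:
                    net_atoms = sum(
                        coef * self.metabolites[met].atoms(element)
                        for met, coef in r.stoichiometry.items()
                    )
                    if abs(net_atoms) > balance_tol:
                        raise NetworkValidationError(
                            f"{r.id}: unbalanced for {element} ({net_atoms:+g})"
                        )

    # -- I/O ---------------------------------------------------------------

    def to_json(self, path=None) -> str:
        """Serialize to the canonical JSON dialect.

        Schema: ``{"metabolites": [{"id", "formula"}], "reactions": [{"id",
        "stoichiometry", "lower_bound", "upper_bound", "gpr" (rule string),
        "membrane", "ec_class"}], "biomass_reaction", "gene_mw",
        "oxygen_exchange"}``.
        """
        doc = {
            "metabolites": [
                {"id": m.id, "formula": m.formula} for m in self.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": r.stoichiometry,
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "gpr": gpr_to_string(r.gpr),
                    "membrane": r.membrane,
                    "ec_class": r.ec_class,
                }
                for r in self.reactions.values()
            ],
            "biomass_reaction": self.biomass_reaction,
            "gene_mw": self.gene_mw,
            "oxygen_exchange": self.oxygen_exchange,
        }
        text = json.dumps(doc, indent=1, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MetabolicNetwork":
        """Read the JSON dialect from a path, file object or string."""
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            s = str(source)
            if s.lstrip().startswith("{"):
                doc = json.loads(s)
            else:
                with open(s) as fh:
                    doc = json.load(fh)
        mets = [Metabolite(m["id"], dict(m.get("formula", {}))) for m in doc["metabolites"]]
        rxns = [
            Reaction(
                r["id"],
                {k: float(v) for k, v in r["stoichiometry"].items()},
                float(r.get("lower_bound", 0.0)),
                float(r.get("upper_bound", 1000.0)),
                parse_gpr(r.get("gpr")),
                bool(r.get("membrane", False)),
                r.get("ec_class"),
            )
            for r in doc["reactions"]
        ]
        return cls(
            mets,
            rxns,
            doc["biomass_reaction"],
            {k: float(v) for k, v in doc.get("gene_mw", {}).items()},
            doc.get("oxygen_exchange"),
        )

    @classmethod
    def from_sbml(
        cls,
        path,
        gene_mw: Mapping[str, float] | None = None,
        biomass_reaction: str | None = None,
    ) -> "MetabolicNetwork":
        """Read an SBML L3+FBC model through COBRApy.

        SBML does not carry gene molecular weights, so ``gene_mw`` must be
        supplied separately (genes absent from it simply cannot be used in
        capacity-constrained problems).
        """
        import cobra.io

        model = cobra.io.read_sbml_model(str(path))
        mets = [
            Metabolite(m.id, dict(m.elements) if m.formula else {})
            for m in model.metabolites
        ]
        rxns = [
            Reaction(
                r.id,
                {m.id: c for m, c in r.metabolites.items()},
                r.lower_bound,
                r.upper_bound,
                parse_gpr(r.gene_reaction_rule),
            )
            for r in model.reactions
        ]
        if biomass_reaction is None:
            objective = [r.id for r in model.reactions if r.objective_coefficient]
            if len(objective) != 1:
                raise ValueError("cannot determine a unique biomass reaction from SBML")
            biomass_reaction = objective[0]
        oxygen = None
        for r in model.exchanges:
            met = next(iter(r.metabolites))
            if met.formula == "O2":
                oxygen = r.id
                break
        return cls(mets, rxns, biomass_reaction, gene_mw or {}, oxygen)
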