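"""Structural TBox checks and closed-world ABox checks.

Published dysplasia ontologies are validated with open-world DL reasoners;
at desk scale, checking patient records against ``only``/``some``
restrictions is more useful under constraint (closed-world) semantics:
restrictions are evaluated over the links actually asserted, nothing is
inferred. ``characterized_by only (...)`` is therefore read as "allowed
features", exactly what the universal quantifier says, not as "required
features".

External-term subsumption (e.g. "descends from HP:HP_0000118") is resolved
through MIREOT parent-hint chains; a chain that runs out of hints before
reaching any recognized root is tolerated (missing information, not an
inconsistency) rather than reported as a violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .kb_model import (
    ClassAxiom,
    ClassExpression,
    DisjunctiveAxiom,
    KnowledgeBase,
    PILLAR_ROOTS,
    RELATIONS,
)

__all__ = [
    "Individual",
    "Violation",
    "check_tbox",
    "check_abox",
    "classify_membership",
]


@dataclass
class Individual:
    """An ABox individual: asserted types, relation links, datatype values."""

    id: str
    types: list[str] = field(default_factory=list)
    links: list[tuple[str, str]] = field(default_factory=list)
    data: dict[str, str] = field(default_factory=dict)


VIOLATION_KINDS = (
    "some_unsatisfied",
    "only_violated",
    "domain_mismatch",
    "range_mismatch",
    "dag_cycle",
    "unknown_ref",
)


@dataclass(frozen=True, order=True)
class Violation:
    """A machine-readable constraint violation, with stable ordering."""

    subject: str
    relation: str
    kind: str
    message: str

    def __str__(self) -> str:
        return f"{self.subject}\t{self.relation}\t{self.kind}\t{self.message}"


#: Recognized external subtree roots; an ancestry chain ending at one of
#: these is considered complete.
KNOWN_EXTERNAL_ROOTS = frozenset(
    {
        "HP:HP_0000118",
        "HP:HP_0000005",
        "REAMS:Abnormality",
        "NCI:Mutation_Abnormality",
        "PATO:PATO_0001241",
        "PATO:PATO_0000068",
        "FMA:Anatomical_entity",
        "FMA:Primary_anatomical_coordinate",
        "FMA:Secondary_anatomical_coordinate",
    }
)


def _descends_or_open(kb: KnowledgeBase, term_id: str, roots: Iterable[str]) -> bool:
    """True when the external term descends from any of ``roots``.

    Also true when its parent-hint chain is incomplete (never reaches a
    recognized root): the placement is then unknown, and unknown placement
    degrades to acceptance, not a violation.
    """
    chain = kb.external_ancestry(term_id)
    if any(r in chain for r in roots):
        return True
    if not chain:
        return True  # unresolvable term handled separately as unknown_ref
    return chain[-1] not in KNOWN_EXTERNAL_ROOTS


# ---------------------------------------------------------------------------
# per-relation range rules

def _range_ok(kb: KnowledgeBase, relation: str, owner_pillar: str, rid: str) -> bool:
    """Does resolved atom ``rid`` fit the range of ``relation`` (Table-style)?"""
    is_class = rid in kb.classes
    pillar = kb.classes[rid].pillar if is_class else None
    if relation == "characterized_by":
        if is_class:
            return pillar in ("gene_mutation", "phenotypic_composite")
        return _descends_or_open(kb, rid, ["HP:HP_0000118", "REAMS:Abnormality"])
    if relation == "mode_of_inheritance":
        return not is_class and _descends_or_open(kb, rid, ["HP:HP_0000005"])
    if relation in ("has_locus", "is_encoded_by"):
        return is_class and pillar == "gene"
    if relation == "mutation_type":
        return not is_class and _descends_or_open(kb, rid, ["NCI:Mutation_Abnormality"])
    if relation == "describes":
        if is_class:
            return pillar == "anatomical_composite"
        return _descends_or_open(kb, rid, ["FMA:Anatomical_entity"])
    if relation == "has_quality":
        if is_class:
            return pillar == "quality_composite"
        return _descends_or_open(kb, rid, ["PATO:PATO_0001241"])
    if relation == "has_qualifier":
        return not is_class and _descends_or_open(
            kb, rid, ["PATO:PATO_0000068", "PATO:PATO_0001241"]
        )
    if relation == "has_anatomical_coordinate":
        return not is_class and _descends_or_open(
            kb,
            rid,
            ["FMA:Primary_anatomical_coordinate", "FMA:Secondary_anatomical_coordinate"],
        )
    if relation == "has_part":
        if owner_pillar == "phenotypic_composite":
            return is_class and pillar == "phenotypic_composite"
        if owner_pillar == "anatomical_composite":
            if is_class:
                return pillar == "anatomical_composite"
            return _descends_or_open(kb, rid, ["FMA:Anatomical_entity"])
        if owner_pillar == "quality_composite":
            return not is_class and _descends_or_open(kb, rid, ["PATO:PATO_0001241"])
        return False
    return False  # pragma: no cover - registry is closed


# ---------------------------------------------------------------------------
# TBox

def check_tbox(kb: KnowledgeBase) -> list[Violation]:
    """Structural consistency of class definitions.

    Empty result iff the subclass graph is acyclic, every axiom's relation
    domain matches the owning class's pillar, every filler atom resolves,
    and every filler atom fits the relation's range (including the
    ``characterized_by`` filler constraint: gene mutations, phenotypic
    composites, or HP/REAMS abnormality descendants).
    """
    violations: list[Violation] = []
    if not kb.is_dag():
        violations.append(
            Violation("<graph>", "rdfs:subClassOf", "dag_cycle",
                      "subclass graph contains a cycle")
        )
    for cls in kb.classes.values():
        for parent in cls.parents:
            if parent not in kb.classes and parent not in kb.externals:
                violations.append(
                    Violation(cls.id, "rdfs:subClassOf", "unknown_ref",
                              f"unresolvable parent {parent}")
                )
        for ax in cls.class_axioms():
            rel = RELATIONS[ax.relation]
            if cls.pillar not in rel.domains:
                violations.append(
                    Violation(cls.id, ax.relation, "domain_mismatch",
                              f"relation {ax.relation} does not apply to pillar "
                              f"{cls.pillar}")
                )
                continue
            owner_pillar = cls.pillar
            for a in ax.filler.atoms():
                rid = kb.resolve(a)
                if rid is None:
                    violations.append(
                        Violation(cls.id, ax.relation, "unknown_ref",
                                  f"unresolvable filler atom {a}")
                    )
                elif not _range_ok(kb, ax.relation, owner_pillar, rid):
                    violations.append(
                        Violation(cls.id, ax.relation, "range_mismatch",
                                  f"filler atom {a} outside the range of "
                                  f"{ax.relation}")
                    )
    return sorted(set(violations))


# ---------------------------------------------------------------------------
# ABox

def _instance_of(kb: KnowledgeBase, types: list[str], expr: ClassExpression) -> bool:
    """Closed-world: do the asserted ``types`` satisfy the expression?"""
    if expr.kind == "atom":
        return any(kb.subsumes(expr.atom, t) for t in types)
    if expr.kind == "and":
        return all(_instance_of(kb, types, c) for c in expr.children)
    return any(_instance_of(kb, types, c) for c in expr.children)


def _axiom_satisfied(
    kb: KnowledgeBase,
    ind: Individual,
    ax: ClassAxiom,
    type_of: Mapping[str, list[str]],
) -> tuple[bool, list[Violation]]:
    """Evaluate one plain axiom over an individual's asserted links."""
    violations: list[Violation] = []
    targets = [t for rel, t in ind.links if rel == ax.relation]
    if ax.kind in ("some", "only_and_some"):
        hit = any(_instance_of(kb, type_of.get(t, [t]), ax.filler) for t in targets)
        if not hit:
            violations.append(
                Violation(ind.id, ax.relation, "some_unsatisfied",
                          f"no {ax.relation} link satisfies "
                          f"'{_expr_text(ax.filler)}'")
            )
    if ax.kind in ("only", "only_and_some"):
        for t in targets:
            if not _instance_of(kb, type_of.get(t, [t]), ax.filler):
                violations.append(
                    Violation(ind.id, ax.relation, "only_violated",
                              f"{ax.relation} link to {t} outside "
                              f"'{_expr_text(ax.filler)}'")
                )
    return (not violations), violations


def _expr_text(expr: ClassExpression) -> str:
    from .owl_io import serialize_expression

    return serialize_expression(expr)


def check_abox(
    kb: KnowledgeBase, individuals: Iterable[Individual]
) -> list[Violation]:
    """Closed-world constraint check of individuals against their classes.

    For each individual and each restriction of its *asserted* classes:
    ``some`` requires at least one link of that relation to a target typed
    by the filler; ``only`` requires every such link to be. A disjunctive
    axiom is satisfied when at least one branch is fully satisfied.
    Violations are data, not exceptions.
    """
    individuals = list(individuals)
    type_of: dict[str, list[str]] = {ind.id: ind.types for ind in individuals}
    violations: list[Violation] = []
    for ind in individuals:
        if not ind.types:
            violations.append(
                Violation(ind.id, "rdf:type", "unknown_ref", "individual has no type")
            )
        for t in ind.types:
            if kb.resolve(t) is None:
                violations.append(
                    Violation(ind.id, "rdf:type", "unknown_ref",
                              f"unresolvable type {t}")
                )
        for rel, target in ind.links:
            if rel not in RELATIONS:
                violations.append(
                    Violation(ind.id, rel, "unknown_ref", f"unknown relation {rel}")
                )
            if target not in type_of and kb.resolve(target) is None:
                violations.append(
                    Violation(ind.id, rel, "unknown_ref",
                              f"unresolvable link target {target}")
                )
        for t in ind.types:
            rid = kb.resolve(t)
            if rid is None or rid not in kb.classes:
                continue
            for ax in kb.classes[rid].axioms:
                if isinstance(ax, ClassAxiom):
                    _, vs = _axiom_satisfied(kb, ind, ax, type_of)
                    violations.extend(vs)
                else:
                    if not any(
                        all(
                            _axiom_satisfied(kb, ind, a, type_of)[0]
                            for a in branch
                        )
                        for branch in ax.branches
                    ):
                        rels = "|".join(
                            sorted({a.relation for b in ax.branches for a in b})
                        )
                        violations.append(
                            Violation(ind.id, rels, "some_unsatisfied",
                                      "no branch of the disjunctive axiom of "
                                      f"{rid} is satisfied")
                        )
    return sorted(set(violations))


# ---------------------------------------------------------------------------
# patient classification

def _characterized_by_fillers(kb: KnowledgeBase, dysplasia: str) -> list[ClassExpression]:
    """Own + inherited ``characterized_by`` only-fillers of a dysplasia class."""
    ids = [dysplasia] + sorted(kb.superclasses(dysplasia))
    fillers = []
    for cid in ids:
        for ax in kb.classes[cid].axioms:
            if (
                isinstance(ax, ClassAxiom)
                and ax.relation == "characterized_by"
                and ax.kind in ("only", "only_and_some")
            ):
                fillers.append(ax.filler)
    return fillers


def classify_membership(
    kb: KnowledgeBase,
    individual: Individual,
    individuals: Optional[Iterable[Individual]] = None,
) -> list[str]:
    """Dysplasia classes compatible with a patient's asserted features.

    A dysplasia is compatible when every ``characterized_by`` link of the
    patient falls inside every applicable only-filler (own and inherited) —
    closed-world compatibility, not DL realization. Link targets are typed
    through the supplied ABox when given, else the target id itself is
    taken as the feature term. A patient with no links matches every
    dysplasia (a universal restriction over the empty set is vacuous).
    Result sorted by id.
    """
    type_of = {ind.id: ind.types for ind in (individuals or [])}
    feature_types = [
        type_of.get(target, [target])
        for rel, target in individual.links
        if rel == "characterized_by"
    ]
    root = PILLAR_ROOTS["dysplasia"]
    out = []
    for cls in kb.own_classes():
        if cls.pillar != "dysplasia":
            continue
        fillers = _characterized_by_fillers(kb, cls.id)
        ok = all(
            _instance_of(kb, types, filler)
            for filler in fillers
            for types in feature_types
        )
        if ok and cls.id != root:
            out.append(cls.id)
    return sorted(out)
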