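"""Independent brute-force reference implementations used only by tests.

Everything here recomputes results from first principles over the plain
data fields of a KnowledgeBase (``classes``, ``externals``) and the
documented contracts — no library graph helpers, resolvers, or validators
are reused — so agreement with the library is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import re

from bdokit.axiom_validator import Individual, Violation
from bdokit.kb_model import ClassAxiom, DisjunctiveAxiom, KnowledgeBase

# --------------------------------------------------------------------------
# identifier resolution (independent copies of the id conventions)

_ID_RE = re.compile(r"^(GM|G|P|PC_|AC_|QC_)(\d{5,8})$")
_SOURCES = (
    "HP", "PATO", "FMA", "NCI", "REAMS", "UO",
    "OMIM", "MeSH", "UniProt", "UMLS", "OGMS", "snap",
)


def oracle_normalize(value: str) -> str:
    m = _ID_RE.match(value.strip())
    if m:
        return m.group(1) + str(int(m.group(2))).rjust(7, "0")
    return value.strip()


def oracle_resolve(kb: KnowledgeBase, token: str):
    tid = oracle_normalize(token)
    if tid in kb.classes or tid in kb.externals:
        return tid
    for src in _SOURCES:
        cand = src + ":" + tid
        if cand in kb.externals:
            return cand
    return None


# --------------------------------------------------------------------------
# graph reachability (recursive walks over the raw parent lists)

def oracle_ancestors(kb: KnowledgeBase, cid: str) -> set[str]:
    """All own-class ancestors of ``cid``, by upward recursion."""
    out: set[str] = set()

    def walk(node: str) -> None:
        for parent in kb.classes[node].parents:
            if parent in kb.classes and parent not in out:
                out.add(parent)
                walk(parent)

    walk(cid)
    return out


def oracle_descendants(kb: KnowledgeBase, cid: str) -> set[str]:
    return {c for c in kb.classes if cid in oracle_ancestors(kb, c)}


def oracle_has_cycle(kb: KnowledgeBase) -> bool:
    """Three-color DFS over the own-class parent edges."""
    color = {c: 0 for c in kb.classes}

    def visit(node: str) -> bool:
        color[node] = 1
        for parent in kb.classes[node].parents:
            if parent not in kb.classes:
                continue
            if color[parent] == 1:
                return True
            if color[parent] == 0 and visit(parent):
                return True
        color[node] = 2
        return False

    return any(color[c] == 0 and visit(c) for c in kb.classes)


def oracle_depth(kb: KnowledgeBase, cid: str) -> int:
    """Longest root→class path length by exhaustive path enumeration."""
    if cid == "Bone_Dysplasia":
        return 0
    best = -1
    stack = [(cid, 0)]
    while stack:
        node, d = stack.pop()
        for parent in kb.classes[node].parents:
            if parent == "Bone_Dysplasia":
                best = max(best, d + 1)
            elif parent in kb.classes:
                stack.append((parent, d + 1))
    if best < 0:
        raise ValueError(f"{cid} not under Bone_Dysplasia")
    return best


def oracle_external_chain(kb: KnowledgeBase, ext_id: str) -> list[str]:
    chain, seen, cur = [], set(), ext_id
    while cur and cur in kb.externals and cur not in seen:
        chain.append(cur)
        seen.add(cur)
        cur = kb.externals[cur].parent_hint
    return chain


def oracle_subsumes(kb: KnowledgeBase, general: str, specific: str) -> bool:
    g = oracle_resolve(kb, general) or oracle_normalize(general)
    s = oracle_resolve(kb, specific) or oracle_normalize(specific)
    if g == s:
        return True
    if s in kb.classes and g in kb.classes:
        return g in oracle_ancestors(kb, s)
    if s in kb.externals:
        return g in oracle_external_chain(kb, s)
    return False


# --------------------------------------------------------------------------
# TBox oracle: flat enumeration of (class, axiom, atom) triples

_DOMAINS = {
    "characterized_by": {"dysplasia"},
    "mode_of_inheritance": {"dysplasia"},
    "has_locus": {"gene_mutation"},
    "mutation_type": {"gene_mutation"},
    "is_encoded_by": {"protein"},
    "describes": {"phenotypic_composite"},
    "has_quality": {"phenotypic_composite"},
    "has_qualifier": {"quality_composite"},
    "has_anatomical_coordinate": {"anatomical_composite"},
    "has_part": {"phenotypic_composite", "anatomical_composite",
                 "quality_composite"},
}

_KNOWN_ROOTS = {
    "HP:HP_0000118", "HP:HP_0000005", "REAMS:Abnormality",
    "NCI:Mutation_Abnormality", "PATO:PATO_0001241", "PATO:PATO_0000068",
    "FMA:Anatomical_entity", "FMA:Primary_anatomical_coordinate",
    "FMA:Secondary_anatomical_coordinate",
}

# (class-pillars accepted, external roots accepted); has_part handled apart
_RANGES = {
    "characterized_by": ({"gene_mutation", "phenotypic_composite"},
                         {"HP:HP_0000118", "REAMS:Abnormality"}),
    "mode_of_inheritance": (set(), {"HP:HP_0000005"}),
    "has_locus": ({"gene"}, set()),
    "is_encoded_by": ({"gene"}, set()),
    "mutation_type": (set(), {"NCI:Mutation_Abnormality"}),
    "describes": ({"anatomical_composite"}, {"FMA:Anatomical_entity"}),
    "has_quality": ({"quality_composite"}, {"PATO:PATO_0001241"}),
    "has_qualifier": (set(), {"PATO:PATO_0000068", "PATO:PATO_0001241"}),
    "has_anatomical_coordinate": (set(), {"FMA:Primary_anatomical_coordinate",
                                          "FMA:Secondary_anatomical_coordinate"}),
}

_HAS_PART_RANGES = {
    "phenotypic_composite": ({"phenotypic_composite"}, set()),
    "anatomical_composite": ({"anatomical_composite"},
                             {"FMA:Anatomical_entity"}),
    "quality_composite": (set(), {"PATO:PATO_0001241"}),
}


def _flat_axioms(cls):
    """Plain ClassAxioms of a class, descending disjunctive branches."""
    for ax in cls.axioms:
        if isinstance(ax, DisjunctiveAxiom):
            for branch in ax.branches:
                yield from branch
        else:
            yield ax


def _expr_atoms(expr):
    if expr.kind == "atom":
        yield expr.atom
    else:
        for child in expr.children:
            yield from _expr_atoms(child)


def _oracle_range_ok(kb: KnowledgeBase, relation: str, owner_pillar: str,
                     rid: str) -> bool:
    if relation == "has_part":
        pillars, roots = _HAS_PART_RANGES.get(owner_pillar, (set(), set()))
    else:
        pillars, roots = _RANGES[relation]
    if rid in kb.classes:
        return kb.classes[rid].pillar in pillars
    if not roots:
        return False
    chain = oracle_external_chain(kb, rid)
    if any(r in chain for r in roots):
        return True
    # an ancestry chain that never reaches a recognized root is tolerated
    return bool(chain) and chain[-1] not in _KNOWN_ROOTS


def oracle_check_tbox(kb: KnowledgeBase) -> list[Violation]:
    out: list[Violation] = []
    if oracle_has_cycle(kb):
        out.append(Violation("<graph>", "rdfs:subClassOf", "dag_cycle",
                             "subclass graph contains a cycle"))
    for cls in kb.classes.values():
        for parent in cls.parents:
            if parent not in kb.classes and parent not in kb.externals:
                out.append(Violation(cls.id, "rdfs:subClassOf", "unknown_ref",
                                     f"unresolvable parent {parent}"))
        for ax in _flat_axioms(cls):
            if cls.pillar not in _DOMAINS[ax.relation]:
                out.append(Violation(
                    cls.id, ax.relation, "domain_mismatch",
                    f"relation {ax.relation} does not apply to pillar "
                    f"{cls.pillar}"))
                continue
            for a in _expr_atoms(ax.filler):
                rid = oracle_resolve(kb, a)
                if rid is None:
                    out.append(Violation(
                        cls.id, ax.relation, "unknown_ref",
                        f"unresolvable filler atom {a}"))
                elif not _oracle_range_ok(kb, ax.relation, cls.pillar, rid):
                    out.append(Violation(
                        cls.id, ax.relation, "range_mismatch",
                        f"filler atom {a} outside the range of {ax.relation}"))
    return sorted(set(out))


# --------------------------------------------------------------------------
# ABox oracle

def _oracle_instance_of(kb: KnowledgeBase, types, expr) -> bool:
    if expr.kind == "atom":
        return any(oracle_subsumes(kb, expr.atom, t) for t in types)
    if expr.kind == "and":
        return all(_oracle_instance_of(kb, types, c) for c in expr.children)
    return any(_oracle_instance_of(kb, types, c) for c in expr.children)


def _oracle_axiom_ok(kb, ind, ax, type_of) -> tuple[bool, list[Violation]]:
    from bdokit.owl_io import serialize_expression

    vs: list[Violation] = []
    targets = [t for rel, t in ind.links if rel == ax.relation]
    if ax.kind in ("some", "only_and_some"):
        if not any(
            _oracle_instance_of(kb, type_of.get(t, [t]), ax.filler)
            for t in targets
        ):
            vs.append(Violation(
                ind.id, ax.relation, "some_unsatisfied",
                f"no {ax.relation} link satisfies "
                f"'{serialize_expression(ax.filler)}'"))
    if ax.kind in ("only", "only_and_some"):
        for t in targets:
            if not _oracle_instance_of(kb, type_of.get(t, [t]), ax.filler):
                vs.append(Violation(
                    ind.id, ax.relation, "only_violated",
                    f"{ax.relation} link to {t} outside "
                    f"'{serialize_expression(ax.filler)}'"))
    return (not vs), vs


def oracle_check_abox(kb: KnowledgeBase, individuals) -> list[Violation]:
    individuals = list(individuals)
    type_of = {ind.id: ind.types for ind in individuals}
    out: list[Violation] = []
    for ind in individuals:
        if not ind.types:
            out.append(Violation(ind.id, "rdf:type", "unknown_ref",
                                 "individual has no type"))
        for t in ind.types:
            if oracle_resolve(kb, t) is None:
                out.append(Violation(ind.id, "rdf:type", "unknown_ref",
                                     f"unresolvable type {t}"))
        for rel, target in ind.links:
            if rel not in _DOMAINS:
                out.append(Violation(ind.id, rel, "unknown_ref",
                                     f"unknown relation {rel}"))
            if target not in type_of and oracle_resolve(kb, target) is None:
                out.append(Violation(ind.id, rel, "unknown_ref",
                                     f"unresolvable link target {target}"))
        for t in ind.types:
            rid = oracle_resolve(kb, t)
            if rid is None or rid not in kb.classes:
                continue
            for ax in kb.classes[rid].axioms:
                if isinstance(ax, ClassAxiom):
                    out.extend(_oracle_axiom_ok(kb, ind, ax, type_of)[1])
                elif not any(
                    all(_oracle_axiom_ok(kb, ind, a, type_of)[0] for a in branch)
                    for branch in ax.branches
                ):
                    rels = "|".join(sorted(
                        {a.relation for b in ax.branches for a in b}))
                    out.append(Violation(
                        ind.id, rels, "some_unsatisfied",
                        f"no branch of the disjunctive axiom of {rid} "
                        "is satisfied"))
    return sorted(set(out))


def oracle_classify(kb: KnowledgeBase, individual: Individual,
                    individuals=None) -> list[str]:
    type_of = {ind.id: ind.types for ind in (individuals or [])}
    feature_types = [
        type_of.get(target, [target])
        for rel, target in individual.links
        if rel == "characterized_by"
    ]
    out = []
    for cid, cls in kb.classes.items():
        if cls.pillar != "dysplasia" or cid == "Bone_Dysplasia":
            continue
        fillers = []
        for holder in [cid] + sorted(oracle_ancestors(kb, cid)):
            for ax in kb.classes[holder].axioms:
                if (isinstance(ax, ClassAxiom)
                        and ax.relation == "characterized_by"
                        and ax.kind in ("only", "only_and_some")):
                    fillers.append(ax.filler)
        if all(_oracle_instance_of(kb, types, filler)
               for filler in fillers for types in feature_types):
            out.append(cid)
    return sorted(out)


# --------------------------------------------------------------------------
# analytics oracles

def oracle_profile(kb: KnowledgeBase, dysplasia: str) -> set[str]:
    profile: set[str] = set()
    for ax in _flat_axioms(kb.classes[oracle_normalize(dysplasia)]):
        if ax.relation != "characterized_by":
            continue
        for a in _expr_atoms(ax.filler):
            rid = oracle_resolve(kb, a)
            if rid is None:
                continue
            if rid in kb.classes:
                if kb.classes[rid].pillar == "phenotypic_composite":
                    profile.add(rid)
            elif kb.externals[rid].source in ("HP", "REAMS"):
                profile.add(rid)
    return profile


def oracle_rank_jaccard(kb: KnowledgeBase, phenotypes) -> list[tuple[str, float]]:
    pset = {oracle_normalize(p) for p in phenotypes}
    rows = []
    for cid, cls in kb.classes.items():
        if cls.pillar != "dysplasia" or cid == "Bone_Dysplasia":
            continue
        profile = oracle_profile(kb, cid)
        inter = pset & profile
        if inter:
            rows.append((cid, len(inter) / len(pset | profile)))
    return sorted(rows, key=lambda r: (-r[1], r[0]))


def oracle_mine_rules(cases, min_support, min_confidence, max_antecedent=3):
    """Exhaustive enumeration of every antecedent subset × diagnosis.

    Feasible only for small cohorts (few distinct phenotypes); used to
    cross-check the level-wise miner.
    """
    n = len(cases)
    items = sorted({p for c in cases for p in c.phenotypes})
    diagnoses = sorted({c.diagnosis for c in cases if c.diagnosis})
    out = []
    for size in range(1, max_antecedent + 1):
        for combo in itertools.combinations(items, size):
            ante = frozenset(combo)
            a_count = sum(1 for c in cases if ante <= c.phenotypes)
            if a_count == 0:
                continue
            for d in diagnoses:
                j = sum(1 for c in cases
                        if c.diagnosis == d and ante <= c.phenotypes)
                if j == 0:
                    continue
                support = j / n
                confidence = j / a_count
                if support >= min_support and confidence >= min_confidence:
                    out.append((ante, d, support, confidence))
    return sorted(out, key=lambda r: (-r[3], -r[2], r[1], sorted(r[0])))


def oracle_refine_keep(kb: KnowledgeBase, antecedent, consequent) -> bool:
    """Should a mined rule survive axiom-based refinement?"""
    if consequent not in kb.classes:
        return False
    fillers = []
    for holder in [consequent] + sorted(oracle_ancestors(kb, consequent)):
        for ax in kb.classes[holder].axioms:
            if (isinstance(ax, ClassAxiom)
                    and ax.relation == "characterized_by"
                    and ax.kind in ("only", "only_and_some")):
                fillers.append(ax.filler)
    return all(_oracle_instance_of(kb, [p], filler)
               for filler in fillers for p in antecedent)
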