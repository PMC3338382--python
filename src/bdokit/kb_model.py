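"""Core typed knowledge base for a skeletal-dysplasia nosology.

The model follows the three-pillar architecture used by ontologies in this
domain: a disease hierarchy (bone dysplasias grouped into nosology groups),
a genotype pillar (genes, gene mutations, proteins) and a phenotype pillar
(entity--quality composites plus references into external phenotype
ontologies such as HP, PATO and FMA).

Classes live in a subclass DAG rooted at per-pillar top-level classes.
Class semantics beyond subsumption are carried by restriction axioms
(universal ``only``, existential ``some``, or the paired form
``only_and_some``) over a fixed relation registry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Union

import networkx as nx

__all__ = [
    "PILLARS",
    "ANNOTATION_KEYS",
    "ClassExpression",
    "ClassAxiom",
    "DisjunctiveAxiom",
    "Axiom",
    "Relation",
    "RELATIONS",
    "ExternalTermRef",
    "ClassDef",
    "KBStats",
    "KnowledgeBase",
    "BdoError",
    "DuplicateIdError",
    "UnknownTermError",
    "CycleError",
    "InvalidClassError",
    "atom",
    "conj",
    "disj",
    "normalize_term_id",
]


# --------------------------------------------------------------------------
# errors

class BdoError(Exception):
    """Base error for knowledge-base operations."""


class DuplicateIdError(BdoError):
    pass


class UnknownTermError(BdoError):
    pass


class CycleError(BdoError):
    pass


class InvalidClassError(BdoError):
    pass


# --------------------------------------------------------------------------
# vocabulary

PILLARS = (
    "dysplasia",
    "gene",
    "gene_mutation",
    "protein",
    "phenotypic_composite",
    "anatomical_composite",
    "quality_composite",
    "external",
)

#: Annotation-property vocabulary: cross-reference keys plus the datatype
#: properties used on gene-mutation classes (encoding, offset, count and the
#: original/mutated nucleotide content).
ANNOTATION_KEYS = frozenset(
    {
        "omim_no",
        "uniprot_id",
        "mesh_id",
        "umls_cui",
        "ref_seq",
        "entrezgene_id",
        "accession_no",
        "chromosomal_locus",
        "encoding",
        "offset",
        "count",
        "original_content",
        "mutated_content",
    }
)

#: Upper-level (BFO/OGMS) rooting of the pillar top classes, kept as
#: metadata tags: it documents ontological commitment but carries no
#: computational behaviour at this scale.
UPPER_LEVEL_ROOTING = {
    "dysplasia": "OGMS:OGMS_0000047",
    "gene": "snap:MaterialEntity",
    "gene_mutation": "snap:SpecificallyDependentContinuant",
    "phenotypic_composite": "OGMS:OGMS_0000023",
}

#: Root class id per pillar (bootstrapped into every KnowledgeBase).
PILLAR_ROOTS = {
    "dysplasia": "Bone_Dysplasia",
    "gene": "Gene",
    "gene_mutation": "Gene_Mutation",
    "protein": "Protein",
    "phenotypic_composite": "Phenotypic_Composite",
    "anatomical_composite": "Anatomical_Composite",
    "quality_composite": "Quality_Composite",
}

ROOT_PILLARS = {v: k for k, v in PILLAR_ROOTS.items()}

#: The five primary top-level classes.
PRIMARY_ROOTS = (
    "Bone_Dysplasia",
    "Gene",
    "Gene_Mutation",
    "Protein",
    "Phenotypic_Composite",
)

#: Incrementally-encoded id prefixes (zero-padded integers).
ID_PREFIXES = {"gene": "G", "gene_mutation": "GM", "protein": "P"}
COMPOSITE_PREFIXES = {
    "phenotypic_composite": "PC_",
    "anatomical_composite": "AC_",
    "quality_composite": "QC_",
}

ID_WIDTH = 7

_INCREMENTAL_RE = re.compile(r"^(GM|G|P|PC_|AC_|QC_)(\d{5,8})$")


def normalize_term_id(value: str) -> str:
    """Canonicalize incrementally-encoded ids to 7-digit zero padding.

    Sources print these ids with inconsistent padding (``GM0000001`` and
    ``GM000001`` both occur in the wild); 5--8 digit forms are accepted and
    normalized. Anything else is returned unchanged.
    """
    m = _INCREMENTAL_RE.match(value.strip())
    if m:
        return f"{m.group(1)}{int(m.group(2)):0{ID_WIDTH}d}"
    return value.strip()


# --------------------------------------------------------------------------
# class expressions and axioms

@dataclass(frozen=True)
class ClassExpression:
    """Tree of atomic class references combined with ``and`` / ``or``.

    ``kind`` is one of ``atom``, ``and``, ``or``. Atoms hold a term id;
    boolean nodes hold >= 2 children.
    """

    kind: str
    atom: Optional[str] = None
    children: tuple["ClassExpression", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "atom":
            if not self.atom:
                raise InvalidClassError("atom expression requires a term id")
        elif self.kind in ("and", "or"):
            if len(self.children) < 2:
                raise InvalidClassError(f"{self.kind} node needs >= 2 children")
        else:
            raise InvalidClassError(f"unknown expression kind {self.kind!r}")

    def atoms(self) -> Iterator[str]:
        """Yield every atomic term id in the tree (left to right)."""
        if self.kind == "atom":
            yield self.atom  # type: ignore[misc]
        else:
            for child in self.children:
                yield from child.atoms()


def atom(term_id: str) -> ClassExpression:
    return ClassExpression("atom", atom=normalize_term_id(term_id))


def conj(*children: ClassExpression) -> ClassExpression:
    return ClassExpression("and", children=tuple(children))


def disj(*children: ClassExpression) -> ClassExpression:
    return ClassExpression("or", children=tuple(children))


AXIOM_KINDS = ("only", "some", "only_and_some")


@dataclass(frozen=True)
class ClassAxiom:
    """A restriction ``relation only/some FILLER`` on the owning class.

    ``only_and_some`` records the common paired pattern
    ``R only F and R some F`` as a single axiom.
    """

    relation: str
    kind: str
    filler: ClassExpression

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise InvalidClassError(f"unknown relation {self.relation!r}")
        if self.kind not in AXIOM_KINDS:
            raise InvalidClassError(f"unknown axiom kind {self.kind!r}")


@dataclass(frozen=True)
class DisjunctiveAxiom:
    """A disjunction of restriction conjunctions.

    Needed for top-level composite definitions of the shape
    ``(R some A and R only A) or (S some B and S only B)``; each branch is a
    tuple of plain :class:`ClassAxiom`. Satisfying any one branch satisfies
    the axiom.
    """

    branches: tuple[tuple[ClassAxiom, ...], ...]

    def __post_init__(self) -> None:
        if len(self.branches) < 2 or any(not b for b in self.branches):
            raise InvalidClassError("disjunctive axiom needs >= 2 non-empty branches")


Axiom = Union[ClassAxiom, DisjunctiveAxiom]


# --------------------------------------------------------------------------
# relation registry

@dataclass(frozen=True)
class Relation:
    """A fixed object property with its domain pillars and range note.

    Range semantics (which atoms may appear in fillers) are enforced by the
    validator; ``range_note`` is the human-readable statement of the range.
    """

    name: str
    domains: frozenset
    range_note: str


def _rel(name: str, domains: Iterable[str], range_note: str) -> Relation:
    return Relation(name, frozenset(domains), range_note)


RELATIONS: Mapping[str, Relation] = {
    r.name: r
    for r in (
        _rel(
            "characterized_by",
            ["dysplasia"],
            "Phenotypic_Composite | Gene_Mutation | HP:HP_0000118 | REAMS:Abnormality",
        ),
        _rel("mode_of_inheritance", ["dysplasia"], "HP:HP_0000005"),
        _rel("has_locus", ["gene_mutation"], "Gene"),
        _rel("mutation_type", ["gene_mutation"], "NCI:Mutation_Abnormality"),
        _rel("is_encoded_by", ["protein"], "Gene"),
        _rel(
            "describes",
            ["phenotypic_composite"],
            "Anatomical_Composite | FMA:Anatomical_entity",
        ),
        _rel(
            "has_quality",
            ["phenotypic_composite"],
            "Quality_Composite | PATO:PATO_0001241",
        ),
        _rel(
            "has_qualifier",
            ["quality_composite"],
            "PATO:PATO_0000068 | PATO:PATO_0001241",
        ),
        _rel(
            "has_anatomical_coordinate",
            ["anatomical_composite"],
            "FMA:Primary_anatomical_coordinate | FMA:Secondary_anatomical_coordinate",
        ),
        _rel(
            "has_part",
            ["phenotypic_composite", "anatomical_composite", "quality_composite"],
            "composite-dependent: PC->Phenotypic_Composite, "
            "AC->FMA:Anatomical_entity|Anatomical_Composite, QC->PATO:PATO_0001241",
        ),
    )
}


# --------------------------------------------------------------------------
# external term references (MIREOT-style)

EXTERNAL_SOURCES = (
    "HP",
    "PATO",
    "FMA",
    "NCI",
    "REAMS",
    "UO",
    "OMIM",
    "MeSH",
    "UniProt",
    "UMLS",
    "OGMS",
    "snap",
)


@dataclass(frozen=True)
class ExternalTermRef:
    """Minimal reference to a single external-ontology term.

    Only the information needed to cite and place the term is kept (id,
    source, label and an optional parent hint used for subsumption checks);
    the external ontology itself is never imported wholesale.
    """

    id: str
    source: str
    label: str
    parent_hint: str = ""

    def __post_init__(self) -> None:
        if self.source not in EXTERNAL_SOURCES:
            raise InvalidClassError(f"unknown external source {self.source!r}")
        if not self.label:
            raise InvalidClassError(f"external ref {self.id} requires a label")
        if not self.id.startswith(self.source + ":"):
            raise InvalidClassError(
                f"external id {self.id!r} does not carry the {self.source} prefix"
            )


# --------------------------------------------------------------------------
# class definitions

@dataclass
class ClassDef:
    """An own-defined ontology class."""

    id: str
    pillar: str
    label: str
    alt_labels: list[str] = field(default_factory=list)
    description: str = ""
    parents: list[str] = field(default_factory=list)
    axioms: list[Axiom] = field(default_factory=list)
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.id = normalize_term_id(self.id)
        self.parents = [normalize_term_id(p) for p in self.parents]
        if self.pillar not in PILLARS:
            raise InvalidClassError(f"unknown pillar {self.pillar!r}")
        bad = set(self.annotations) - ANNOTATION_KEYS
        if bad:
            raise InvalidClassError(
                f"annotation keys {sorted(bad)} outside the allowed vocabulary"
            )

    def class_axioms(self) -> Iterator[ClassAxiom]:
        """Iterate plain axioms, descending into disjunctive branches."""
        for ax in self.axioms:
            if isinstance(ax, ClassAxiom):
                yield ax
            else:
                for branch in ax.branches:
                    yield from branch


@dataclass(frozen=True)
class KBStats:
    total: int
    per_pillar: dict
    n_groups: int
    n_dysplasia_leaves: int
    frac_mutation_linked: float
    frac_phenotype_linked: float


# --------------------------------------------------------------------------
# the knowledge base

class KnowledgeBase:
    """Classes, external references, the subclass DAG and KB metadata.

    Every KB bootstraps the seven pillar root classes; own-defined content
    is everything added on top of them.
    """

    def __init__(self, metadata: Optional[Mapping[str, str]] = None):
        self.classes: dict[str, ClassDef] = {}
        self.externals: dict[str, ExternalTermRef] = {}
        self.metadata: dict[str, str] = dict(metadata or {})
        self.load_warnings: list[str] = []
        for pillar, root in PILLAR_ROOTS.items():
            cls = ClassDef(id=root, pillar=pillar, label=root.replace("_", " "))
            self.classes[root] = cls

    # -- basic access -----------------------------------------------------

    @property
    def roots(self) -> tuple[str, ...]:
        return PRIMARY_ROOTS

    def own_classes(self) -> Iterator[ClassDef]:
        """Own-defined classes, excluding the bootstrapped pillar roots."""
        for cid, cls in self.classes.items():
            if cid not in ROOT_PILLARS:
                yield cls

    def __contains__(self, term_id: str) -> bool:
        tid = normalize_term_id(term_id)
        return tid in self.classes or tid in self.externals

    def get_class(self, term_id: str) -> ClassDef:
        tid = normalize_term_id(term_id)
        try:
            return self.classes[tid]
        except KeyError:
            raise UnknownTermError(f"unknown class {term_id!r}") from None

    def add_external(self, ref: ExternalTermRef) -> ExternalTermRef:
        existing = self.externals.get(ref.id)
        if existing is not None and existing != ref:
            raise DuplicateIdError(f"conflicting external ref {ref.id}")
        self.externals[ref.id] = ref
        return ref

    def resolve(self, token: str) -> Optional[str]:
        """Resolve an expression atom to a known class or external id.

        Tries the normalized token directly, then probes source-prefixed
        forms (printed axioms often drop the ``HP:`` prefix from HP ids).
        Returns the resolved id or None.
        """
        tid = normalize_term_id(token)
        if tid in self.classes or tid in self.externals:
            return tid
        for src in EXTERNAL_SOURCES:
            cand = f"{src}:{tid}"
            if cand in self.externals:
                return cand
        return None

    # -- mutation of the class graph --------------------------------------

    def add_class(self, cls: ClassDef) -> "KnowledgeBase":
        """Register a class; parents must already exist; DAG is preserved."""
        if cls.id in self.classes or cls.id in self.externals:
            raise DuplicateIdError(f"duplicate id {cls.id}")
        for parent in cls.parents:
            if parent == cls.id:
                raise CycleError(f"class {cls.id} lists itself as a parent")
            if parent not in self.classes and parent not in self.externals:
                raise UnknownTermError(f"dangling parent {parent!r} for {cls.id}")
        if cls.label:
            for other in self.own_classes():
                if other.pillar == cls.pillar and other.label == cls.label:
                    raise DuplicateIdError(
                        f"label {cls.label!r} already used in pillar {cls.pillar}"
                    )
        self.classes[cls.id] = cls
        # A fresh node with existing parents cannot close a cycle, but a
        # defensive re-check keeps the invariant independent of call order.
        if not self.is_dag():  # pragma: no cover - unreachable by construction
            del self.classes[cls.id]
            raise CycleError(f"adding {cls.id} would create a cycle")
        return self

    def move_class(self, term_id: str, new_parents: list[str]) -> "KnowledgeBase":
        """Editorial re-classification: replace the parent list, re-check DAG."""
        cls = self.get_class(term_id)
        parents = [normalize_term_id(p) for p in new_parents]
        for parent in parents:
            if parent not in self.classes and parent not in self.externals:
                raise UnknownTermError(f"dangling parent {parent!r}")
        old = cls.parents
        cls.parents = parents
        if not self.is_dag():
            cls.parents = old
            raise CycleError(f"moving {term_id} under {parents} creates a cycle")
        return self

    # -- graph queries -----------------------------------------------------

    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        for cls in self.classes.values():
            for parent in cls.parents:
                if parent in self.classes:
                    g.add_edge(parent, cls.id)
        return g

    def is_dag(self) -> bool:
        return nx.is_directed_acyclic_graph(self._graph())

    def subclasses(self, term_id: str, direct: bool = False) -> set[str]:
        tid = self.get_class(term_id).id
        g = self._graph()
        if direct:
            return set(g.successors(tid))
        return set(nx.descendants(g, tid))

    def superclasses(self, term_id: str, direct: bool = False) -> set[str]:
        tid = self.get_class(term_id).id
        g = self._graph()
        if direct:
            return set(g.predecessors(tid))
        return set(nx.ancestors(g, tid))

    def depth(self, term_id: str) -> int:
        """Longest subclass-edge path from Bone_Dysplasia down to the class."""
        cls = self.get_class(term_id)
        if cls.pillar != "dysplasia":
            raise UnknownTermError(f"{term_id} is not a dysplasia-pillar class")
        root = PILLAR_ROOTS["dysplasia"]
        if cls.id == root:
            return 0
        g = self._graph()
        if cls.id not in nx.descendants(g, root):
            raise UnknownTermError(f"{term_id} is not under {root}")
        best = 0
        stack = [(root, 0)]
        while stack:
            node, d = stack.pop()
            if node == cls.id:
                best = max(best, d)
                continue
            for child in g.successors(node):
                stack.append((child, d + 1))
        return best

    def groups(self) -> set[str]:
        """Nosology groups: direct subclasses of Bone_Dysplasia."""
        return self.subclasses(PILLAR_ROOTS["dysplasia"], direct=True)

    def dysplasia_leaves(self) -> set[str]:
        """Disease-level dysplasia classes: leaves at depth >= 2."""
        out = set()
        for cls in self.own_classes():
            if cls.pillar != "dysplasia":
                continue
            if self.subclasses(cls.id, direct=True):
                continue
            try:
                if self.depth(cls.id) >= 2:
                    out.add(cls.id)
            except UnknownTermError:
                continue
        return out

    # -- id allocation -----------------------------------------------------

    def next_id(self, pillar: str) -> str:
        """Smallest unused id in the incremental scheme for the pillar."""
        prefix = ID_PREFIXES.get(pillar)
        if prefix is None:
            raise InvalidClassError(f"pillar {pillar!r} has no incremental id scheme")
        used = set()
        for cid in self.classes:
            m = _INCREMENTAL_RE.match(cid)
            if m and m.group(1) == prefix:
                used.add(int(m.group(2)))
        n = 1
        while n in used:
            n += 1
        return f"{prefix}{n:0{ID_WIDTH}d}"

    def next_composite_id(self, pillar: str) -> str:
        prefix = COMPOSITE_PREFIXES.get(pillar)
        if prefix is None:
            raise InvalidClassError(f"pillar {pillar!r} has no composite id scheme")
        used = set()
        for cid in self.classes:
            m = _INCREMENTAL_RE.match(cid)
            if m and m.group(1) == prefix:
                used.add(int(m.group(2)))
        n = 1
        while n in used:
            n += 1
        return f"{prefix}{n:0{ID_WIDTH}d}"

    # -- external subsumption ----------------------------------------------

    def external_ancestry(self, term_id: str) -> list[str]:
        """Chain of parent hints starting at the term itself.

        Broken hints terminate the chain silently: an unresolvable hint is
        missing information, not an inconsistency.
        """
        chain = []
        seen = set()
        cur = term_id
        while cur and cur in self.externals and cur not in seen:
            chain.append(cur)
            seen.add(cur)
            cur = self.externals[cur].parent_hint
        return chain

    def external_descends(self, term_id: str, ancestor: str) -> bool:
        """True when ``term_id`` is ``ancestor`` or below it via parent hints."""
        return ancestor in self.external_ancestry(term_id)

    def subsumes(self, general: str, specific: str) -> bool:
        """True when ``specific`` equals or specializes ``general``.

        Covers both own classes (subclass DAG) and external references
        (parent-hint chains).
        """
        g = self.resolve(general) or normalize_term_id(general)
        s = self.resolve(specific) or normalize_term_id(specific)
        if g == s:
            return True
        if s in self.classes and g in self.classes:
            return s in self.subclasses(g)
        if s in self.externals:
            return self.external_descends(s, g)
        return False

    # -- summary -----------------------------------------------------------

    def stats(self) -> KBStats:
        """Own-class counts per pillar plus axiom-coverage fractions.

        The coverage fractions are computed over disease-level leaves: the
        share whose ``characterized_by`` filler names at least one gene
        mutation, and the share whose filler names at least one phenotype
        (external HP/REAMS term or phenotypic composite).
        """
        per_pillar = {p: 0 for p in PILLARS}
        for cls in self.own_classes():
            per_pillar[cls.pillar] += 1
        leaves = self.dysplasia_leaves()
        n_mut = n_phen = 0
        for leaf in leaves:
            has_mut = has_phen = False
            for ax in self.get_class(leaf).class_axioms():
                if ax.relation != "characterized_by":
                    continue
                for a in ax.filler.atoms():
                    rid = self.resolve(a)
                    if rid is None:
                        continue
                    if rid in self.classes:
                        p = self.classes[rid].pillar
                        if p == "gene_mutation":
                            has_mut = True
                        elif p == "phenotypic_composite":
                            has_phen = True
                    elif self.externals[rid].source in ("HP", "REAMS"):
                        has_phen = True
            n_mut += has_mut
            n_phen += has_phen
        n_leaves = len(leaves)
        return KBStats(
            total=sum(per_pillar.values()),
            per_pillar=per_pillar,
            n_groups=len(self.groups()),
            n_dysplasia_leaves=n_leaves,
            frac_mutation_linked=(n_mut / n_leaves) if n_leaves else 0.0,
            frac_phenotype_linked=(n_phen / n_leaves) if n_leaves else 0.0,
        )
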