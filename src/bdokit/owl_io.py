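"""Reading and writing the knowledge base.

Three surfaces:

* a restricted Manchester-style class-expression grammar
  (:func:`parse_class_expression` / :func:`serialize_axiom`) covering
  ``REL only EXPR``, ``REL some EXPR``, conjunction, disjunction and
  parentheses — exactly the fragment used in published dysplasia class
  definitions;
* a canonical plain-text dialect (one ``Class:`` block per class with
  ``SubClassOf:`` grammar lines, ``Annotation:`` pairs, plus ``Meta:`` and
  ``External:`` lines) that round-trips losslessly and deterministically;
* a read-only OWL loader (Turtle / RDF-XML via rdflib) mapping
  ``owl:allValuesFrom``/``owl:someValuesFrom`` restriction nodes onto the
  same axiom model and classes outside the ontology namespace onto
  MIREOT-style external term references.

Universal+existential pairs on the same relation and filler are stored once
as ``only_and_some``; a lone ``only`` stays ``kind="only"``.
"""

from __future__ import annotations

import re
from typing import Optional, Union

import rdflib
from rdflib import RDF, RDFS, OWL, Namespace

from .kb_model import (
    ANNOTATION_KEYS,
    Axiom,
    ClassAxiom,
    ClassDef,
    ClassExpression,
    DisjunctiveAxiom,
    EXTERNAL_SOURCES,
    ExternalTermRef,
    KnowledgeBase,
    PILLAR_ROOTS,
    RELATIONS,
    ROOT_PILLARS,
    atom,
    conj,
    disj,
    normalize_term_id,
)

__all__ = [
    "ParseError",
    "parse_class_expression",
    "serialize_expression",
    "serialize_axiom",
    "parse_kb",
    "serialize_kb",
    "load_kb",
    "write_kb",
    "load_external_table",
    "write_external_table",
]

# A parsed subclass line: a bare expression, one axiom, a
# conjunction of axioms, or a disjunction of axiom conjunctions.
ParsedLine = Union[ClassExpression, ClassAxiom, list, DisjunctiveAxiom]


class ParseError(ValueError):
    """Syntax error, carrying the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at token {position})")
        self.position = position


# --------------------------------------------------------------------------
# tokenizer / parser

_TOKEN_RE = re.compile(r"\(|\)|[A-Za-z_][A-Za-z0-9_:.\-]*|\S")
_KEYWORDS = {"and", "or", "only", "some"}


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.i = 0

    def peek(self, offset: int = 0) -> Optional[str]:
        j = self.i + offset
        return self.tokens[j] if j < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of input", self.i)
        self.i += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise ParseError(f"expected {tok!r}, got {got!r}", self.i - 1)

    # -- restriction detection ------------------------------------------

    def _at_axiom(self, offset: int = 0) -> bool:
        """True when the upcoming tokens start a ``REL only|some`` restriction."""
        return (
            self.peek(offset) in RELATIONS
            and self.peek(offset + 1) in ("only", "some")
        )

    # -- expressions ------------------------------------------------------

    def parse_expression(self) -> ClassExpression:
        terms = [self.parse_and_expression()]
        while self.peek() == "or":
            self.next()
            terms.append(self.parse_and_expression())
        return terms[0] if len(terms) == 1 else disj(*terms)

    def parse_and_expression(self) -> ClassExpression:
        terms = [self.parse_primary()]
        while self.peek() == "and":
            self.next()
            terms.append(self.parse_primary())
        return terms[0] if len(terms) == 1 else conj(*terms)

    def parse_primary(self) -> ClassExpression:
        tok = self.peek()
        if tok == "(":
            self.next()
            expr = self.parse_expression()
            self.expect(")")
            return expr
        if tok is None or tok in _KEYWORDS or tok == ")":
            raise ParseError(f"expected class atom, got {tok!r}", self.i)
        return atom(self.next())

    # -- axioms -----------------------------------------------------------

    def parse_simple_axiom(self) -> ClassAxiom:
        rel = self.next()
        if rel not in RELATIONS:
            raise ParseError(f"unknown relation {rel!r}", self.i - 1)
        kind = self.next()
        if kind not in ("only", "some"):
            raise ParseError(f"expected only/some after {rel}", self.i - 1)
        if self.peek() == "(":
            self.next()
            filler = self.parse_expression()
            self.expect(")")
        else:
            filler = self.parse_primary()
            if filler.kind != "atom":
                raise ParseError("multi-atom fillers must be parenthesized", self.i)
        return ClassAxiom(rel, kind, filler)

    def parse_axiom_conjunction(self) -> list[ClassAxiom]:
        axioms = [self.parse_simple_axiom()]
        while self.peek() == "and":
            if not self._at_axiom(1):
                raise ParseError("expected a restriction after 'and'", self.i + 1)
            self.next()
            axioms.append(self.parse_simple_axiom())
        return _normalize_conjunction(axioms)

    def parse_axiom_group(self) -> tuple[ClassAxiom, ...]:
        if self.peek() == "(" and self._at_axiom(1):
            self.next()
            axioms = self.parse_axiom_conjunction()
            self.expect(")")
            return tuple(axioms)
        return tuple(self.parse_axiom_conjunction())

    def parse_line(self) -> ParsedLine:
        looks_like_axiom = self._at_axiom() or (
            self.peek() == "(" and self._at_axiom(1)
        )
        if not looks_like_axiom:
            expr = self.parse_expression()
            self._expect_end()
            return expr
        groups = [self.parse_axiom_group()]
        while self.peek() == "or":
            self.next()
            groups.append(self.parse_axiom_group())
        self._expect_end()
        if len(groups) > 1:
            return DisjunctiveAxiom(branches=tuple(groups))
        axioms = list(groups[0])
        return axioms[0] if len(axioms) == 1 else axioms

    def _expect_end(self) -> None:
        if self.peek() is not None:
            raise ParseError(f"trailing input {self.peek()!r}", self.i)


def _normalize_conjunction(axioms: list[ClassAxiom]) -> list[ClassAxiom]:
    """Merge ``R only F`` + ``R some F`` pairs into ``only_and_some``."""
    out: list[ClassAxiom] = []
    for ax in axioms:
        merged = False
        for idx, prev in enumerate(out):
            if prev.relation == ax.relation and prev.filler == ax.filler:
                kinds = {prev.kind, ax.kind}
                if kinds == {"only", "some"}:
                    out[idx] = ClassAxiom(ax.relation, "only_and_some", ax.filler)
                    merged = True
                    break
                if prev.kind == ax.kind:  # duplicate conjunct
                    merged = True
                    break
        if not merged:
            out.append(ax)
    return out


def parse_class_expression(text: str) -> ParsedLine:
    """Parse one subclass line of the restriction grammar.

    Returns a bare :class:`ClassExpression` (e.g. for a parent atom), a
    single :class:`ClassAxiom`, a list of axioms for a conjunction, or a
    :class:`DisjunctiveAxiom` for a disjunction of restriction groups.
    ``R only F and R some F`` normalizes to one ``only_and_some`` axiom.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ParseError("empty expression", 0)
    return _Parser(tokens).parse_line()


# --------------------------------------------------------------------------
# serialization of expressions / axioms

def serialize_expression(expr: ClassExpression) -> str:
    if expr.kind == "atom":
        return expr.atom  # type: ignore[return-value]
    sep = f" {expr.kind} "
    parts = [
        serialize_expression(c) if c.kind == "atom" else f"({serialize_expression(c)})"
        for c in expr.children
    ]
    return sep.join(parts)


def _filler_text(filler: ClassExpression) -> str:
    s = serialize_expression(filler)
    return s if filler.kind == "atom" else f"({s})"


def serialize_axiom(ax: Axiom) -> str:
    """Render an axiom back into the grammar; inverse of the parser."""
    if isinstance(ax, DisjunctiveAxiom):
        return " or ".join(
            "(" + " and ".join(serialize_axiom(a) for a in branch) + ")"
            for branch in ax.branches
        )
    f = _filler_text(ax.filler)
    if ax.kind == "only_and_some":
        return f"{ax.relation} only {f} and {ax.relation} some {f}"
    return f"{ax.relation} {ax.kind} {f}"


# --------------------------------------------------------------------------
# canonical text dialect

_META_RE = re.compile(r'^Meta:\s*(\S+)\s+"(.*)"\s*$')
_ANNOT_RE = re.compile(r'^Annotation:\s*(\S+)\s+"(.*)"\s*$')


def _norm_ws(text: str) -> str:
    return " ".join(text.split())


def serialize_kb(kb: KnowledgeBase) -> str:
    """Deterministic canonical text for a KB (sorted blocks and fields)."""
    lines: list[str] = []
    for key in sorted(kb.metadata):
        lines.append(f'Meta: {key} "{kb.metadata[key]}"')
    if kb.metadata:
        lines.append("")
    for eid in sorted(kb.externals):
        ref = kb.externals[eid]
        lines.append(
            f"External: {ref.id}\t{ref.source}\t{ref.label}\t{ref.parent_hint}"
        )
    if kb.externals:
        lines.append("")
    own_ids = {c.id for c in kb.own_classes()}
    # pillar roots are bootstrapped, but serialize them when they carry
    # content (axioms, annotations, ...) so loaded definitions round-trip
    for root in ROOT_PILLARS:
        cls = kb.classes[root]
        if (
            cls.axioms
            or cls.annotations
            or cls.description
            or cls.alt_labels
            or cls.parents
            or cls.label != root.replace("_", " ")
        ):
            own_ids.add(root)
    for cid in sorted(own_ids):
        cls = kb.classes[cid]
        lines.append(f"Class: {cls.id}")
        lines.append(f"Pillar: {cls.pillar}")
        if cls.label:
            lines.append(f"Label: {cls.label}")
        for alt in sorted(cls.alt_labels):
            lines.append(f"AltLabel: {alt}")
        if cls.description:
            lines.append(f"Description: {_norm_ws(cls.description)}")
        for parent in sorted(cls.parents):
            lines.append(f"Parent: {parent}")
        for ax_line in sorted(serialize_axiom(ax) for ax in cls.axioms):
            lines.append(f"SubClassOf: {ax_line}")
        for key in sorted(cls.annotations):
            lines.append(f'Annotation: {key} "{cls.annotations[key]}"')
        lines.append("")
    return "\n".join(lines).rstrip("\n") + "\n"


def parse_kb(text: str) -> KnowledgeBase:
    """Parse the canonical dialect into a KnowledgeBase.

    Class blocks may appear in any order; insertion is deferred until all
    parents are known. Structural problems short of a parse failure (e.g.
    an axiom whose relation does not fit the class pillar) are collected on
    ``kb.load_warnings`` rather than aborting the load.
    """
    kb = KnowledgeBase()
    blocks: list[dict] = []
    current: Optional[dict] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("Meta:"):
            m = _META_RE.match(line)
            if not m:
                raise ParseError(f"bad Meta line {lineno}: {line!r}", lineno)
            kb.metadata[m.group(1)] = m.group(2)
        elif line.startswith("External:"):
            fields = line[len("External:"):].strip().split("\t")
            if len(fields) < 3:
                raise ParseError(f"bad External line {lineno}", lineno)
            eid, source, label = fields[0], fields[1], _norm_ws(fields[2])
            parent = fields[3].strip() if len(fields) > 3 else ""
            kb.add_external(ExternalTermRef(eid, source, label, parent))
        elif line.startswith("Class:"):
            current = {
                "id": line[len("Class:"):].strip(),
                "pillar": "dysplasia",
                "label": "",
                "alt_labels": [],
                "description": "",
                "parents": [],
                "axioms": [],
                "annotations": {},
            }
            blocks.append(current)
        elif current is not None and line.startswith("Pillar:"):
            current["pillar"] = line[len("Pillar:"):].strip()
        elif current is not None and line.startswith("Label:"):
            current["label"] = _norm_ws(line[len("Label:"):])
        elif current is not None and line.startswith("AltLabel:"):
            current["alt_labels"].append(_norm_ws(line[len("AltLabel:"):]))
        elif current is not None and line.startswith("Description:"):
            current["description"] = _norm_ws(line[len("Description:"):])
        elif current is not None and line.startswith("Parent:"):
            current["parents"].append(line[len("Parent:"):].strip())
        elif current is not None and line.startswith("SubClassOf:"):
            parsed = parse_class_expression(line[len("SubClassOf:"):].strip())
            if isinstance(parsed, ClassExpression):
                if parsed.kind != "atom":
                    raise ParseError(
                        f"bare boolean expression is not a valid subclass line "
                        f"(line {lineno})",
                        lineno,
                    )
                current["parents"].append(parsed.atom)
            elif isinstance(parsed, list):
                current["axioms"].extend(parsed)
            else:
                current["axioms"].append(parsed)
        elif current is not None and line.startswith("Annotation:"):
            m = _ANNOT_RE.match(line)
            if not m:
                raise ParseError(f"bad Annotation line {lineno}: {line!r}", lineno)
            current["annotations"][m.group(1)] = m.group(2)
        else:
            raise ParseError(f"unrecognized line {lineno}: {line!r}", lineno)

    _insert_blocks(kb, blocks)
    _canonicalize_atoms(kb)

    from .axiom_validator import check_tbox  # local import: validator layers above

    kb.load_warnings = [str(v) for v in check_tbox(kb)]
    return kb


def _canonicalize_atoms(kb: KnowledgeBase) -> None:
    """Rewrite axiom atoms to resolved ids (e.g. HP_0000238 -> HP:HP_0000238).

    Printed fragments drop source prefixes; storing the resolved form makes
    canonical and OWL loads of the same content structurally equal.
    Unresolvable atoms are left as written (reported by the TBox check).
    """

    def rewrite(expr: ClassExpression) -> ClassExpression:
        if expr.kind == "atom":
            rid = kb.resolve(expr.atom)
            return atom(rid) if rid else expr
        return ClassExpression(
            expr.kind, children=tuple(rewrite(c) for c in expr.children)
        )

    def rewrite_axiom(ax):
        if isinstance(ax, DisjunctiveAxiom):
            return DisjunctiveAxiom(
                branches=tuple(
                    tuple(rewrite_axiom(a) for a in branch) for branch in ax.branches
                )
            )
        return ClassAxiom(ax.relation, ax.kind, rewrite(ax.filler))

    for cls in kb.classes.values():
        cls.axioms = [rewrite_axiom(ax) for ax in cls.axioms]


def _merge_root_block(kb: KnowledgeBase, blk: dict) -> None:
    """Blocks redefining a bootstrapped pillar root update it in place."""
    root = kb.classes[blk["id"]]
    if blk["label"]:
        root.label = blk["label"]
    root.alt_labels = blk["alt_labels"] or root.alt_labels
    root.description = blk["description"] or root.description
    root.parents = [normalize_term_id(p) for p in blk["parents"]] or root.parents
    root.axioms = blk["axioms"] or root.axioms
    root.annotations.update(blk["annotations"])


def _insert_blocks(kb: KnowledgeBase, blocks: list[dict]) -> None:
    pending = []
    for blk in blocks:
        if normalize_term_id(blk["id"]) in ROOT_PILLARS:
            _merge_root_block(kb, blk)
        else:
            pending.append(blk)
    while pending:
        progressed = False
        remaining = []
        for blk in pending:
            if all(
                normalize_term_id(p) in kb.classes
                or normalize_term_id(p) in kb.externals
                for p in blk["parents"]
            ):
                kb.add_class(ClassDef(**blk))
                progressed = True
            else:
                remaining.append(blk)
        if not progressed:
            missing = sorted(
                p
                for blk in remaining
                for p in blk["parents"]
                if normalize_term_id(p) not in kb.classes
                and normalize_term_id(p) not in kb.externals
            )
            raise ParseError(f"dangling parents: {missing}", 0)
        pending = remaining


def write_kb(kb: KnowledgeBase, path: str) -> str:
    """Write the canonical dialect; returns the serialized document."""
    doc = serialize_kb(kb)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(doc)
    return doc


# --------------------------------------------------------------------------
# external-term TSV table

def write_external_table(kb: KnowledgeBase, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tsource\tlabel\tparent_hint\n")
        for eid in sorted(kb.externals):
            ref = kb.externals[eid]
            fh.write(f"{ref.id}\t{ref.source}\t{ref.label}\t{ref.parent_hint}\n")


def load_external_table(path: str) -> list[ExternalTermRef]:
    refs = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ParseError("external table must start with an 'id' header", 0)
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            parent = fields[3] if len(fields) > 3 else ""
            refs.append(ExternalTermRef(fields[0], fields[1], fields[2], parent))
    return refs


# --------------------------------------------------------------------------
# OWL (Turtle / RDF-XML) ingestion

BDO_NS = "http://purl.org/skeletome/bonedysplasia#"
SKOS = Namespace("http://www.w3.org/2004/02/skos/core#")

#: Namespaces whose terms map to a fixed external source.
_NS_SOURCES = {
    "http://purl.org/sig/ont/fma/": "FMA",
    "http://sig.biostr.washington.edu/fma#": "FMA",
    "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#": "NCI",
    "http://d-reams.org/reams#": "REAMS",
    "http://www.ifomis.org/bfo/1.1/snap#": "snap",
}

_LOCAL_SOURCE_RE = re.compile(
    r"^(HP|PATO|FMA|NCI|REAMS|UO|OMIM|UMLS|OGMS)[_:]", re.IGNORECASE
)


def _local_name(uri: str) -> str:
    for sep in ("#", "/"):
        if sep in uri:
            uri = uri.rsplit(sep, 1)[1]
    return uri


def _external_identity(uri: str) -> Optional[tuple[str, str]]:
    """Map an external class URI to (id, source), or None if unrecognized."""
    local = _local_name(uri)
    for ns, source in _NS_SOURCES.items():
        if uri.startswith(ns):
            return f"{source}:{local}", source
    m = _LOCAL_SOURCE_RE.match(local)
    if m:
        source = m.group(1).upper()
        if source in EXTERNAL_SOURCES:
            return f"{source}:{local}", source
    return None


def load_kb(path: str, format: str = "canonical") -> KnowledgeBase:
    """Load a KB from the canonical dialect or an OWL file.

    ``format`` is one of ``canonical``, ``turtle``, ``rdfxml``. The OWL
    path is read-only ingestion: restriction nodes become axioms, classes
    outside the ontology namespace become external term references and
    their ``rdfs:subClassOf`` links become parent hints.
    """
    if format == "canonical":
        with open(path, encoding="utf-8") as fh:
            return parse_kb(fh.read())
    if format not in ("turtle", "rdfxml"):
        raise ValueError(f"unknown format {format!r}")
    graph = rdflib.Graph()
    graph.parse(path, format="turtle" if format == "turtle" else "xml")
    return _kb_from_graph(graph)


def _expr_from_node(graph: rdflib.Graph, node, resolve_atom) -> ClassExpression:
    if isinstance(node, rdflib.URIRef):
        return atom(resolve_atom(node))
    for prop, kind in ((OWL.unionOf, disj), (OWL.intersectionOf, conj)):
        head = graph.value(node, prop)
        if head is not None:
            members = [
                _expr_from_node(graph, m, resolve_atom)
                for m in graph.items(head)
            ]
            return kind(*members)
    raise ParseError(f"unsupported filler node {node!r}", 0)


def _axioms_from_node(graph: rdflib.Graph, node, resolve_atom) -> list[ClassAxiom]:
    """Flatten a restriction or an intersection of restrictions."""
    if (node, RDF.type, OWL.Restriction) in graph:
        prop = graph.value(node, OWL.onProperty)
        rel = _local_name(str(prop))
        only = graph.value(node, OWL.allValuesFrom)
        some = graph.value(node, OWL.someValuesFrom)
        out = []
        if only is not None:
            out.append(
                ClassAxiom(rel, "only", _expr_from_node(graph, only, resolve_atom))
            )
        if some is not None:
            out.append(
                ClassAxiom(rel, "some", _expr_from_node(graph, some, resolve_atom))
            )
        return out
    head = graph.value(node, OWL.intersectionOf)
    if head is not None:
        out = []
        for member in graph.items(head):
            out.extend(_axioms_from_node(graph, member, resolve_atom))
        return out
    raise ParseError(f"unsupported axiom node {node!r}", 0)


def _kb_from_graph(graph: rdflib.Graph) -> KnowledgeBase:
    kb = KnowledgeBase()
    warnings: list[str] = []

    own_uris: dict[rdflib.URIRef, str] = {}
    external_uris: dict[rdflib.URIRef, tuple[str, str]] = {}
    for s in set(graph.subjects(RDF.type, OWL.Class)):
        if not isinstance(s, rdflib.URIRef):
            continue
        uri = str(s)
        if uri.startswith(BDO_NS):
            own_uris[s] = normalize_term_id(_local_name(uri))
        else:
            ident = _external_identity(uri)
            if ident is None:
                warnings.append(f"unrecognized external class {uri}")
            else:
                external_uris[s] = ident

    def resolve_atom(uriref: rdflib.URIRef) -> str:
        if uriref in own_uris:
            return own_uris[uriref]
        if uriref in external_uris:
            return external_uris[uriref][0]
        ident = _external_identity(str(uriref))
        return ident[0] if ident else _local_name(str(uriref))

    # external refs: label + subClassOf parent hint
    for s, (eid, source) in external_uris.items():
        label = graph.value(s, RDFS.label)
        parent_hint = ""
        for parent in graph.objects(s, RDFS.subClassOf):
            if isinstance(parent, rdflib.URIRef) and parent in external_uris:
                parent_hint = external_uris[parent][0]
                break
        kb.add_external(
            ExternalTermRef(
                eid, source, _norm_ws(str(label)) if label else eid, parent_hint
            )
        )

    # own classes: gather parents / axioms / annotations
    blocks: dict[str, dict] = {}
    parent_edges: dict[str, list[str]] = {}
    for s, cid in own_uris.items():
        blk = {
            "id": cid,
            "pillar": ROOT_PILLARS.get(cid, ""),
            "label": "",
            "alt_labels": [],
            "description": "",
            "parents": [],
            "axioms": [],
            "annotations": {},
        }
        label = graph.value(s, RDFS.label)
        if label:
            blk["label"] = _norm_ws(str(label))
        blk["alt_labels"] = sorted(
            _norm_ws(str(v)) for v in graph.objects(s, SKOS.altLabel)
        )
        desc = graph.value(s, SKOS.description)
        if desc:
            blk["description"] = _norm_ws(str(desc))
        for p, o in graph.predicate_objects(s):
            key = _local_name(str(p))
            if key in ANNOTATION_KEYS and isinstance(o, rdflib.Literal):
                blk["annotations"][key] = str(o)
        axiom_lines: list[str] = []
        for obj in graph.objects(s, RDFS.subClassOf):
            if isinstance(obj, rdflib.URIRef):
                if obj in own_uris:
                    blk["parents"].append(own_uris[obj])
                elif obj in external_uris:
                    blk["parents"].append(external_uris[obj][0])
                # upper-level (BFO/OGMS) parents are rooting metadata; skip
                continue
            # bnode: restriction, intersection of restrictions, or union
            union_head = graph.value(obj, OWL.unionOf)
            if union_head is not None and (obj, RDF.type, OWL.Restriction) not in graph:
                branches = []
                for member in graph.items(union_head):
                    branch = _normalize_conjunction(
                        _axioms_from_node(graph, member, resolve_atom)
                    )
                    branches.append(tuple(branch))
                ax: Axiom = DisjunctiveAxiom(branches=tuple(branches))
                axiom_lines.append(serialize_axiom(ax))
                blk["axioms"].append(ax)
            else:
                merged = _normalize_conjunction(
                    _axioms_from_node(graph, obj, resolve_atom)
                )
                for a in merged:
                    axiom_lines.append(serialize_axiom(a))
                    blk["axioms"].append(a)
        # deterministic axiom order regardless of triple iteration order
        order = sorted(range(len(axiom_lines)), key=lambda i: axiom_lines[i])
        blk["axioms"] = [blk["axioms"][i] for i in order]
        blk["parents"] = sorted(set(blk["parents"]))
        blocks[cid] = blk
        parent_edges[cid] = [p for p in blk["parents"]]

    _assign_pillars(blocks, parent_edges, warnings)
    _insert_blocks(kb, [blocks[c] for c in sorted(blocks)])
    _canonicalize_atoms(kb)

    # ontology metadata (DublinCore on the ontology node)
    for s in graph.subjects(RDF.type, OWL.Ontology):
        for p, o in graph.predicate_objects(s):
            key = _local_name(str(p))
            if key in ("title", "creator", "contributor", "publisher", "versionInfo"):
                kb.metadata["version" if key == "versionInfo" else f"dc:{key}"] = str(o)

    from .axiom_validator import check_tbox

    kb.load_warnings = warnings + [str(v) for v in check_tbox(kb)]
    return kb


def _assign_pillars(blocks, parent_edges, warnings) -> None:
    """Propagate pillar membership down from the pillar root classes."""
    pillar_of = dict(ROOT_PILLARS)
    changed = True
    while changed:
        changed = False
        for cid, blk in blocks.items():
            if blk["pillar"]:
                continue
            for parent in parent_edges[cid]:
                p = pillar_of.get(parent) or (
                    blocks[parent]["pillar"] if parent in blocks else None
                )
                if p:
                    blk["pillar"] = p
                    changed = True
                    break
    for cid, blk in blocks.items():
        if not blk["pillar"]:
            warnings.append(f"class {cid} unreachable from any pillar root")
            blk["pillar"] = "dysplasia"
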