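"""Entity--quality (EQ) phenotype composites.

Phenotype descriptions decompose into an anatomical entity and a quality
("Mitral valve prolapse" = *mitral valve* + *prolapsed*). Three composite
class shapes carry this model:

* ``AnatomicalComposite`` — anatomical parts (``has_part``) plus optional
  anatomical coordinates (``has_anatomical_coordinate``), e.g. "proximal
  femur";
* ``QualityComposite`` — a conjunction of qualities (``has_part``) with
  optional qualifiers (``has_qualifier``), e.g. "oval translucency";
* ``PhenotypicComposite`` — exactly one target (an anatomical entity, an
  anatomical composite, or nested phenotypic composites) combined with
  exactly one quality (a bare quality or a quality composite).

Constructors mint ``AC_``/``QC_``/``PC_`` ids with 7-digit counters and
emit the paired ``only``+``some`` restriction pattern, so generated classes
satisfy the disjunctive top-level composite definition by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .kb_model import (
    BdoError,
    ClassAxiom,
    ClassDef,
    ClassExpression,
    KnowledgeBase,
    atom,
    disj,
    normalize_term_id,
)

__all__ = [
    "AnatomicalComposite",
    "QualityComposite",
    "PhenotypicComposite",
    "Lexicon",
    "LexiconEntry",
    "Candidate",
    "Decomposition",
    "make_anatomical_composite",
    "make_quality_composite",
    "make_phenotypic_composite",
    "decompose_term",
    "compose_candidate",
]


@dataclass(frozen=True)
class AnatomicalComposite:
    id: str
    parts: tuple[str, ...]
    coordinates: tuple[str, ...]
    label: str


@dataclass(frozen=True)
class QualityComposite:
    id: str
    qualities: tuple[str, ...]
    qualifiers: tuple[str, ...]
    label: str


@dataclass(frozen=True)
class PhenotypicComposite:
    id: str
    #: one of: an anatomical entity / anatomical-composite id, or a tuple of
    #: nested phenotypic-composite ids
    target: Union[str, tuple[str, ...]]
    quality: str
    label: str
    description: str = ""


def _resolve_all(kb: KnowledgeBase, ids: Sequence[str], what: str) -> list[str]:
    out = []
    for tid in ids:
        rid = kb.resolve(tid)
        if rid is None:
            raise BdoError(f"unresolvable {what} reference {tid!r}")
        out.append(rid)
    return out


def _restriction_axioms(relation: str, fillers: Sequence[str]) -> list[ClassAxiom]:
    """Paired universal+existential axioms over one or more fillers.

    A single filler yields the printed ``R only F and R some F`` pattern;
    several fillers yield ``R only (F1 or ... or Fn)`` plus one ``some`` per
    filler.
    """
    if len(fillers) == 1:
        return [ClassAxiom(relation, "only_and_some", atom(fillers[0]))]
    axioms: list[ClassAxiom] = [
        ClassAxiom(relation, "only", disj(*[atom(f) for f in fillers]))
    ]
    axioms.extend(ClassAxiom(relation, "some", atom(f)) for f in fillers)
    return axioms


def _term_label(kb: KnowledgeBase, term_id: str) -> str:
    if term_id in kb.classes:
        return kb.classes[term_id].label or term_id
    if term_id in kb.externals:
        return kb.externals[term_id].label
    return term_id


def make_anatomical_composite(
    kb: KnowledgeBase,
    parts: Sequence[str],
    coordinates: Sequence[str] = (),
    label: str = "",
    description: str = "",
) -> AnatomicalComposite:
    """Add an anatomical composite ("proximal femur") class to the KB."""
    if not parts:
        raise BdoError("anatomical composite requires at least one part")
    part_ids = _resolve_all(kb, parts, "anatomical part")
    coord_ids = _resolve_all(kb, coordinates, "anatomical coordinate")
    cid = kb.next_composite_id("anatomical_composite")
    axioms = _restriction_axioms("has_part", part_ids)
    if coord_ids:
        axioms += _restriction_axioms("has_anatomical_coordinate", coord_ids)
    kb.add_class(
        ClassDef(
            id=cid,
            pillar="anatomical_composite",
            label=label or " ".join(_term_label(kb, p) for p in part_ids),
            description=description,
            parents=["Anatomical_Composite"],
            axioms=axioms,
        )
    )
    return AnatomicalComposite(cid, tuple(part_ids), tuple(coord_ids), kb.classes[cid].label)


def make_quality_composite(
    kb: KnowledgeBase,
    qualities: Sequence[str],
    qualifiers: Sequence[str] = (),
    label: str = "",
    description: str = "",
) -> QualityComposite:
    """Add a quality composite ("oval translucency") class to the KB."""
    if not qualities:
        raise BdoError("quality composite requires at least one quality")
    quality_ids = _resolve_all(kb, qualities, "quality")
    qualifier_ids = _resolve_all(kb, qualifiers, "qualifier")
    cid = kb.next_composite_id("quality_composite")
    axioms = _restriction_axioms("has_part", quality_ids)
    if qualifier_ids:
        axioms += _restriction_axioms("has_qualifier", qualifier_ids)
    kb.add_class(
        ClassDef(
            id=cid,
            pillar="quality_composite",
            label=label or " ".join(_term_label(kb, q) for q in quality_ids),
            description=description,
            parents=["Quality_Composite"],
            axioms=axioms,
        )
    )
    return QualityComposite(
        cid, tuple(quality_ids), tuple(qualifier_ids), kb.classes[cid].label
    )


def make_phenotypic_composite(
    kb: KnowledgeBase,
    target: Union[str, Sequence[str], None],
    quality: str,
    label: str = "",
    description: str = "",
) -> PhenotypicComposite:
    """Add a phenotypic composite class to the KB.

    ``target`` is exactly one of: an anatomical-entity reference, an
    anatomical-composite id, or a sequence of phenotypic-composite ids
    (nesting via ``has_part``). ``quality`` is a bare quality reference or
    a quality-composite id. The default label is synthesized as
    ``"<quality label> of <target label>"``.
    """
    if target is None or (not isinstance(target, str) and not target):
        raise BdoError("phenotypic composite requires a target")
    qid = kb.resolve(quality)
    if qid is None:
        raise BdoError(f"unresolvable quality reference {quality!r}")
    if qid in kb.classes and kb.classes[qid].pillar != "quality_composite":
        raise BdoError(f"{quality} is not a quality or quality composite")

    if isinstance(target, str):
        tid = kb.resolve(target)
        if tid is None:
            raise BdoError(f"unresolvable target reference {target!r}")
        if tid in kb.classes and kb.classes[tid].pillar == "phenotypic_composite":
            raise BdoError(
                "a single phenotypic composite is not a valid target; "
                "pass a sequence for has_part nesting"
            )
        axioms = _restriction_axioms("describes", [tid])
        stored_target: Union[str, tuple[str, ...]] = tid
        target_label = _term_label(kb, tid)
    else:
        part_ids = _resolve_all(kb, target, "phenotypic composite part")
        for pid in part_ids:
            if pid not in kb.classes or kb.classes[pid].pillar != "phenotypic_composite":
                raise BdoError(f"{pid} is not a phenotypic composite")
        axioms = _restriction_axioms("has_part", part_ids)
        stored_target = tuple(part_ids)
        target_label = " and ".join(_term_label(kb, p) for p in part_ids)

    axioms += _restriction_axioms("has_quality", [qid])
    cid = kb.next_composite_id("phenotypic_composite")
    kb.add_class(
        ClassDef(
            id=cid,
            pillar="phenotypic_composite",
            label=label or f"{_term_label(kb, qid)} of {target_label}",
            description=description,
            parents=["Phenotypic_Composite"],
            axioms=axioms,
        )
    )
    return PhenotypicComposite(
        cid, stored_target, qid, kb.classes[cid].label, description
    )


# ---------------------------------------------------------------------------
# label decomposition

LEXICON_KINDS = ("entity", "quality", "qualifier")


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    term_id: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in LEXICON_KINDS:
            raise BdoError(f"unknown lexicon kind {self.kind!r}")


def _norm_tokens(text: str) -> list[str]:
    return re.sub(r"[^a-z0-9 ]+", " ", text.lower()).split()


class Lexicon:
    """Surface-form → term mapping for EQ decomposition.

    Morphological variants ("prolapsed" vs "prolapse") are handled by
    listing alternate surface forms, not by lemmatization: deterministic
    and auditable at desk scale.
    """

    def __init__(self, entries: Sequence[LexiconEntry]):
        self.entries = list(entries)
        self._by_tokens = {
            tuple(_norm_tokens(e.surface)): e for e in entries if e.surface.strip()
        }
        self.max_span = max((len(k) for k in self._by_tokens), default=0)

    @classmethod
    def from_tsv(cls, path: str) -> "Lexicon":
        entries = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("surface"):
                    continue
                surface, term_id, kind = line.split("\t")[:3]
                entries.append(LexiconEntry(surface, term_id, kind))
        return cls(entries)

    def lookup(self, tokens: Sequence[str]) -> Optional[LexiconEntry]:
        return self._by_tokens.get(tuple(tokens))


@dataclass(frozen=True)
class Candidate:
    """One EQ reading of a label: entity + quality (+ optional qualifier)."""

    entity: str
    quality: str
    qualifier: Optional[str] = None


@dataclass(frozen=True)
class Decomposition:
    candidates: tuple[Candidate, ...]
    matched: tuple[LexiconEntry, ...]
    unmatched_tokens: tuple[str, ...]


def decompose_term(label: str, lexicon: Lexicon) -> Decomposition:
    """Decompose a phenotype label into EQ candidates via the lexicon.

    Greedy left-to-right longest-span matching over the normalized
    (lower-cased, punctuation-stripped) token stream; candidates are the
    cross product of matched entities and qualities, paired with each
    matched qualifier or none, ordered by match position. The empty
    candidate list is a valid result.
    """
    tokens = _norm_tokens(label)
    matched: list[LexiconEntry] = []
    unmatched: list[str] = []
    i = 0
    while i < len(tokens):
        hit = None
        for span in range(min(lexicon.max_span, len(tokens) - i), 0, -1):
            hit = lexicon.lookup(tokens[i : i + span])
            if hit is not None:
                matched.append(hit)
                i += span
                break
        if hit is None:
            unmatched.append(tokens[i])
            i += 1
    entities = [e for e in matched if e.kind == "entity"]
    qualities = [e for e in matched if e.kind == "quality"]
    qualifiers = [e for e in matched if e.kind == "qualifier"] or [None]
    candidates = tuple(
        Candidate(ent.term_id, qual.term_id, q.term_id if q else None)
        for ent in entities
        for qual in qualities
        for q in qualifiers
    )
    return Decomposition(candidates, tuple(matched), tuple(unmatched))


def compose_candidate(kb: KnowledgeBase, cand: Candidate) -> PhenotypicComposite:
    """Materialize an EQ candidate as composite classes in the KB.

    The quality (wrapped with its qualifier in a quality composite when one
    is present) is attached to the anatomical entity; the synthesized label
    follows the ``"<quality> of <target>"`` convention.
    """
    quality: str = normalize_term_id(cand.quality)
    if cand.qualifier is not None:
        qc = make_quality_composite(kb, [cand.quality], [cand.qualifier])
        quality = qc.id
    return make_phenotypic_composite(kb, cand.entity, quality)
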