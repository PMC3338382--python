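"""Decision-support analytics over the knowledge base and patient cases.

Covers the exploratory and diagnostic services a curation platform builds
on top of the ontology: per-disorder phenotype profiles, pairwise profile
overlap (the "disorders with correlated phenotypes" chart), ranked
differential diagnosis for a phenotype set, association-rule mining over
diagnosed cases with axiom-based rule refinement, and dictionary annotation
of clinical free text.

The default ranking score is the Jaccard index between the patient's
phenotype set and each disorder's profile — deterministic and scale-free; a
confidence-weighted rule-voting scorer is available as an alternative.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .axiom_validator import _characterized_by_fillers, _instance_of
from .kb_model import BdoError, ClassAxiom, KnowledgeBase, normalize_term_id

__all__ = [
    "PatientCase",
    "AssociationRule",
    "RankedDisorder",
    "AnnotationLexicon",
    "phenotype_profile",
    "overlap",
    "overlap_distribution",
    "rank_disorders",
    "mine_rules",
    "refine_rules",
    "annotate_text",
]


@dataclass
class PatientCase:
    """One anonymized case: asserted phenotype/mutation terms, optional
    ground-truth diagnosis."""

    id: str
    phenotypes: set[str] = field(default_factory=set)
    mutations: set[str] = field(default_factory=set)
    diagnosis: str = ""

    def __post_init__(self) -> None:
        self.phenotypes = {normalize_term_id(p) for p in self.phenotypes}
        self.mutations = {normalize_term_id(m) for m in self.mutations}
        self.diagnosis = normalize_term_id(self.diagnosis) if self.diagnosis else ""


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset
    consequent: str
    support: float
    confidence: float

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise BdoError("rule antecedent must be non-empty")


@dataclass(frozen=True)
class RankedDisorder:
    dysplasia: str
    score: float
    evidence: frozenset


def load_cases(path: str) -> list[PatientCase]:
    """Read a JSON array of {id, phenotypes[], mutations[], diagnosis}."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return [
        PatientCase(
            id=item["id"],
            phenotypes=set(item.get("phenotypes", [])),
            mutations=set(item.get("mutations", [])),
            diagnosis=item.get("diagnosis", "") or "",
        )
        for item in raw
    ]


def write_cases(cases: Sequence[PatientCase], path: str) -> None:
    payload = [
        {
            "id": c.id,
            "phenotypes": sorted(c.phenotypes),
            "mutations": sorted(c.mutations),
            "diagnosis": c.diagnosis,
        }
        for c in cases
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# profiles and overlap

def phenotype_profile(kb: KnowledgeBase, dysplasia: str) -> set[str]:
    """Phenotype-kind atoms of the class's own ``characterized_by`` fillers.

    Keeps HP/REAMS external terms and phenotypic-composite classes; gene
    mutation atoms are excluded. A class without a ``characterized_by``
    axiom has an empty profile.
    """
    cls = kb.get_class(dysplasia)
    profile: set[str] = set()
    for ax in cls.class_axioms():
        if ax.relation != "characterized_by":
            continue
        for a in ax.filler.atoms():
            rid = kb.resolve(a)
            if rid is None:
                continue
            if rid in kb.classes:
                if kb.classes[rid].pillar == "phenotypic_composite":
                    profile.add(rid)
            elif kb.externals[rid].source in ("HP", "REAMS"):
                profile.add(rid)
    return profile


def overlap(kb: KnowledgeBase, d1: str, d2: str) -> int:
    """Number of shared profile phenotypes; symmetric."""
    return len(phenotype_profile(kb, d1) & phenotype_profile(kb, d2))


def overlap_distribution(kb: KnowledgeBase, focus: str) -> list[tuple[str, int]]:
    """All other dysplasias sharing phenotypes with ``focus``.

    Rows (dysplasia id, overlap count) with count > 0, sorted by count
    descending then id — chart-ready.
    """
    focus_id = kb.get_class(focus).id
    focus_profile = phenotype_profile(kb, focus_id)
    rows = []
    for cls in kb.own_classes():
        if cls.pillar != "dysplasia" or cls.id == focus_id:
            continue
        n = len(focus_profile & phenotype_profile(kb, cls.id))
        if n > 0:
            rows.append((cls.id, n))
    return sorted(rows, key=lambda r: (-r[1], r[0]))


# ---------------------------------------------------------------------------
# ranking

def rank_disorders(
    kb: KnowledgeBase,
    phenotypes: Iterable[str],
    scorer: str = "jaccard",
    rules: Optional[Sequence[AssociationRule]] = None,
) -> list[RankedDisorder]:
    """Rank dysplasias against a patient phenotype set.

    ``jaccard`` (default): |P ∩ profile| / |P ∪ profile|. ``rules``: sum of
    confidences of supplied rules whose antecedent is contained in P and
    whose consequent is the disorder, normalized to [0, 1] by the largest
    sum. Only disorders with score > 0 are returned, sorted by score
    descending then id.
    """
    pset = {normalize_term_id(p) for p in phenotypes}
    if not pset:
        raise BdoError("rank_disorders requires a non-empty phenotype set")
    scores: list[RankedDisorder] = []
    if scorer == "jaccard":
        for cls in kb.own_classes():
            if cls.pillar != "dysplasia":
                continue
            profile = phenotype_profile(kb, cls.id)
            inter = pset & profile
            if not inter:
                continue
            score = len(inter) / len(pset | profile)
            scores.append(RankedDisorder(cls.id, score, frozenset(inter)))
    elif scorer == "rules":
        if rules is None:
            raise BdoError("rule-voting scorer requires mined rules")
        votes: dict[str, float] = {}
        evidence: dict[str, set[str]] = {}
        for rule in rules:
            if rule.antecedent <= pset:
                votes[rule.consequent] = votes.get(rule.consequent, 0.0) + rule.confidence
                evidence.setdefault(rule.consequent, set()).update(rule.antecedent)
        top = max(votes.values(), default=0.0)
        for d, v in votes.items():
            scores.append(RankedDisorder(d, v / top, frozenset(evidence[d])))
    else:
        raise BdoError(f"unknown scorer {scorer!r}")
    return sorted(scores, key=lambda r: (-r.score, r.dysplasia))


# ---------------------------------------------------------------------------
# association rules

def mine_rules(
    cases: Sequence[PatientCase],
    min_support: float,
    min_confidence: float,
    max_antecedent: int = 3,
) -> list[AssociationRule]:
    """Apriori mining of {phenotype set} → diagnosis rules.

    ``support`` = fraction of all cases containing both the antecedent and
    the diagnosis; ``confidence`` = that count over the antecedent count.
    Complete for antecedents up to ``max_antecedent`` items. Thresholds in
    (0, 1].
    """
    if not (0 < min_support <= 1) or not (0 < min_confidence <= 1):
        raise BdoError("thresholds must lie in (0, 1]")
    diagnosed = [c for c in cases if c.diagnosis]
    if not diagnosed:
        raise BdoError("rule mining requires diagnosed cases")
    n = len(cases)

    def support_count(itemset: frozenset) -> int:
        return sum(1 for c in cases if itemset <= c.phenotypes)

    def joint_count(itemset: frozenset, diagnosis: str) -> int:
        return sum(
            1
            for c in cases
            if c.diagnosis == diagnosis and itemset <= c.phenotypes
        )

    # level-wise frequent antecedents; supp(A ∪ {d}) <= supp(A) justifies
    # pruning on antecedent support alone
    items = sorted({p for c in cases for p in c.phenotypes})
    frequent: list[frozenset] = []
    level = [
        frozenset([i]) for i in items if support_count(frozenset([i])) / n >= min_support
    ]
    size = 1
    while level and size <= max_antecedent:
        frequent.extend(level)
        size += 1
        seen = set()
        nxt = []
        level_set = set(level)
        for a, b in itertools.combinations(level, 2):
            cand = a | b
            if len(cand) != size or cand in seen:
                continue
            seen.add(cand)
            if all(cand - {x} in level_set for x in cand) and (
                support_count(cand) / n >= min_support
            ):
                nxt.append(cand)
        level = nxt

    diagnoses = sorted({c.diagnosis for c in diagnosed})
    rules = []
    for antecedent in frequent:
        a_count = support_count(antecedent)
        for d in diagnoses:
            j = joint_count(antecedent, d)
            support = j / n
            if support < min_support or j == 0:
                continue
            confidence = j / a_count
            if confidence >= min_confidence:
                rules.append(AssociationRule(antecedent, d, support, confidence))
    return sorted(
        rules, key=lambda r: (-r.confidence, -r.support, r.consequent, sorted(r.antecedent))
    )


def refine_rules(
    kb: KnowledgeBase, rules: Sequence[AssociationRule]
) -> list[AssociationRule]:
    """Drop rules incompatible with the consequent's class axioms.

    A rule survives when every antecedent phenotype falls inside every
    applicable ``characterized_by`` only-filler of the consequent class
    (membership is subsumption-aware: a more specific patient term matches
    a more general filler atom). Never grows the rule set; idempotent.
    """
    out = []
    for rule in rules:
        if rule.consequent not in kb.classes:
            continue
        fillers = _characterized_by_fillers(kb, rule.consequent)
        if all(
            _instance_of(kb, [p], filler)
            for filler in fillers
            for p in rule.antecedent
        ):
            out.append(rule)
    return out


# ---------------------------------------------------------------------------
# text annotation

_WORD_RE = re.compile(r"[A-Za-z0-9]+")


class AnnotationLexicon:
    """Surface (label / synonym) → term-id dictionary for text annotation."""

    def __init__(self, surfaces: Mapping[str, str]):
        self._by_tokens: dict[tuple[str, ...], str] = {}
        for surface, term_id in surfaces.items():
            toks = tuple(t.lower() for t in _WORD_RE.findall(surface))
            if toks:
                self._by_tokens[toks] = term_id
        self.max_span = max((len(t) for t in self._by_tokens), default=0)

    @classmethod
    def from_tsv(cls, path: str) -> "AnnotationLexicon":
        """Rows ``term_id<TAB>surface[<TAB>surface...]``; '#' comments."""
        surfaces: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                for surface in fields[1:]:
                    if surface:
                        surfaces[surface] = fields[0]
        return cls(surfaces)

    @classmethod
    def from_kb(cls, kb: KnowledgeBase) -> "AnnotationLexicon":
        surfaces: dict[str, str] = {}
        for ref in kb.externals.values():
            surfaces[ref.label] = ref.id
        for cls_ in kb.own_classes():
            if cls_.label:
                surfaces[cls_.label] = cls_.id
            for alt in cls_.alt_labels:
                surfaces[alt] = cls_.id
        return cls(surfaces)

    def lookup(self, tokens: Sequence[str]) -> Optional[str]:
        return self._by_tokens.get(tuple(tokens))


def normalize_clinical_text(text: str) -> str:
    """Whitespace normalization applied before annotation (span basis)."""
    return " ".join(text.split())


def annotate_text(
    text: str, lexicon: AnnotationLexicon
) -> list[tuple[int, int, str]]:
    """Dictionary annotation of clinical text.

    Non-overlapping, left-to-right longest-match, case-insensitive;
    matching is word-based so punctuation between words breaks a match but
    punctuation adjacent to a word does not. Offsets are 0-based half-open
    on the whitespace-normalized text (:func:`normalize_clinical_text`).
    """
    norm = normalize_clinical_text(text)
    words = [(m.start(), m.end(), m.group(0).lower()) for m in _WORD_RE.finditer(norm)]
    spans: list[tuple[int, int, str]] = []
    i = 0
    while i < len(words):
        matched = False
        for span in range(min(lexicon.max_span, len(words) - i), 0, -1):
            window = words[i : i + span]
            # punctuation other than space between words breaks the phrase
            contiguous = all(
                norm[window[k][1] : window[k + 1][0]] == " "
                for k in range(span - 1)
            )
            if not contiguous and span > 1:
                continue
            term = lexicon.lookup([w[2] for w in window])
            if term is not None:
                spans.append((window[0][0], window[-1][1], term))
                i += span
                matched = True
                break
        if not matched:
            i += 1
    return spans
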