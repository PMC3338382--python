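"""Seeded random KBs, ABoxes, and expression trees for differential testing.

Unlike the library's fixture generator (which always emits well-formed
nosologies), these generators deliberately inject malformed constructs —
wrong-domain axioms, unresolvable atoms, range-violating fillers, dangling
parents, even subclass cycles — so that validator-versus-oracle comparisons
exercise the violating paths, not just the happy one.
"""

from __future__ import annotations

import random

from bdokit.axiom_validator import Individual
from bdokit.kb_model import (
    ClassAxiom,
    ClassDef,
    DisjunctiveAxiom,
    ExternalTermRef,
    KnowledgeBase,
    atom,
    conj,
    disj,
)

_RELS = [
    "characterized_by", "mode_of_inheritance", "has_locus", "mutation_type",
    "is_encoded_by", "describes", "has_quality", "has_qualifier",
    "has_anatomical_coordinate", "has_part",
]


def _externals(rng: random.Random, kb: KnowledgeBase) -> list[str]:
    refs = [
        ExternalTermRef("HP:HP_0000118", "HP", "Phenotypic abnormality", ""),
        ExternalTermRef("HP:HP_0000005", "HP", "Mode of inheritance", ""),
        ExternalTermRef("REAMS:Abnormality", "REAMS", "Abnormality", ""),
        ExternalTermRef("NCI:Mutation_Abnormality", "NCI", "Mutation", ""),
        ExternalTermRef("PATO:PATO_0001241", "PATO", "Quality", ""),
        ExternalTermRef("PATO:PATO_0000068", "PATO", "Qualifier", ""),
        ExternalTermRef("FMA:Anatomical_entity", "FMA", "Anatomical entity", ""),
        ExternalTermRef("FMA:Primary_anatomical_coordinate", "FMA",
                        "Primary coordinate", ""),
    ]
    # random HP terms; some chains deliberately broken or dangling
    for i in range(rng.randint(4, 10)):
        tid = f"HP:HP_{8000000 + i}"
        roll = rng.random()
        if roll < 0.6:
            parent = "HP:HP_0000118"
        elif roll < 0.75 and i > 0:
            parent = f"HP:HP_{8000000 + rng.randrange(i)}"
        elif roll < 0.85:
            parent = f"HP:HP_{8100000 + i}"  # dangling hint: chain breaks
        else:
            parent = ""  # no hint at all: open placement
        refs.append(ExternalTermRef(tid, "HP", f"Phenotype {i}", parent))
    for i in range(rng.randint(1, 3)):
        refs.append(ExternalTermRef(f"PATO:PATO_{7000000 + i}", "PATO",
                                    f"Quality {i}", "PATO:PATO_0001241"))
        refs.append(ExternalTermRef(f"FMA:Part_{i}", "FMA", f"Part {i}",
                                    "FMA:Anatomical_entity"))
    for ref in refs:
        kb.add_external(ref)
    return [r.id for r in refs]


def random_kb(seed: int) -> KnowledgeBase:
    """A small KB mixing valid structure with injected violations."""
    rng = random.Random(seed)
    kb = KnowledgeBase()
    _externals(rng, kb)
    hp_terms = [e for e in kb.externals if e.startswith("HP:HP_8")]
    pato_terms = [e for e in kb.externals if e.startswith("PATO:PATO_7")]
    fma_parts = [e for e in kb.externals if e.startswith("FMA:Part_")]

    genes = []
    for i in range(rng.randint(1, 4)):
        gid = f"G{i + 1:07d}"
        kb.add_class(ClassDef(gid, "gene", label=f"GENE{i}", parents=["Gene"]))
        genes.append(gid)

    mutations = []
    for i in range(rng.randint(1, 5)):
        mid = f"GM{i + 1:07d}"
        axioms = []
        if rng.random() < 0.85:
            axioms.append(ClassAxiom("has_locus", "only_and_some",
                                     atom(rng.choice(genes))))
        else:  # range violation: locus pointing at an HP term
            axioms.append(ClassAxiom("has_locus", "only_and_some",
                                     atom(rng.choice(hp_terms))))
        if rng.random() < 0.5:
            axioms.append(ClassAxiom("mutation_type", "only_and_some",
                                     atom("NCI:Mutation_Abnormality")))
        kb.add_class(ClassDef(mid, "gene_mutation", label=f"Mut {i}",
                              parents=["Gene_Mutation"], axioms=axioms))
        mutations.append(mid)

    composites = []
    for i in range(rng.randint(0, 3)):
        pid = f"PC_{i + 1:07d}"
        axioms = [
            ClassAxiom("describes", "only_and_some", atom(rng.choice(fma_parts))),
            ClassAxiom("has_quality", "only_and_some", atom(rng.choice(pato_terms))),
        ]
        if rng.random() < 0.15:  # domain violation on a composite
            axioms.append(ClassAxiom("mode_of_inheritance", "only",
                                     atom("HP:HP_0000005")))
        kb.add_class(ClassDef(pid, "phenotypic_composite", label=f"Comp {i}",
                              parents=["Phenotypic_Composite"], axioms=axioms))
        composites.append(pid)

    groups = []
    for i in range(rng.randint(1, 3)):
        gid = f"GRP_{i}"
        kb.add_class(ClassDef(gid, "dysplasia", label=f"Group {i}",
                              parents=["Bone_Dysplasia"]))
        groups.append(gid)

    dysplasias = []
    feature_pool = hp_terms + composites
    for i in range(rng.randint(2, 6)):
        did = f"DYS_{i}"
        features = rng.sample(feature_pool,
                              rng.randint(1, min(4, len(feature_pool))))
        if rng.random() < 0.5 and mutations:
            features += rng.sample(mutations, 1)
        if rng.random() < 0.12:  # range violation: a PATO quality as feature
            features.append(rng.choice(pato_terms))
        if rng.random() < 0.12:  # unresolvable filler atom
            features.append(f"ZZ_MISSING_{i}")
        filler = atom(features[0]) if len(features) == 1 else disj(
            *[atom(f) for f in features])
        axioms = [ClassAxiom("characterized_by", "only", filler)]
        if rng.random() < 0.6:
            axioms.append(ClassAxiom("mode_of_inheritance", "only_and_some",
                                     atom("HP:HP_0000005")))
        if rng.random() < 0.12:  # domain violation on a dysplasia
            axioms.append(ClassAxiom("has_locus", "some",
                                     atom(rng.choice(genes))))
        if rng.random() < 0.2 and len(feature_pool) >= 2:
            a, b = rng.sample(feature_pool, 2)
            axioms.append(DisjunctiveAxiom(branches=(
                (ClassAxiom("characterized_by", "some", atom(a)),),
                (ClassAxiom("characterized_by", "some", atom(b)),),
            )))
        kb.add_class(ClassDef(did, "dysplasia", label=f"Dys {i}",
                              parents=[rng.choice(groups)], axioms=axioms))
        dysplasias.append(did)

    if rng.random() < 0.1:  # dangling parent, injected past add_class checks
        kb.classes[rng.choice(dysplasias)].parents.append("ZZ_NO_SUCH_PARENT")
    if rng.random() < 0.05 and len(dysplasias) >= 2:  # subclass cycle
        a, b = rng.sample(dysplasias, 2)
        kb.classes[a].parents.append(b)
        kb.classes[b].parents.append(a)
    return kb


def random_abox(kb: KnowledgeBase, seed: int, n: int = 8) -> list[Individual]:
    """Random individuals, some well-typed and some deliberately broken."""
    rng = random.Random(seed)
    dysplasias = [c.id for c in kb.classes.values()
                  if c.pillar == "dysplasia" and c.id.startswith("DYS_")]
    mutations = [c.id for c in kb.classes.values()
                 if c.pillar == "gene_mutation"]
    hp_terms = [e for e in kb.externals if e.startswith("HP:HP_8")]
    pool = hp_terms + mutations
    out = []
    for i in range(n):
        pid = f"patient{i}"
        roll = rng.random()
        if roll < 0.1:
            out.append(Individual(pid, types=[]))
            continue
        if roll < 0.2:
            out.append(Individual(pid, types=["ZZ_UNKNOWN_TYPE"]))
            continue
        types = [rng.choice(dysplasias)] if dysplasias else ["Bone_Dysplasia"]
        links = [("characterized_by", t)
                 for t in rng.sample(pool, rng.randint(0, min(4, len(pool))))]
        if rng.random() < 0.15:
            links.append(("characterized_by", "ZZ_UNKNOWN_TARGET"))
        if rng.random() < 0.1:
            links.append(("zz_unknown_rel", rng.choice(pool)))
        out.append(Individual(pid, types=types, links=links))
    return out


# --------------------------------------------------------------------------
# random grammar instances

def random_expression(rng: random.Random, vocabulary, depth: int = 0):
    """Random expression tree over a vocabulary of atom tokens."""
    if depth >= 3 or rng.random() < 0.4:
        return atom(rng.choice(vocabulary))
    build = conj if rng.random() < 0.5 else disj
    return build(*[random_expression(rng, vocabulary, depth + 1)
                   for _ in range(rng.randint(2, 3))])


def random_axiom(rng: random.Random, vocabulary) -> ClassAxiom:
    return ClassAxiom(rng.choice(_RELS),
                      rng.choice(["only", "some", "only_and_some"]),
                      random_expression(rng, vocabulary))
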