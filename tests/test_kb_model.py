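"""Knowledge-base model: ids, graph invariants, queries, statistics."""

import random

import pytest

from bdokit.kb_model import (
    ClassAxiom,
    ClassDef,
    CycleError,
    DuplicateIdError,
    KnowledgeBase,
    PILLAR_ROOTS,
    RELATIONS,
    UnknownTermError,
    atom,
    normalize_term_id,
)

import oracles
import randkb


# --------------------------------------------------------------------------
# identifiers

@pytest.mark.parametrize(
    "raw,expected",
    [
        ("GM000001", "GM0000001"),
        ("GM0000001", "GM0000001"),
        ("GM00000001", "GM0000001"),
        ("G0000048", "G0000048"),
        ("G00048", "G0000048"),
        ("P0000007", "P0000007"),
        ("PC_0000004", "PC_0000004"),
        ("PC_000004", "PC_0000004"),
        ("AC_0000001", "AC_0000001"),
        ("QC_00001", "QC_0000001"),
        (" GM000001 ", "GM0000001"),
        ("HP:HP_0000118", "HP:HP_0000118"),  # not incremental: unchanged
        ("Achondroplasia", "Achondroplasia"),
        ("GM1", "GM1"),  # too few digits for the scheme: unchanged
    ],
)
def test_normalize_term_id(raw, expected):
    assert normalize_term_id(raw) == expected


def test_next_id_starts_at_one():
    kb = KnowledgeBase()
    assert kb.next_id("gene") == "G0000001"
    assert kb.next_id("gene_mutation") == "GM0000001"
    assert kb.next_id("protein") == "P0000001"


def test_next_id_smallest_unused():
    kb = KnowledgeBase()
    for n in (1, 2, 4):
        kb.add_class(ClassDef(f"G{n:07d}", "gene", label=f"g{n}", parents=["Gene"]))
    assert kb.next_id("gene") == "G0000003"


def test_next_id_allocates_unique_ids():
    kb = KnowledgeBase()
    seen = set()
    for i in range(500):
        gid = kb.next_id("gene")
        assert gid not in seen
        seen.add(gid)
        kb.add_class(ClassDef(gid, "gene", label=f"g{i}", parents=["Gene"]))
    assert len(seen) == 500
    assert kb.next_id("gene") == "G0000501"


def test_next_composite_id():
    kb = KnowledgeBase()
    assert kb.next_composite_id("phenotypic_composite") == "PC_0000001"
    assert kb.next_composite_id("anatomical_composite") == "AC_0000001"
    assert kb.next_composite_id("quality_composite") == "QC_0000001"
    with pytest.raises(Exception):
        kb.next_composite_id("gene")


# --------------------------------------------------------------------------
# bootstrapping and mutation of the class graph

def test_pillar_roots_bootstrapped():
    kb = KnowledgeBase()
    for pillar, root in PILLAR_ROOTS.items():
        assert root in kb.classes
        assert kb.classes[root].pillar == pillar


def test_add_class_duplicate_id():
    kb = KnowledgeBase()
    kb.add_class(ClassDef("G0000001", "gene", label="A", parents=["Gene"]))
    with pytest.raises(DuplicateIdError):
        kb.add_class(ClassDef("G0000001", "gene", label="B", parents=["Gene"]))


def test_add_class_dangling_parent():
    kb = KnowledgeBase()
    with pytest.raises(UnknownTermError):
        kb.add_class(ClassDef("G0000001", "gene", label="A", parents=["Nope"]))


def test_add_class_self_parent():
    kb = KnowledgeBase()
    with pytest.raises(CycleError):
        kb.add_class(ClassDef("G0000001", "gene", label="A",
                              parents=["G0000001"]))


def test_add_class_duplicate_label_same_pillar():
    kb = KnowledgeBase()
    kb.add_class(ClassDef("G0000001", "gene", label="FGFR3", parents=["Gene"]))
    with pytest.raises(DuplicateIdError):
        kb.add_class(ClassDef("G0000002", "gene", label="FGFR3",
                              parents=["Gene"]))
    # same label in a different pillar is allowed
    kb.add_class(ClassDef("P0000001", "protein", label="FGFR3",
                          parents=["Protein"]))


def test_move_class_rejects_cycle():
    kb = KnowledgeBase()
    kb.add_class(ClassDef("A1", "dysplasia", label="a", parents=["Bone_Dysplasia"]))
    kb.add_class(ClassDef("B1", "dysplasia", label="b", parents=["A1"]))
    with pytest.raises(CycleError):
        kb.move_class("A1", ["B1"])
    # the failed move must not have corrupted the graph
    assert kb.is_dag()
    assert kb.classes["A1"].parents == ["Bone_Dysplasia"]
    kb.move_class("B1", ["Bone_Dysplasia"])
    assert kb.classes["B1"].parents == ["Bone_Dysplasia"]


# --------------------------------------------------------------------------
# depth / groups / leaves

def _three_level_kb():
    kb = KnowledgeBase()
    kb.add_class(ClassDef("GRP", "dysplasia", label="Group",
                          parents=["Bone_Dysplasia"]))
    kb.add_class(ClassDef("DIS", "dysplasia", label="Disease", parents=["GRP"]))
    kb.add_class(ClassDef("SUB", "dysplasia", label="Subtype", parents=["DIS"]))
    return kb


def test_depth_three_levels():
    kb = _three_level_kb()
    assert kb.depth("Bone_Dysplasia") == 0
    assert kb.depth("GRP") == 1
    assert kb.depth("DIS") == 2
    assert kb.depth("SUB") == 3


def test_depth_is_longest_path():
    kb = _three_level_kb()
    # multi-parent: SUB also directly under the group -> longest path wins
    kb.move_class("SUB", ["DIS", "GRP"])
    assert kb.depth("SUB") == 3


def test_depth_errors():
    kb = _three_level_kb()
    kb.add_class(ClassDef("G0000001", "gene", label="g", parents=["Gene"]))
    with pytest.raises(UnknownTermError):
        kb.depth("G0000001")  # wrong pillar
    with pytest.raises(UnknownTermError):
        kb.depth("NoSuchClass")


def test_groups_and_leaves():
    kb = _three_level_kb()
    assert kb.groups() == {"GRP"}
    # SUB is the only leaf at depth >= 2 (DIS has a child)
    assert kb.dysplasia_leaves() == {"SUB"}


# --------------------------------------------------------------------------
# graph queries versus independent recursion oracles

@pytest.mark.parametrize("seed", range(20))
def test_graph_queries_match_oracle(seed):
    kb = randkb.random_kb(seed)
    assert kb.is_dag() == (not oracles.oracle_has_cycle(kb))
    if not kb.is_dag():
        return
    for cid in kb.classes:
        assert kb.superclasses(cid) == oracles.oracle_ancestors(kb, cid)
        assert kb.subclasses(cid) == oracles.oracle_descendants(kb, cid)
    for cls in kb.classes.values():
        if cls.pillar != "dysplasia":
            continue
        try:
            expected = oracles.oracle_depth(kb, cls.id)
        except ValueError:
            with pytest.raises(UnknownTermError):
                kb.depth(cls.id)
        else:
            assert kb.depth(cls.id) == expected


@pytest.mark.parametrize("seed", range(10))
def test_subsumes_matches_oracle(seed):
    kb = randkb.random_kb(seed)
    if not kb.is_dag():
        return
    rng = random.Random(seed)
    terms = sorted(kb.classes) + sorted(kb.externals)
    for _ in range(200):
        a, b = rng.choice(terms), rng.choice(terms)
        assert kb.subsumes(a, b) == oracles.oracle_subsumes(kb, a, b)


def test_resolve_probes_source_prefixes(printed_kb):
    assert printed_kb.resolve("HP_0000238") == "HP:HP_0000238"
    assert printed_kb.resolve("HP:HP_0000238") == "HP:HP_0000238"
    assert printed_kb.resolve("PATO_0001241") == "PATO:PATO_0001241"
    assert printed_kb.resolve("GM000001") == "GM0000001"
    assert printed_kb.resolve("NoSuchTerm") is None


def test_external_ancestry_guards_against_hint_cycles():
    from bdokit.kb_model import ExternalTermRef

    kb = KnowledgeBase()
    kb.add_external(ExternalTermRef("HP:A", "HP", "a", "HP:B"))
    kb.add_external(ExternalTermRef("HP:B", "HP", "b", "HP:A"))
    assert kb.external_ancestry("HP:A") == ["HP:A", "HP:B"]
    assert kb.external_descends("HP:A", "HP:B")
    assert not kb.external_descends("HP:A", "HP:C")


# --------------------------------------------------------------------------
# relation registry and stats

def test_relation_registry_is_complete():
    assert set(RELATIONS) == {
        "characterized_by", "mode_of_inheritance", "has_locus",
        "mutation_type", "is_encoded_by", "describes", "has_quality",
        "has_qualifier", "has_anatomical_coordinate", "has_part",
    }
    assert RELATIONS["characterized_by"].domains == frozenset({"dysplasia"})
    assert RELATIONS["has_part"].domains == frozenset(
        {"phenotypic_composite", "anatomical_composite", "quality_composite"}
    )


def test_stats_match_generator_bookkeeping(fixture_kb):
    truth = fixture_kb.generator_truth
    s = fixture_kb.stats()
    for pillar, count in truth.per_pillar.items():
        assert s.per_pillar[pillar] == count
    assert s.per_pillar["dysplasia"] == truth.n_dysplasias
    assert s.n_groups == truth.n_groups
    assert s.n_dysplasia_leaves == truth.n_leaves
    assert s.frac_mutation_linked == pytest.approx(truth.frac_mutation_linked)
    assert s.frac_phenotype_linked == pytest.approx(truth.frac_phenotype_linked)


def test_class_axioms_descend_disjunctive_branches(printed_kb):
    pc = printed_kb.classes["Phenotypic_Composite"]
    flat = list(pc.class_axioms())
    assert all(isinstance(a, ClassAxiom) for a in flat)
    # each branch's paired only/some restrictions merge to one axiom:
    # 3 branches (part/anatomy/composite) + 2 branches (quality kinds)
    assert len(flat) == 5
    assert all(a.kind == "only_and_some" for a in flat)
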