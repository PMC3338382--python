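"""Profiles, ranking, rule mining/refinement, and text annotation."""

import random

import pytest

from bdokit.analytics import (
    AnnotationLexicon,
    AssociationRule,
    PatientCase,
    annotate_text,
    load_cases,
    mine_rules,
    normalize_clinical_text,
    overlap,
    overlap_distribution,
    phenotype_profile,
    rank_disorders,
    refine_rules,
    write_cases,
)
from bdokit.kb_model import BdoError

import oracles
import randkb


# --------------------------------------------------------------------------
# profiles

def test_printed_profile_is_the_hp_terms(printed_kb):
    assert phenotype_profile(printed_kb, "Achondroplasia") == {
        "HP:HP_0000238", "HP:HP_0002938", "HP:HP_0002968", "HP:HP_0003505",
    }


def test_profile_excludes_mutations(printed_kb):
    profile = phenotype_profile(printed_kb, "Achondroplasia")
    assert not any(p.startswith("GM") for p in profile)


def test_profile_empty_without_axiom(printed_kb):
    assert phenotype_profile(printed_kb, "Bone_Dysplasia") != set()  # root has one
    assert phenotype_profile(printed_kb, "G0000001") == set()


def test_fixture_profiles_match_generator_truth(fixture_kb):
    truth = fixture_kb.generator_truth
    for leaf, expected in truth.profiles.items():
        assert phenotype_profile(fixture_kb, leaf) == set(expected)


@pytest.mark.parametrize("seed", range(10))
def test_profile_matches_oracle(seed):
    kb = randkb.random_kb(seed)
    for cls in kb.classes.values():
        if cls.pillar == "dysplasia":
            assert phenotype_profile(kb, cls.id) == \
                oracles.oracle_profile(kb, cls.id)


def test_overlap_symmetric(fixture_kb):
    leaves = sorted(fixture_kb.generator_truth.profiles)[:10]
    for a in leaves:
        for b in leaves:
            assert overlap(fixture_kb, a, b) == overlap(fixture_kb, b, a)


def test_overlap_distribution_sorted_and_positive(fixture_kb):
    focus = sorted(fixture_kb.generator_truth.profiles)[0]
    rows = overlap_distribution(fixture_kb, focus)
    focus_profile = phenotype_profile(fixture_kb, focus)
    assert all(n > 0 for _, n in rows)
    assert rows == sorted(rows, key=lambda r: (-r[1], r[0]))
    for other, n in rows:
        assert len(focus_profile & phenotype_profile(fixture_kb, other)) == n
        assert other != focus


# --------------------------------------------------------------------------
# ranking

def test_rank_printed_patient(printed_kb):
    ranked = rank_disorders(printed_kb, ["HP:HP_0000238"])
    assert ranked[0].dysplasia == "Achondroplasia"
    # 1 shared / 4 profile terms = 0.25
    assert ranked[0].score == pytest.approx(0.25)
    assert ranked[0].evidence == frozenset({"HP:HP_0000238"})


def test_rank_requires_phenotypes(printed_kb):
    with pytest.raises(BdoError):
        rank_disorders(printed_kb, [])


def test_rank_excludes_zero_scores(printed_kb):
    ranked = rank_disorders(printed_kb, ["PATO:PATO_0001354"])
    assert ranked == []


@pytest.mark.parametrize("seed", range(10))
def test_rank_matches_oracle(seed):
    kb = randkb.random_kb(seed)
    rng = random.Random(seed)
    hp_terms = [e for e in kb.externals if e.startswith("HP:HP_8")]
    pset = rng.sample(hp_terms, min(3, len(hp_terms)))
    got = [(r.dysplasia, r.score) for r in rank_disorders(kb, pset)]
    want = [(d, pytest.approx(s)) for d, s in oracles.oracle_rank_jaccard(kb, pset)]
    assert got == want


def test_rank_with_rule_votes(printed_kb):
    rules = [
        AssociationRule(frozenset({"HP:HP_0000238"}), "Achondroplasia", 0.5, 0.8),
        AssociationRule(frozenset({"HP:HP_0002968"}), "Achondroplasia", 0.5, 0.6),
        AssociationRule(frozenset({"HP:HP_0000238"}), "OtherDys", 0.2, 0.7),
    ]
    ranked = rank_disorders(printed_kb, ["HP:HP_0000238", "HP:HP_0002968"],
                            scorer="rules", rules=rules)
    assert ranked[0].dysplasia == "Achondroplasia"
    assert ranked[0].score == pytest.approx(1.0)  # normalized to the top vote
    assert ranked[1].score == pytest.approx(0.7 / 1.4)


def test_rank_unknown_scorer(printed_kb):
    with pytest.raises(BdoError):
        rank_disorders(printed_kb, ["HP:HP_0000238"], scorer="zscore")


# --------------------------------------------------------------------------
# rule mining

def _toy_cases():
    # 5 cases; {A} -> D1 holds in 4/5 of the A-cases
    return [
        PatientCase("c1", {"HP:A", "HP:B"}, diagnosis="D1"),
        PatientCase("c2", {"HP:A"}, diagnosis="D1"),
        PatientCase("c3", {"HP:A", "HP:C"}, diagnosis="D1"),
        PatientCase("c4", {"HP:A", "HP:B"}, diagnosis="D2"),
        PatientCase("c5", {"HP:B"}, diagnosis="D1"),
    ]


def test_mine_rules_hand_computed():
    rules = mine_rules(_toy_cases(), min_support=0.4, min_confidence=0.7)
    by_key = {(tuple(sorted(r.antecedent)), r.consequent): r for r in rules}
    rule = by_key[(("HP:A",), "D1")]
    assert rule.support == pytest.approx(3 / 5)
    assert rule.confidence == pytest.approx(3 / 4)


def test_mine_rules_respects_thresholds():
    rules = mine_rules(_toy_cases(), min_support=0.61, min_confidence=0.5)
    assert rules == []  # best joint support is 3/5


def test_mine_rules_max_antecedent():
    rules = mine_rules(_toy_cases(), min_support=0.2, min_confidence=0.1,
                       max_antecedent=1)
    assert all(len(r.antecedent) == 1 for r in rules)


def test_mine_rules_threshold_validation():
    for bad in ((0.0, 0.5), (0.5, 0.0), (1.1, 0.5), (0.5, 1.1)):
        with pytest.raises(BdoError):
            mine_rules(_toy_cases(), *bad)


def test_mine_rules_requires_diagnosed_cases():
    with pytest.raises(BdoError):
        mine_rules([PatientCase("c", {"HP:A"})], 0.5, 0.5)


def _random_cohort(seed, n_cases, n_items=6):
    rng = random.Random(seed)
    items = [f"HP:HP_90{i:05d}" for i in range(n_items)]
    out = []
    for i in range(n_cases):
        phen = set(rng.sample(items, rng.randint(1, 4)))
        diag = f"DYS_{rng.randint(0, 2)}" if rng.random() < 0.9 else ""
        out.append(PatientCase(f"c{i}", phen, diagnosis=diag))
    return out


@pytest.mark.parametrize("seed", range(15))
def test_miner_matches_exhaustive_enumeration(seed):
    rng = random.Random(seed + 100)
    cases = _random_cohort(seed, rng.randint(5, 15))
    if not any(c.diagnosis for c in cases):
        return
    min_s, min_c = rng.choice([(0.1, 0.5), (0.2, 0.7), (0.34, 0.34)])
    got = mine_rules(cases, min_s, min_c)
    want = oracles.oracle_mine_rules(cases, min_s, min_c)
    assert [(r.antecedent, r.consequent) for r in got] == \
        [(a, d) for a, d, _, _ in want]
    for r, (_, _, s, c) in zip(got, want):
        assert r.support == pytest.approx(s)
        assert r.confidence == pytest.approx(c)


# --------------------------------------------------------------------------
# rule refinement

def test_refine_drops_off_profile_rules(fixture_kb):
    truth = fixture_kb.generator_truth
    leaf, profile = next(
        (l, p) for l, p in sorted(truth.profiles.items()) if p)
    good = AssociationRule(frozenset(list(profile)[:1]), leaf, 0.5, 0.9)
    off = sorted(set(truth.phenotype_pool) - set(profile))[0]
    bad = AssociationRule(frozenset({off}), leaf, 0.5, 0.9)
    kept = refine_rules(fixture_kb, [good, bad])
    assert kept == [good]


def test_refine_drops_unknown_consequent(fixture_kb):
    rule = AssociationRule(frozenset({"HP:HP_9000001"}), "ZZ_NOT_A_CLASS",
                           0.5, 0.9)
    assert refine_rules(fixture_kb, [rule]) == []


def test_refine_idempotent_and_never_grows(fixture_kb, cohort):
    rules = mine_rules(cohort, min_support=0.01, min_confidence=0.5)
    refined = refine_rules(fixture_kb, rules)
    assert len(refined) <= len(rules)
    assert refine_rules(fixture_kb, refined) == refined


@pytest.mark.parametrize("seed", range(10))
def test_refine_matches_subset_oracle(seed):
    kb = randkb.random_kb(seed)
    hp_terms = sorted(e for e in kb.externals if e.startswith("HP:HP_8"))
    dysplasias = sorted(c.id for c in kb.classes.values()
                        if c.pillar == "dysplasia")
    rng = random.Random(seed)
    rules = [
        AssociationRule(
            frozenset(rng.sample(hp_terms, rng.randint(1, 2))),
            rng.choice(dysplasias + ["ZZ_MISSING"]), 0.5, 0.9)
        for _ in range(20)
    ]
    kept = refine_rules(kb, rules)
    want = [r for r in rules
            if oracles.oracle_refine_keep(kb, r.antecedent, r.consequent)]
    assert kept == want


# --------------------------------------------------------------------------
# case persistence

def test_cases_round_trip(tmp_path, cohort):
    path = tmp_path / "cases.json"
    write_cases(cohort, str(path))
    again = load_cases(str(path))
    assert again == list(cohort)


# --------------------------------------------------------------------------
# text annotation

_SURFACES = {
    "hydrocephalus": "HP:HP_0000238",
    "disproportionate short stature": "HP:HP_0003505",
    "rhizomelia": "HP:HP_0002968",
    "short stature": "HP:ZZ_SHORT",
}


def test_annotate_simple_sentence():
    lex = AnnotationLexicon(_SURFACES)
    text = "Patient presents with hydrocephalus and rhizomelia."
    spans = annotate_text(text, lex)
    norm = normalize_clinical_text(text)
    assert [(norm[s:e], t) for s, e, t in spans] == [
        ("hydrocephalus", "HP:HP_0000238"),
        ("rhizomelia", "HP:HP_0002968"),
    ]


def test_annotate_prefers_longest_match():
    lex = AnnotationLexicon(_SURFACES)
    spans = annotate_text("disproportionate short stature noted", lex)
    assert [t for _, _, t in spans] == ["HP:HP_0003505"]


def test_annotate_case_insensitive_and_punctuation_adjacent():
    lex = AnnotationLexicon(_SURFACES)
    spans = annotate_text("Findings: HYDROCEPHALUS, (short stature).", lex)
    assert [t for _, _, t in spans] == ["HP:HP_0000238", "HP:ZZ_SHORT"]


def test_annotate_punctuation_between_words_breaks_match():
    lex = AnnotationLexicon(_SURFACES)
    spans = annotate_text("short, stature", lex)
    assert spans == []


def test_annotate_offsets_on_normalized_text():
    lex = AnnotationLexicon(_SURFACES)
    text = "  rhizomelia\n\n  and   hydrocephalus "
    norm = normalize_clinical_text(text)
    assert norm == "rhizomelia and hydrocephalus"
    spans = annotate_text(text, lex)
    assert [(norm[s:e]) for s, e, _ in spans] == ["rhizomelia", "hydrocephalus"]


def test_annotate_constructive_oracle():
    """Build text from known surfaces + filler; every surface is recovered."""
    rng = random.Random(7)
    surfaces = list(_SURFACES)
    fillers = ["the", "patient", "shows", "signs", "of", "marked"]
    for _ in range(25):
        picked = rng.sample(surfaces, rng.randint(1, 3))
        words: list[str] = []
        expected = []
        for s in picked:
            words.extend(rng.sample(fillers, rng.randint(1, 3)))
            words.append(s + ".")
            expected.append(_SURFACES[s])
        text = " ".join(words)
        # "short stature" may shadow nothing here since fillers are disjoint
        got = [t for _, _, t in annotate_text(text, AnnotationLexicon(_SURFACES))]
        assert got == expected


def test_annotation_lexicon_from_kb(printed_kb):
    lex = AnnotationLexicon.from_kb(printed_kb)
    spans = annotate_text("Diagnosis is achondroplasia with hydrocephalus",
                          lex)
    assert [t for _, _, t in spans] == ["Achondroplasia", "HP:HP_0000238"]


def test_annotation_lexicon_from_tsv(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(
        "HP:HP_0000238\tHydrocephalus\twater on the brain\n"
        "# comment line\n"
        "HP:HP_0002968\tRhizomelia\n",
        encoding="utf-8",
    )
    lex = AnnotationLexicon.from_tsv(str(path))
    spans = annotate_text("water on the brain and rhizomelia", lex)
    assert [t for _, _, t in spans] == ["HP:HP_0000238", "HP:HP_0002968"]
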