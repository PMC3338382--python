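"""Shared fixtures: the canonical published class definitions, a seeded
synthetic KB + cohort, and a test-only OWL exporter used to exercise the
read-only OWL loader."""

import pytest
import rdflib
from rdflib import BNode, Literal, Namespace, OWL, RDF, RDFS, URIRef
from rdflib.collection import Collection

from bdokit import fixtures, owl_io
from bdokit.kb_model import ClassAxiom, DisjunctiveAxiom, ROOT_PILLARS

BDO = Namespace(owl_io.BDO_NS)
SKOS = Namespace("http://www.w3.org/2004/02/skos/core#")
DCT = Namespace("http://purl.org/dc/terms/")

_SOURCE_NS = {
    "FMA": "http://purl.org/sig/ont/fma/",
    "NCI": "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#",
    "REAMS": "http://d-reams.org/reams#",
    "snap": "http://www.ifomis.org/bfo/1.1/snap#",
}


def _ext_uri(ref):
    local = ref.id.split(":", 1)[1]
    ns = _SOURCE_NS.get(ref.source, "http://purl.obolibrary.org/obo/")
    return URIRef(ns + local)


def kb_to_graph(kb):
    """Synthetic OWL export of a KB (test helper, not a library feature)."""
    g = rdflib.Graph()
    uri_of = {}
    for ref in kb.externals.values():
        uri_of[ref.id] = _ext_uri(ref)
    for cid in kb.classes:
        uri_of[cid] = BDO[cid]

    def expr_node(expr):
        if expr.kind == "atom":
            return uri_of[kb.resolve(expr.atom)]
        node = BNode()
        g.add((node, RDF.type, OWL.Class))
        members = [expr_node(c) for c in expr.children]
        head = BNode()
        Collection(g, head, members)
        prop = OWL.unionOf if expr.kind == "or" else OWL.intersectionOf
        g.add((node, prop, head))
        return node

    def restriction(rel, quantifier, filler):
        node = BNode()
        g.add((node, RDF.type, OWL.Restriction))
        g.add((node, OWL.onProperty, BDO[rel]))
        g.add((node, quantifier, expr_node(filler)))
        return node

    def axiom_node(ax):
        if isinstance(ax, DisjunctiveAxiom):
            node = BNode()
            g.add((node, RDF.type, OWL.Class))
            members = [conjunction_node(list(branch)) for branch in ax.branches]
            head = BNode()
            Collection(g, head, members)
            g.add((node, OWL.unionOf, head))
            return node
        return conjunction_node([ax])

    def conjunction_node(axioms):
        parts = []
        for ax in axioms:
            if ax.kind in ("only", "only_and_some"):
                parts.append(restriction(ax.relation, OWL.allValuesFrom, ax.filler))
            if ax.kind in ("some", "only_and_some"):
                parts.append(restriction(ax.relation, OWL.someValuesFrom, ax.filler))
        if len(parts) == 1:
            return parts[0]
        node = BNode()
        g.add((node, RDF.type, OWL.Class))
        head = BNode()
        Collection(g, head, parts)
        g.add((node, OWL.intersectionOf, head))
        return node

    for ref in kb.externals.values():
        s = uri_of[ref.id]
        g.add((s, RDF.type, OWL.Class))
        g.add((s, RDFS.label, Literal(ref.label)))
        if ref.parent_hint and ref.parent_hint in uri_of:
            g.add((s, RDFS.subClassOf, uri_of[ref.parent_hint]))

    for cls in kb.classes.values():
        s = uri_of[cls.id]
        g.add((s, RDF.type, OWL.Class))
        if cls.label:
            g.add((s, RDFS.label, Literal(cls.label)))
        for alt in cls.alt_labels:
            g.add((s, SKOS.altLabel, Literal(alt)))
        if cls.description:
            g.add((s, SKOS.description, Literal(cls.description)))
        for key, value in cls.annotations.items():
            g.add((s, BDO[key], Literal(value)))
        for parent in cls.parents:
            g.add((s, RDFS.subClassOf, uri_of[parent]))
        for ax in cls.axioms:
            g.add((s, RDFS.subClassOf, axiom_node(ax)))

    onto = URIRef(owl_io.BDO_NS.rstrip("#"))
    g.add((onto, RDF.type, OWL.Ontology))
    if "dc:title" in kb.metadata:
        g.add((onto, DCT.title, Literal(kb.metadata["dc:title"])))
    if "dc:creator" in kb.metadata:
        g.add((onto, DCT.creator, Literal(kb.metadata["dc:creator"])))
    if "version" in kb.metadata:
        g.add((onto, OWL.versionInfo, Literal(kb.metadata["version"])))
    return g

# The canonical-dialect transcription of the published top-level and example
# class definitions (Bone_Dysplasia, Gene_Mutation, Phenotypic_Composite,
# Achondroplasia, GM0000001, and the PC/AC/QC examples), plus the external
# terms and supporting gene/mutation classes they reference.
SEVEN_DEFINITIONS = """\
Meta: dc:title "Printed class definitions"
Meta: version "1.5"

External: OGMS:OGMS_0000047\tOGMS\tGenetic disorder\t
External: OGMS:OGMS_0000023\tOGMS\tPhenotype\t
External: snap:SpecificallyDependentContinuant\tsnap\tSpecifically dependent continuant\t
External: HP:HP_0000118\tHP\tPhenotypic abnormality\t
External: HP:HP_0000005\tHP\tMode of inheritance\t
External: HP:HP_0000006\tHP\tAutosomal dominant inheritance\tHP:HP_0000005
External: HP:HP_0000238\tHP\tHydrocephalus\tHP:HP_0000118
External: HP:HP_0002938\tHP\tLumbar hyperlordosis\tHP:HP_0000118
External: HP:HP_0002968\tHP\tRhizomelia\tHP:HP_0000118
External: HP:HP_0003505\tHP\tDisproportionate short stature\tHP:HP_0000118
External: REAMS:Abnormality\tREAMS\tAbnormality\t
External: NCI:Mutation_Abnormality\tNCI\tMutation Abnormality\t
External: NCI:Missense_Mutation\tNCI\tMissense Mutation\tNCI:Mutation_Abnormality
External: PATO:PATO_0001241\tPATO\tPhysical object quality\t
External: PATO:PATO_0000068\tPATO\tQualitative\t
External: PATO:PATO_0001354\tPATO\ttranslucent\tPATO:PATO_0001241
External: PATO:PATO_0000947\tPATO\toval\tPATO:PATO_0000068
External: FMA:Anatomical_entity\tFMA\tAnatomical entity\t
External: FMA:Femur\tFMA\tFemur\tFMA:Anatomical_entity
External: FMA:Primary_anatomical_coordinate\tFMA\tPrimary anatomical coordinate\t
External: FMA:Proximal\tFMA\tProximal\tFMA:Primary_anatomical_coordinate

Class: Bone_Dysplasia
Parent: OGMS:OGMS_0000047
SubClassOf: characterized_by only (REAMS:Abnormality or HP:HP_0000118 or Phenotypic_Composite or Gene_Mutation)
SubClassOf: mode_of_inheritance only HP:HP_0000005
Description: A genetic disorder that involves abnormal development of bones and connective tissues.

Class: Gene_Mutation
Parent: snap:SpecificallyDependentContinuant
SubClassOf: has_locus only Gene and has_locus some Gene
SubClassOf: mutation_type only NCI:Mutation_Abnormality and mutation_type some NCI:Mutation_Abnormality
Description: A change or alteration in a gene.

Class: Phenotypic_Composite
Parent: OGMS:OGMS_0000023
SubClassOf: (has_part some Phenotypic_Composite and has_part only Phenotypic_Composite) or (describes some FMA:Anatomical_entity and describes only FMA:Anatomical_entity) or (describes some Anatomical_Composite and describes only Anatomical_Composite)
SubClassOf: (has_quality only PATO_0001241 and has_quality some PATO_0001241) or (has_quality only Quality_Composite and has_quality some Quality_Composite)
Description: A continuant describing the conjunction between a quality and an anatomical part or an anatomical composite.

Class: G0000001
Pillar: gene
Label: FGFR3
Parent: Gene

Class: GM000001
Pillar: gene_mutation
Label: GLY380ARG FGFR3
Parent: Gene_Mutation
SubClassOf: has_locus only G0000001 and has_locus some G0000001
SubClassOf: mutation_type only NCI:Missense_Mutation and mutation_type some NCI:Missense_Mutation
Annotation: count "1"
Annotation: encoding "GLY380ARG, 1138 G-A"
Annotation: mutated_content "A"
Annotation: offset "1138"
Annotation: original_content "G"

Class: GM000361
Pillar: gene_mutation
Label: Second FGFR3 mutation
Parent: Gene_Mutation
SubClassOf: has_locus only G0000001 and has_locus some G0000001

Class: Achondroplasia
Pillar: dysplasia
Label: Achondroplasia
Parent: Bone_Dysplasia
SubClassOf: characterized_by only (GM000001 or GM000361 or HP_0000238 or HP_0002938 or HP_0002968 or HP_0003505)
SubClassOf: mode_of_inheritance only HP_0000006 and mode_of_inheritance some HP_0000006

Class: AC_0000001
Pillar: anatomical_composite
Label: Proximal femur
Parent: Anatomical_Composite
SubClassOf: has_part only FMA:Femur and has_part some FMA:Femur
SubClassOf: has_anatomical_coordinate only FMA:Proximal and has_anatomical_coordinate some FMA:Proximal
Description: The proximal area of the femur

Class: PC_0000004
Pillar: phenotypic_composite
Label: Translucency of proximal femur
Parent: Phenotypic_Composite
SubClassOf: describes only AC_0000001 and describes some AC_0000001
SubClassOf: has_quality only PATO:PATO_0001354 and has_quality some PATO:PATO_0001354
Description: Translucent proximal area of femur

Class: QC_0000001
Pillar: quality_composite
Label: Oval translucency
Parent: Quality_Composite
SubClassOf: has_part only PATO:PATO_0001354 and has_part some PATO:PATO_0001354
SubClassOf: has_qualifier only PATO:PATO_0000947 and has_qualifier some PATO:PATO_0000947
Description: Oval-shaped area of translucency

Class: PC_0000005
Pillar: phenotypic_composite
Label: Oval translucency of proximal femur
Parent: Phenotypic_Composite
SubClassOf: describes only AC_0000001 and describes some AC_0000001
SubClassOf: has_quality only QC_0000001 and has_quality some QC_0000001
Description: Oval-shaped translucent area of the proximal femur
"""


@pytest.fixture(scope="session")
def printed_kb():
    return owl_io.parse_kb(SEVEN_DEFINITIONS)


@pytest.fixture(scope="session")
def fixture_kb():
    return fixtures.generate_nosology(fixtures.FixtureConfig())


@pytest.fixture(scope="session")
def cohort(fixture_kb):
    return fixtures.generate_cases(
        fixture_kb, 200, dropout=0.2, n_spurious=2, seed=7
    )
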