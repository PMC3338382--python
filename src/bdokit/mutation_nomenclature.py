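"""HGVS-derived gene-mutation encoding.

Gene mutations are recorded in a compact dialect combining a protein-level
change with a nucleotide-level substitution, e.g. ``GLY380ARG, 1138 G-A``:
glycine 380 replaced by arginine, caused by a G→A substitution at
nucleotide offset 1138. Either part may stand alone. ``count`` is the
number of affected nucleotides and always equals the length of the original
content for substitutions (the only event type in this dialect).

The offset is an opaque 1-based integer: the dialect does not distinguish
cDNA from genomic coordinates, so no conversion is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .kb_model import (
    BdoError,
    ClassAxiom,
    ClassDef,
    ExternalTermRef,
    KnowledgeBase,
    atom,
    normalize_term_id,
)

__all__ = [
    "AMINO_ACIDS",
    "ProteinChange",
    "GeneMutationRecord",
    "MutationSyntaxError",
    "parse_mutation_encoding",
    "serialize_mutation",
    "attach_mutation",
]

#: The 20 standard three-letter amino-acid codes.
AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

NCI_MUTATION_ROOT = "NCI:Mutation_Abnormality"


class MutationSyntaxError(BdoError):
    pass


@dataclass(frozen=True)
class ProteinChange:
    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in AMINO_ACIDS:
                raise MutationSyntaxError(f"unknown amino-acid code {aa!r}")
        if self.position < 1:
            raise MutationSyntaxError("protein position must be >= 1")


@dataclass(frozen=True)
class GeneMutationRecord:
    """Structured mutation description.

    At least one of the protein part and the nucleotide part is present.
    For the nucleotide part, ``count == len(original_content)``.
    """

    encoding: str = ""
    protein_change: Optional[ProteinChange] = None
    offset: Optional[int] = None
    original_content: str = ""
    mutated_content: str = ""
    count: int = 0
    mutation_type: Optional[ExternalTermRef] = None
    locus: str = ""

    def __post_init__(self) -> None:
        if self.protein_change is None and self.offset is None:
            raise MutationSyntaxError(
                "record needs a protein change or a nucleotide substitution"
            )
        if self.offset is not None:
            if self.offset < 1:
                raise MutationSyntaxError("offset must be >= 1 (1-based)")
            for seq in (self.original_content, self.mutated_content):
                if not seq or not re.fullmatch(r"[ACGT]+", seq):
                    raise MutationSyntaxError(
                        f"nucleotide content must be non-empty A/C/G/T, got {seq!r}"
                    )
            if self.count != len(self.original_content):
                raise MutationSyntaxError(
                    f"count {self.count} != length of original content "
                    f"{self.original_content!r}"
                )
        elif self.original_content or self.mutated_content or self.count:
            raise MutationSyntaxError("nucleotide fields require an offset")


_PROTEIN_RE = re.compile(r"^([A-Za-z]{3})(\d+)([A-Za-z]{3})$")
_NUCLEOTIDE_RE = re.compile(r"^(\d+)\s+([A-Za-z]+)-([A-Za-z]+)$")


def parse_mutation_encoding(text: str) -> GeneMutationRecord:
    """Parse ``[AAA<pos>BBB][, ]<offset> <orig>-<mut>`` (either part optional).

    Amino-acid codes are case-insensitive on input; the record stores the
    upper-case canonical form. ``count`` is derived as the length of the
    original content.
    """
    raw = text.strip()
    if not raw:
        raise MutationSyntaxError("empty mutation encoding")
    if "," in raw:
        head, _, tail = raw.partition(",")
        parts = [head.strip(), tail.strip()]
        if not parts[0] or not parts[1]:
            raise MutationSyntaxError(f"dangling comma in {text!r}")
    else:
        m = _PROTEIN_RE.match(raw.split()[0]) if raw.split() else None
        if m and len(raw.split()) > 1:
            first, rest = raw.split(None, 1)
            parts = [first, rest.strip()]
        else:
            parts = [raw]

    protein: Optional[ProteinChange] = None
    nucleotide: Optional[re.Match] = None
    for part in parts:
        pm = _PROTEIN_RE.match(part)
        nm = _NUCLEOTIDE_RE.match(part)
        if pm and protein is None and nm is None:
            ref, pos, alt = pm.group(1).upper(), int(pm.group(2)), pm.group(3).upper()
            protein = ProteinChange(ref, pos, alt)
        elif nm and nucleotide is None:
            nucleotide = nm
        else:
            raise MutationSyntaxError(f"cannot parse mutation part {part!r}")

    if nucleotide is None:
        return GeneMutationRecord(
            encoding=serialize_fields(protein, None, "", ""),
            protein_change=protein,
        )
    offset = int(nucleotide.group(1))
    orig = nucleotide.group(2).upper()
    mut = nucleotide.group(3).upper()
    if not re.fullmatch(r"[ACGT]+", orig) or not re.fullmatch(r"[ACGT]+", mut):
        raise MutationSyntaxError(
            f"non-nucleotide characters in substitution {nucleotide.group(0)!r}"
        )
    return GeneMutationRecord(
        encoding=serialize_fields(protein, offset, orig, mut),
        protein_change=protein,
        offset=offset,
        original_content=orig,
        mutated_content=mut,
        count=len(orig),
    )


def serialize_fields(
    protein: Optional[ProteinChange],
    offset: Optional[int],
    orig: str,
    mut: str,
) -> str:
    parts = []
    if protein is not None:
        parts.append(f"{protein.ref_aa}{protein.position}{protein.alt_aa}")
    if offset is not None:
        parts.append(f"{offset} {orig}-{mut}")
    return ", ".join(parts)


def serialize_mutation(rec: GeneMutationRecord) -> str:
    """Canonical form ``AAA<pos>BBB, <offset> <orig>-<mut>``; deterministic."""
    return serialize_fields(
        rec.protein_change, rec.offset, rec.original_content, rec.mutated_content
    )


def attach_mutation(
    kb: KnowledgeBase,
    mutation_id: str,
    record: GeneMutationRecord,
    gene_id: str,
    type_ref: ExternalTermRef,
    label: str = "",
) -> KnowledgeBase:
    """Register a gene-mutation class wired to its gene and mutation type.

    Creates a class under the Gene_Mutation root carrying
    ``has_locus only G and has_locus some G`` and
    ``mutation_type only T and mutation_type some T`` axioms, with the
    encoding and its nucleotide fields as annotations.
    """
    gid = normalize_term_id(gene_id)
    gene = kb.get_class(gid)
    if gene.pillar != "gene":
        raise BdoError(f"{gene_id} is not a gene-pillar class")
    kb.add_external(type_ref)
    if not kb.external_descends(type_ref.id, NCI_MUTATION_ROOT):
        raise BdoError(
            f"{type_ref.id} is not under {NCI_MUTATION_ROOT}"
        )
    annotations = {"encoding": serialize_mutation(record)}
    if record.offset is not None:
        annotations.update(
            offset=str(record.offset),
            count=str(record.count),
            original_content=record.original_content,
            mutated_content=record.mutated_content,
        )
    cls = ClassDef(
        id=mutation_id,
        pillar="gene_mutation",
        label=label or serialize_mutation(record),
        parents=["Gene_Mutation"],
        axioms=[
            ClassAxiom("has_locus", "only_and_some", atom(gid)),
            ClassAxiom("mutation_type", "only_and_some", atom(type_ref.id)),
        ],
        annotations=annotations,
    )
    kb.add_class(cls)
    return kb
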