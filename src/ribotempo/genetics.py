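"""Standard genetic code lookup tables.

All codons are DNA-alphabet, uppercase 3-mers. Synonymous families are
keyed by one-letter amino acid codes; stop codons are not part of any
family.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: The three stop codons (TAA, TAG, TGA).
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

#: Map from sense codon to one-letter amino acid.
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

#: The 61 sense codons in lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: Map amino acid -> lexicographically sorted tuple of its codons.
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    _aa = CODON_TO_AA[_codon]
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)

#: Map codon -> tuple of codons in its synonymous family (itself included).
FAMILY_OF: dict[str, tuple[str, ...]] = {
    c: FAMILIES[CODON_TO_AA[c]] for c in SENSE_CODONS
}

#: Codons that are the sole member of their family (ATG, TGG).
SINGLETON_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if len(FAMILY_OF[c]) == 1
)

#: Column index of each sense codon in feature matrices.
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

VALID_BASES = frozenset("ACGT")


def is_stop(codon: str) -> bool:
    return codon in _TABLE.stop_codons


def family_size(codon: str) -> int:
    """Number of synonymous codons in ``codon``'s family.

    Raises ``KeyError`` for stop codons or malformed codons.
    """
    return len(FAMILY_OF[codon])
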