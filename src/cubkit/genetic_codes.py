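"""Translation tables and synonymous-family structure.

Every downstream statistic (ENC, RSCU, GC3s, optimal codons) is defined over
the *synonymous families* of a genetic code: the partition of sense codons by
the amino acid they encode. Ciliate nuclear genomes do not use the standard
code — in the ciliate/hypotrich nuclear code (NCBI table 6) UAA and UAG encode
glutamine and only UGA terminates, while in the euplotid nuclear code (table
10) UGA encodes cysteine. Those reassignments change the family structure
(table 6 gains a four-codon Gln family; table 10 a three-codon Cys family) and
therefore every bias index computed under them.

Codons are held in the DNA alphabet (``T`` not ``U``); renderers may print
RNA-style names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Mapping, Tuple

from Bio.Data import CodonTable

__all__ = [
    "CODONS",
    "GeneticCode",
    "SynonymousFamily",
    "UnsupportedCodeError",
    "degeneracy_classes",
    "get_code",
    "reverse_complement",
]

_BASES = "TCAG"
#: All 64 codons in the conventional TCAG table order.
CODONS: Tuple[str, ...] = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)

SUPPORTED_TABLES = (1, 6, 10)

STOP = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class UnsupportedCodeError(ValueError):
    """Raised for a translation-table id outside the supported set."""


@dataclass(frozen=True)
class SynonymousFamily:
    """One amino acid's codon family.

    ``degeneracy`` is the family size (1-6); one-fold families (Met, and Trp
    under tables 1/6) carry no synonymous choice and are excluded from the
    synonymous statistics downstream.
    """

    amino_acid: str
    codons: Tuple[str, ...]

    @property
    def degeneracy(self) -> int:
        return len(self.codons)


@dataclass(frozen=True, eq=False)  # identity hash: instances are lru-cached singletons
class GeneticCode:
    """A translation table plus its synonymous-family partition."""

    table_id: int
    name: str
    codon_to_aa: Mapping[str, str]  # 64 codons -> amino acid symbol or "*"
    stop_codons: frozenset
    families: Tuple[SynonymousFamily, ...]
    _family_of: Mapping[str, SynonymousFamily] = field(repr=False, default=None)

    @property
    def sense_codons(self) -> Tuple[str, ...]:
        return tuple(c for c in CODONS if c not in self.stop_codons)

    @property
    def n_sense(self) -> int:
        return 64 - len(self.stop_codons)

    def family_of(self, codon: str) -> SynonymousFamily:
        return self._family_of[codon]

    def degeneracy_of(self, codon: str) -> int:
        return len(self._family_of[codon].codons)

    def translate(self, seq: str) -> str:
        """Translate an in-frame DNA string; stops render as ``*``."""
        if len(seq) % 3:
            raise ValueError("sequence length is not a multiple of 3")
        aa = self.codon_to_aa
        return "".join(aa[seq[i : i + 3]] for i in range(0, len(seq), 3))


def _build_code(table_id: int) -> GeneticCode:
    ncbi = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa: Dict[str, str] = {}
    for codon in CODONS:
        codon_to_aa[codon] = STOP if codon in ncbi.stop_codons else ncbi.forward_table[codon]
    by_aa: Dict[str, list] = {}
    for codon in CODONS:  # deterministic TCAG order within families
        aa = codon_to_aa[codon]
        if aa != STOP:
            by_aa.setdefault(aa, []).append(codon)
    families = tuple(
        SynonymousFamily(aa, tuple(codons)) for aa, codons in sorted(by_aa.items())
    )
    family_of = {c: fam for fam in families for c in fam.codons}
    return GeneticCode(
        table_id=table_id,
        name=ncbi.names[0],
        codon_to_aa=codon_to_aa,
        stop_codons=frozenset(ncbi.stop_codons),
        families=families,
        _family_of=family_of,
    )


@lru_cache(maxsize=None)
def get_code(table_id: int) -> GeneticCode:
    """Return the genetic code for an NCBI translation-table id.

    Supported ids: 1 (standard), 6 (ciliate/dasycladacean/hexamita nuclear;
    UAR -> Gln, UGA stop), 10 (euplotid nuclear; UGA -> Cys).
    """
    if table_id not in SUPPORTED_TABLES:
        raise UnsupportedCodeError(
            f"translation table {table_id!r} not supported; choose one of {SUPPORTED_TABLES}"
        )
    return _build_code(table_id)


def degeneracy_classes(code: GeneticCode) -> Dict[int, int]:
    """Count synonymous families per degeneracy level.

    The class census drives the ENC class averages: e.g. the standard code has
    {1: 2, 2: 9, 3: 1, 4: 5, 6: 3} for its 61 sense codons.
    """
    classes: Dict[int, int] = {}
    for fam in code.families:
        classes[fam.degeneracy] = classes.get(fam.degeneracy, 0) + 1
    return dict(sorted(classes.items()))
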