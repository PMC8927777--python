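"""CDS quality control: reduce a raw FASTA CDS set to "perfect" CDSs.

A record survives filtering when it is an unambiguous, in-frame coding
sequence: length a multiple of three, ATG start, a canonical terminator
(TAA/TAG/TGA) at the end, no internal stop codon under the working genetic
code, length strictly greater than ``min_len`` nucleotides, and not an exact
duplicate (or exact reverse-complement duplicate) of an earlier record.

Internal stops can alternatively be excised codon-wise (``delete_codon``
mode) instead of rejecting the record; the excisions are logged and the
length test runs on the shortened sequence.

Note the start/stop rule always uses the canonical terminator triplets even
under codes where TAA/TAG are sense codons (table 6): terminators at the CDS
end are retained genomic reality regardless of the code used for the
synonymous statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

from Bio import SeqIO

from .genetic_codes import GeneticCode, reverse_complement

__all__ = [
    "CANONICAL_STOPS",
    "CodingSequence",
    "FastaParseError",
    "FilterReport",
    "filter_cds",
    "read_fasta",
    "write_fasta",
]

#: Terminators accepted at the end of a CDS, independent of the working code.
CANONICAL_STOPS = frozenset({"TAA", "TAG", "TGA"})

REASONS = (
    "AMBIGUOUS_BASE",
    "NOT_TRIPLET",
    "BAD_START",
    "BAD_STOP",
    "INTERNAL_STOP",
    "TOO_SHORT",
    "DUPLICATE",
    "REVCOMP_DUPLICATE",
)


class FastaParseError(ValueError):
    pass


@dataclass(frozen=True)
class CodingSequence:
    """One putative coding sequence (uppercase DNA)."""

    id: str
    seq: str
    species: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    rejections: List[Tuple[str, str]] = field(default_factory=list)
    #: (gene id, 0-based codon index, codon) for each excised internal stop.
    deleted_stops: List[Tuple[str, int, str]] = field(default_factory=list)

    def reason_counts(self) -> dict:
        out: dict = {}
        for _, reason in self.rejections:
            out[reason] = out.get(reason, 0) + 1
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rejections, columns=["id", "reason"])


def read_fasta(path, species: str | None = None) -> List[CodingSequence]:
    """Read a (multi-)FASTA file into CodingSequence records.

    The first whitespace token of each header becomes the id; sequences are
    uppercased. ``species`` defaults to the file's stem. An empty file yields
    an empty list with a warning; a file whose first non-blank line is not a
    header raises :class:`FastaParseError` with the line number.
    """
    path = Path(path)
    if species is None:
        species = path.stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header '>', got {line[:30]!r}"
                    )
                break
        else:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []
    records = [
        CodingSequence(id=rec.id, seq=str(rec.seq).upper(), species=species)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_fasta(records: Iterable[CodingSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _codons(seq: str) -> List[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def filter_cds(
    seqs: Sequence[CodingSequence],
    code: GeneticCode,
    min_len: int = 300,
    internal_stop_mode: str = "reject",
) -> Tuple[List[CodingSequence], FilterReport]:
    """Apply the CDS QC rules; return (kept records, report).

    Rejection reasons are assigned in a fixed order (first failure wins):
    AMBIGUOUS_BASE, NOT_TRIPLET, BAD_START, BAD_STOP, INTERNAL_STOP,
    TOO_SHORT, DUPLICATE, REVCOMP_DUPLICATE. The length rule is strict:
    kept sequences are *longer than* ``min_len`` nucleotides after any
    internal-stop excision. Duplicate checks keep the first occurrence.
    """
    if internal_stop_mode not in ("reject", "delete_codon"):
        raise ValueError("internal_stop_mode must be 'reject' or 'delete_codon'")
    if min_len % 3:
        raise ValueError(f"min_len must be a multiple of 3, got {min_len}")

    report = FilterReport(n_input=len(seqs))
    kept: List[CodingSequence] = []
    # every prior record is registered, kept or not: a raw minus-strand copy
    # of a gene fails the start/stop rules itself, yet its plus-strand twin
    # appearing later must still be recognised as redundant
    seen: set = set()
    seen_rc: set = set()

    for rec in seqs:
        seq = rec.seq.upper()

        def register(s: str = None) -> None:
            s = seq if s is None else s
            seen.add(s)
            seen_rc.add(reverse_complement(s))

        if set(seq) - set("ACGT"):
            report.rejections.append((rec.id, "AMBIGUOUS_BASE"))
            continue
        if len(seq) % 3:
            report.rejections.append((rec.id, "NOT_TRIPLET"))
            register()
            continue
        if not seq.startswith("ATG"):
            report.rejections.append((rec.id, "BAD_START"))
            register()
            continue
        if seq[-3:] not in CANONICAL_STOPS:
            report.rejections.append((rec.id, "BAD_STOP"))
            register()
            continue
        codons = _codons(seq)
        internal = [i for i, c in enumerate(codons[:-1]) if c in code.stop_codons]
        if internal:
            if internal_stop_mode == "reject":
                report.rejections.append((rec.id, "INTERNAL_STOP"))
                register()
                continue
            for i in internal:
                report.deleted_stops.append((rec.id, i, codons[i]))
            codons = [c for i, c in enumerate(codons) if i not in set(internal)]
            seq = "".join(codons)
        if len(seq) <= min_len:
            report.rejections.append((rec.id, "TOO_SHORT"))
            register()
            continue
        if seq in seen:
            report.rejections.append((rec.id, "DUPLICATE"))
            continue
        if seq in seen_rc:
            report.rejections.append((rec.id, "REVCOMP_DUPLICATE"))
            continue
        register()
        kept.append(CodingSequence(id=rec.id, seq=seq, species=rec.species))

    report.n_kept = len(kept)
    return kept, report
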