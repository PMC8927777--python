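"""CRISPR support: SpCas9 NGG PAM/guide-site scanning and optimal-codon
synonymous rewriting of a coding sequence.

SpCas9 requires a 5'-NGG protospacer-adjacent motif (PAM) immediately 3' of a
20-nt protospacer. :func:`scan_pam_sites` enumerates every such window on
either strand; :func:`optimize_codons` rewrites a CDS so that each amino acid
with a designated optimal codon uses it, leaving the protein sequence, the
start codon and the terminal stop untouched. Guide scoring (GC content,
homopolymers, off-target search) is deliberately not implemented — scanning
and counting only.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple, Union

import pandas as pd

from .bias_analysis import OptimalCodonReport
from .cds_filter import CANONICAL_STOPS, CodingSequence
from .genetic_codes import GeneticCode, reverse_complement

__all__ = [
    "CodonEdit",
    "GuideSite",
    "classify_pams",
    "optimize_codons",
    "scan_pam_sites",
    "sites_frame",
]

logger = logging.getLogger(__name__)

GUIDE_LEN = 20
PAM_LEN = 3


@dataclass(frozen=True)
class GuideSite:
    """One candidate Cas9 target.

    ``start`` is the 0-based plus-strand position of the protospacer's
    leftmost base; for minus-strand sites the protospacer/PAM strings are
    given in minus-strand orientation while the coordinate stays in
    plus-strand space.
    """

    start: int
    strand: str  # "+" or "-"
    protospacer: str
    pam: str


@dataclass(frozen=True)
class CodonEdit:
    codon_index: int  # 0-based codon position within the CDS
    old_codon: str
    new_codon: str
    amino_acid: str


def _scan_strand(seq: str) -> List[Tuple[int, str, str]]:
    hits = []
    window = GUIDE_LEN + PAM_LEN
    for i in range(len(seq) - window + 1):
        chunk = seq[i : i + window]
        if "N" in chunk:
            continue
        if chunk[GUIDE_LEN + 1] == "G" and chunk[GUIDE_LEN + 2] == "G":
            hits.append((i, chunk[:GUIDE_LEN], chunk[GUIDE_LEN:]))
    return hits


def scan_pam_sites(seq: str, both_strands: bool = True) -> List[GuideSite]:
    """Enumerate all 20-nt+NGG Cas9 target sites in a sequence.

    Overlapping sites are all reported; windows containing N are skipped
    (logged). Output is sorted by plus-strand coordinate, then strand.
    """
    seq = seq.upper()
    n_with_n = seq.count("N")
    if n_with_n:
        logger.info("scan_pam_sites: sequence contains %d N bases; windows with N skipped", n_with_n)
    sites = [GuideSite(i, "+", proto, pam) for i, proto, pam in _scan_strand(seq)]
    if both_strands:
        rc = reverse_complement(seq)
        n = len(seq)
        for i, proto, pam in _scan_strand(rc):
            # leftmost plus-strand base of the protospacer's span
            sites.append(GuideSite(n - i - GUIDE_LEN, "-", proto, pam))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def classify_pams(sites: List[GuideSite]) -> Dict[str, int]:
    """Count sites per PAM triplet (e.g. {'AGG': 9, 'TGG': 3, 'GGG': 3})."""
    return dict(Counter(s.pam for s in sites))


def sites_frame(sites: List[GuideSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(s) for s in sites], columns=["start", "strand", "protospacer", "pam"]
    )


def _preference_from_report(report: OptimalCodonReport) -> Dict[str, str]:
    """Reduce an optimal-codon report to one target codon per amino acid.

    Families with several flagged codons (e.g. Pro with CCU and CCA) keep the
    one with the largest ΔRSCU.
    """
    best: Dict[str, Tuple[float, str]] = {}
    for codon in report.optimal:
        aa = report.code.codon_to_aa[codon]
        d = report.delta_rscu[codon]
        if aa not in best or d > best[aa][0]:
            best[aa] = (d, codon)
    return {aa: codon for aa, (_, codon) in best.items()}


def optimize_codons(
    cds: Union[CodingSequence, str],
    optimal: Union[OptimalCodonReport, Mapping[str, str]],
    code: GeneticCode,
) -> Tuple[CodingSequence, List[CodonEdit]]:
    """Rewrite a CDS to its optimal synonymous codons.

    ``optimal`` is either an :class:`OptimalCodonReport` or an explicit
    amino-acid -> target-codon mapping (at most one codon per amino acid).
    Every codon whose amino acid has a designated codon, and which is not
    already that codon, is replaced; the start codon and terminal stop are
    never edited, and the translation is unchanged by construction.
    """
    rec = cds if isinstance(cds, CodingSequence) else CodingSequence(id="cds", seq=cds.upper())
    seq = rec.seq
    if len(seq) % 3:
        raise ValueError(f"{rec.id}: length {len(seq)} is not a multiple of 3")

    pref = (
        _preference_from_report(optimal)
        if isinstance(optimal, OptimalCodonReport)
        else dict(optimal)
    )
    for aa, codon in pref.items():
        if code.codon_to_aa.get(codon) != aa:
            raise ValueError(
                f"preference table maps {aa} to {codon}, which encodes "
                f"{code.codon_to_aa.get(codon)!r} under table {code.table_id}"
            )

    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    last = len(codons) - 1
    edits: List[CodonEdit] = []
    for idx, codon in enumerate(codons):
        if idx == 0:
            continue  # start codon untouched
        if idx == last and codon in CANONICAL_STOPS | code.stop_codons:
            continue  # terminal stop untouched
        aa = code.codon_to_aa[codon]
        target = pref.get(aa)
        if target is not None and target != codon:
            edits.append(CodonEdit(idx, codon, target, aa))
            codons[idx] = target
    new = CodingSequence(id=rec.id, seq="".join(codons), species=rec.species)
    return new, edits
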