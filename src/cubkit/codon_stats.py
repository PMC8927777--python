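"""Per-gene codon counting and codon-usage-bias indices.

Implements the classic CodonW-style index family over an arbitrary genetic
code:

* overall base fractions and positional GC (GC1/GC2/GC3, GC12);
* GC3s and A3s/T3s/C3s/G3s — base composition at the third position of
  *synonymous* codons only (families of degeneracy >= 2; Met/Trp and stop
  codons carry no synonymous choice and are excluded);
* Wright's effective number of codons (ENC), with the standard class-average
  estimator and 3-fold-class imputation;
* the expected-ENC curve under pure GC3 compositional drift,
  ``2 + GC3 + 29/(GC3^2 + (1-GC3)^2)``;
* relative synonymous codon usage, ``RSCU(c) = k * n_c / N`` for a codon in a
  k-fold family with family total N.

Counting convention: in-frame codons of a kept CDS, terminal stop excluded,
start ATG included (as Met).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .cds_filter import CANONICAL_STOPS, CodingSequence
from .genetic_codes import CODONS, GeneticCode

__all__ = [
    "CodonCounts",
    "CompositionProfile",
    "RscuTable",
    "composition_profile",
    "count_codons",
    "enc",
    "expected_enc",
    "pool_counts",
    "profiles_frame",
    "rscu",
]

CODON_INDEX: Dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_THIRD_IS_GC = np.array([c[2] in "GC" for c in CODONS])
_BASE_AT = {
    pos: {b: np.array([c[pos] == b for c in CODONS]) for b in "ACGT"} for pos in (0, 1, 2)
}


@dataclass
class CodonCounts:
    """Codon counts of one gene (or a pooled gene set) as a length-64 vector."""

    gene_id: str
    counts: np.ndarray  # shape (64,), int

    @property
    def n_codons(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> Dict[str, int]:
        return {c: int(n) for c, n in zip(CODONS, self.counts) if n}

    def __getitem__(self, codon: str) -> int:
        return int(self.counts[CODON_INDEX[codon]])


@dataclass
class CompositionProfile:
    """Composition and bias indices of one gene; fractions in [0, 1].

    ``gc3s`` and the ``x3s`` fields are ``None`` when the gene contains no
    codon from a synonymous (degeneracy >= 2) family; ``enc`` is ``None``
    when no degeneracy class can be estimated.
    """

    gene_id: str
    n_codons: int
    a_pct: float
    c_pct: float
    g_pct: float
    t_pct: float
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: Optional[float]
    a3s: Optional[float]
    t3s: Optional[float]
    c3s: Optional[float]
    g3s: Optional[float]
    enc: Optional[float]


class _CodeArrays:
    """Precomputed index arrays for one genetic code (vectorised statistics)."""

    def __init__(self, code: GeneticCode):
        self.code = code
        self.sense_mask = np.array([c not in code.stop_codons for c in CODONS])
        self.syn_mask = np.array(
            [
                c not in code.stop_codons and code.degeneracy_of(c) >= 2
                for c in CODONS
            ]
        )
        self.families = [
            np.array([CODON_INDEX[c] for c in fam.codons])
            for fam in code.families
            if fam.degeneracy >= 2
        ]
        self.family_degeneracy = np.array(
            [fam.degeneracy for fam in code.families if fam.degeneracy >= 2]
        )
        self.n_onefold = sum(1 for fam in code.families if fam.degeneracy == 1)
        # per base: synonymous codons whose family offers that base at pos 3
        self.codonw_elig = {}
        for b in "ACGT":
            elig = np.zeros(64, dtype=bool)
            for fam in code.families:
                if fam.degeneracy >= 2 and any(c[2] == b for c in fam.codons):
                    for c in fam.codons:
                        elig[CODON_INDEX[c]] = True
            self.codonw_elig[b] = elig


@lru_cache(maxsize=None)
def _arrays(code: GeneticCode) -> _CodeArrays:
    return _CodeArrays(code)


def count_codons(cds: CodingSequence, code: GeneticCode) -> CodonCounts:
    """In-frame codon counts of a CDS, excluding the terminal stop codon.

    The final triplet is dropped when it is a canonical terminator or a stop
    of the working code; everything else is counted, including the ATG start.
    """
    seq = cds.seq
    if len(seq) % 3:
        raise ValueError(f"{cds.id}: length {len(seq)} is not a multiple of 3")
    counts = np.zeros(64, dtype=np.int64)
    end = len(seq) - 3 if seq[-3:] in CANONICAL_STOPS | code.stop_codons else len(seq)
    for i in range(0, end, 3):
        counts[CODON_INDEX[seq[i : i + 3]]] += 1
    return CodonCounts(gene_id=cds.id, counts=counts)


def pool_counts(counts: Sequence[CodonCounts], gene_id: str = "pooled") -> CodonCounts:
    """Sum per-gene counts into one pooled CodonCounts."""
    total = np.zeros(64, dtype=np.int64)
    for c in counts:
        total += c.counts
    return CodonCounts(gene_id=gene_id, counts=total)


def _x3s(counts: np.ndarray, arrs: _CodeArrays, mode: str) -> Dict[str, Optional[float]]:
    out: Dict[str, Optional[float]] = {}
    if mode == "family":
        denom = counts[arrs.syn_mask].sum()
        for b in "ACGT":
            num = counts[arrs.syn_mask & _BASE_AT[2][b]].sum()
            out[b] = float(num / denom) if denom else None
    elif mode == "codonw":
        for b in "ACGT":
            elig = arrs.codonw_elig[b]
            denom = counts[elig].sum()
            num = counts[elig & _BASE_AT[2][b]].sum()
            out[b] = float(num / denom) if denom else None
    else:
        raise ValueError("x3s_mode must be 'family' or 'codonw'")
    return out


def composition_profile(
    counts: CodonCounts, code: GeneticCode, x3s_mode: str = "family"
) -> CompositionProfile:
    """Compute the full composition/bias index set for one gene.

    GC1/GC2/GC3 run over all counted codons; GC3s and X3s over codons of
    synonymous families only. ``x3s_mode='codonw'`` switches X3s to CodonW's
    historical per-base eligible-codon denominators (the four values then need
    not sum to 1).
    """
    v = counts.counts
    n = v.sum()
    if n < 1:
        raise ValueError(f"{counts.gene_id}: empty codon counts")
    arrs = _arrays(code)

    base_tot = {b: int(sum(v[_BASE_AT[p][b]].sum() for p in (0, 1, 2))) for b in "ACGT"}
    total = 3 * n
    gc_pos = [float(v[_BASE_AT[p]["G"] | _BASE_AT[p]["C"]].sum() / n) for p in (0, 1, 2)]

    syn = v[arrs.syn_mask].sum()
    gc3s = float(v[arrs.syn_mask & _THIRD_IS_GC].sum() / syn) if syn else None
    x3s = _x3s(v, arrs, x3s_mode)

    return CompositionProfile(
        gene_id=counts.gene_id,
        n_codons=int(n),
        a_pct=float(base_tot["A"] / total),
        c_pct=float(base_tot["C"] / total),
        g_pct=float(base_tot["G"] / total),
        t_pct=float(base_tot["T"] / total),
        gc=float((base_tot["G"] + base_tot["C"]) / total),
        gc1=gc_pos[0],
        gc2=gc_pos[1],
        gc3=gc_pos[2],
        gc12=(gc_pos[0] + gc_pos[1]) / 2.0,
        gc3s=gc3s,
        a3s=x3s["A"],
        t3s=x3s["T"],
        c3s=x3s["C"],
        g3s=x3s["G"],
        enc=enc(counts, code),
    )


def enc(counts: CodonCounts, code: GeneticCode) -> Optional[float]:
    """Wright's effective number of codons for one gene.

    For each family of degeneracy k >= 2 with n observed codons and
    within-family proportions p_i, the codon homozygosity is estimated as
    F = (n * sum p_i^2 - 1) / (n - 1); families with n < 2 or F <= 0 are
    dropped from their degeneracy class. ENC is the one-fold family count
    plus, per class, (number of families) / (mean F). A missing 3-fold class
    is imputed as the mean of the 2- and 4-fold class values; if any other
    class cannot be estimated the statistic is undefined (``None``). The
    result is clipped to [2, number of sense codons].
    """
    arrs = _arrays(code)
    v = counts.counts
    class_F: Dict[int, List[float]] = {}
    for fam_idx, k in zip(arrs.families, arrs.family_degeneracy):
        fam_counts = v[fam_idx]
        n = fam_counts.sum()
        if n < 2:
            continue
        p = fam_counts / n
        F = (n * float(p @ p) - 1.0) / (n - 1.0)
        if F <= 0:
            continue
        class_F.setdefault(int(k), []).append(F)

    class_sizes: Dict[int, int] = {}
    for k in arrs.family_degeneracy:
        class_sizes[int(k)] = class_sizes.get(int(k), 0) + 1

    total = float(arrs.n_onefold)
    for k, n_fam in sorted(class_sizes.items()):
        if k in class_F:
            mean_F = float(np.mean(class_F[k]))
        elif k == 3 and 2 in class_F and 4 in class_F:
            mean_F = (float(np.mean(class_F[2])) + float(np.mean(class_F[4]))) / 2.0
        else:
            return None
        total += n_fam / mean_F
    return float(np.clip(total, 2.0, arrs.code.n_sense))


def expected_enc(gc3: float) -> float:
    """Expected ENC under pure compositional (GC3) drift.

    ``ENC_expected = 2 + GC3 + 29 / (GC3^2 + (1 - GC3)^2)`` for GC3 in [0, 1].
    """
    if not 0.0 <= gc3 <= 1.0:
        raise ValueError(f"gc3 must be within [0, 1], got {gc3}")
    return 2.0 + gc3 + 29.0 / (gc3**2 + (1.0 - gc3) ** 2)


@dataclass
class RscuTable:
    """RSCU over the sense codons of degeneracy >= 2 families.

    ``values[c]`` is ``None`` for an unobserved family (N = 0).
    """

    gene_id: str
    values: Dict[str, Optional[float]]
    code: GeneticCode

    def __getitem__(self, codon: str) -> Optional[float]:
        return self.values[codon]

    def to_frame(self, counts: Optional[CodonCounts] = None) -> pd.DataFrame:
        rows = []
        for c, val in self.values.items():
            rows.append(
                {
                    "codon": c,
                    "codon_rna": c.replace("T", "U"),
                    "amino_acid": self.code.codon_to_aa[c],
                    "count": counts[c] if counts is not None else None,
                    "rscu": val,
                }
            )
        return pd.DataFrame(rows)


def rscu(counts: CodonCounts, code: GeneticCode) -> RscuTable:
    """Relative synonymous codon usage: ``k * n_c / N`` per k-fold family."""
    values: Dict[str, Optional[float]] = {}
    for fam in code.families:
        if fam.degeneracy < 2:
            continue
        N = sum(counts[c] for c in fam.codons)
        for c in fam.codons:
            values[c] = fam.degeneracy * counts[c] / N if N else None
    return RscuTable(gene_id=counts.gene_id, values=values, code=code)


def profiles_frame(profiles: Sequence[CompositionProfile], percent: bool = False) -> pd.DataFrame:
    """Tabulate profiles; ``percent=True`` renders fraction columns as %."""
    df = pd.DataFrame([vars(p) for p in profiles])
    if percent:
        frac_cols = [
            "a_pct", "c_pct", "g_pct", "t_pct", "gc", "gc1", "gc2", "gc3",
            "gc12", "gc3s", "a3s", "t3s", "c3s", "g3s",
        ]
        df[frac_cols] = (df[frac_cols] * 100).round(2)
        df["enc"] = df["enc"].round(2)
    return df
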