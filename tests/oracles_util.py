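"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the vectorised/regex code paths of the package:
plain dict/loop arithmetic only.
"""

from typing import Dict, List, Optional, Tuple


def enc_brute_force(counts: Dict[str, int], code) -> Optional[float]:
    """Wright's ENC computed family-by-family with explicit loops."""
    per_class_F: Dict[int, List[float]] = {}
    class_counts: Dict[int, int] = {}
    n_onefold = 0
    for fam in code.families:
        k = len(fam.codons)
        if k == 1:
            n_onefold += 1
            continue
        class_counts[k] = class_counts.get(k, 0) + 1
        n = sum(counts.get(c, 0) for c in fam.codons)
        if n < 2:
            continue
        sum_p2 = 0.0
        for c in fam.codons:
            p = counts.get(c, 0) / n
            sum_p2 += p * p
        F = (n * sum_p2 - 1.0) / (n - 1.0)
        if F > 0:
            per_class_F.setdefault(k, []).append(F)

    enc_total = float(n_onefold)
    for k in sorted(class_counts):
        if k in per_class_F:
            Fbar = sum(per_class_F[k]) / len(per_class_F[k])
        elif k == 3 and 2 in per_class_F and 4 in per_class_F:
            f2 = sum(per_class_F[2]) / len(per_class_F[2])
            f4 = sum(per_class_F[4]) / len(per_class_F[4])
            Fbar = (f2 + f4) / 2.0
        else:
            return None
        enc_total += class_counts[k] / Fbar
    n_sense = 64 - len(code.stop_codons)
    return min(max(enc_total, 2.0), float(n_sense))


_RC = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def pam_brute_force(seq: str, both_strands: bool = True) -> List[Tuple[int, str, str, str]]:
    """All 20-nt+NGG windows by naive sliding-window scan (no regex).

    Returns (plus-strand start of protospacer, strand, protospacer, pam)
    tuples sorted like the implementation.
    """
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - 22):
        window = seq[i : i + 23]
        if "N" in window:
            continue
        if window[21] == "G" and window[22] == "G":
            hits.append((i, "+", window[:20], window[20:]))
    if both_strands:
        rc = "".join(_RC[b] for b in reversed(seq))
        n = len(seq)
        for i in range(len(rc) - 22):
            window = rc[i : i + 23]
            if "N" in window:
                continue
            if window[21] == "G" and window[22] == "G":
                hits.append((n - i - 20, "-", window[:20], window[20:]))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits
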