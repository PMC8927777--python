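"""Cross-species RSCU comparison: pooled RSCU matrix, distances, clustering.

Each species' kept genes are pooled into one codon-count vector and converted
to RSCU under that species' genetic code. Codons that are stop (or one-fold)
under a species' code are missing for that species, so species running on
different ciliate codes remain comparable over their shared sense codons.
Pairwise distances use pairwise-complete columns rescaled by the total/shared
column ratio, and the distance matrix feeds a UPGMA (default) or
neighbour-joining tree rendered as Newick — the "codon-usage phylogeny".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .codon_stats import CodonCounts, pool_counts, rscu
from .genetic_codes import GeneticCode

__all__ = [
    "DistanceMatrixT",
    "RscuMatrix",
    "build_tree",
    "pooled_rscu_matrix",
    "rscu_distance",
]


@dataclass
class RscuMatrix:
    """Species x codon RSCU values (NaN = missing for that species' code)."""

    values: pd.DataFrame  # index: species, columns: codons
    codes: Dict[str, GeneticCode]

    @property
    def species(self) -> List[str]:
        return list(self.values.index)

    @property
    def codons(self) -> List[str]:
        return list(self.values.columns)


@dataclass
class DistanceMatrixT:
    labels: List[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def pooled_rscu_matrix(
    counts_by_species: Mapping[str, Union[CodonCounts, Sequence[CodonCounts]]],
    codes_by_species: Mapping[str, GeneticCode],
) -> RscuMatrix:
    """Pool per-species counts and tabulate RSCU over the union of synonymous
    codons across the species' codes.

    A species whose pooled gene set is empty is excluded with a warning.
    """
    if len(counts_by_species) < 2:
        raise ValueError("pooled RSCU matrix needs >= 2 species")
    rows: Dict[str, Dict[str, float]] = {}
    codes: Dict[str, GeneticCode] = {}
    for sp, counts in counts_by_species.items():
        pooled = counts if isinstance(counts, CodonCounts) else pool_counts(list(counts), sp)
        if pooled.n_codons == 0:
            warnings.warn(f"species {sp!r} has no counted codons; excluded", stacklevel=2)
            continue
        code = codes_by_species[sp]
        table = rscu(pooled, code)
        rows[sp] = {c: (np.nan if v is None else v) for c, v in table.values.items()}
        codes[sp] = code
    if len(rows) < 2:
        raise ValueError("fewer than 2 species with data")
    all_codons = sorted({c for row in rows.values() for c in row})
    df = pd.DataFrame(
        [[rows[sp].get(c, np.nan) for c in all_codons] for sp in rows],
        index=list(rows),
        columns=all_codons,
    )
    return RscuMatrix(values=df, codes=codes)


def rscu_distance(matrix: RscuMatrix, metric: str = "euclidean") -> DistanceMatrixT:
    """Pairwise species distance over shared (non-missing) codon columns.

    To keep pairs with different numbers of shared columns comparable, each
    pairwise distance is rescaled by the total/shared column ratio (square
    root of the ratio for the euclidean metric). Pairs sharing fewer than 10
    columns are an error.
    """
    if metric not in ("euclidean", "manhattan"):
        raise ValueError("metric must be 'euclidean' or 'manhattan'")
    df = matrix.values
    labels = list(df.index)
    k = len(labels)
    n_total = df.shape[1]
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = df.iloc[i].to_numpy(), df.iloc[j].to_numpy()
            shared = ~(np.isnan(a) | np.isnan(b))
            m = int(shared.sum())
            if m < 10:
                raise ValueError(
                    f"species {labels[i]!r} and {labels[j]!r} share only {m} codon columns"
                )
            diff = a[shared] - b[shared]
            if metric == "euclidean":
                d = float(np.sqrt(diff @ diff)) * np.sqrt(n_total / m)
            else:
                d = float(np.abs(diff).sum()) * (n_total / m)
            out[i, j] = out[j, i] = d
    return DistanceMatrixT(labels=labels, matrix=out)


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def _upgma_newick(dist: DistanceMatrixT) -> str:
    # Average linkage with deterministic tie-break: among minimal-distance
    # pairs, merge the one whose (sorted smallest-leaf-label) pair sorts first.
    labels = dist.labels
    d: Dict[frozenset, float] = {}
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((i, j))] = dist.matrix[i, j]
    newick = {i: lab for i, lab in enumerate(labels)}
    height = {i: 0.0 for i in range(n)}
    size = {i: 1 for i in range(n)}
    minleaf = {i: lab for i, lab in enumerate(labels)}
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = min(
            d.items(),
            key=lambda kv: (kv[1], tuple(sorted((minleaf[i] for i in kv[0])))),
        )
        pair, dij = best
        i, j = sorted(pair, key=lambda x: minleaf[x])
        h = dij / 2.0
        newick[next_id] = (
            f"({newick[i]}:{_fmt(h - height[i])},{newick[j]}:{_fmt(h - height[j])})"
        )
        height[next_id] = h
        size[next_id] = size[i] + size[j]
        minleaf[next_id] = min(minleaf[i], minleaf[j])
        active -= {i, j}
        for k2 in active:
            dik = d.pop(frozenset((i, k2)))
            djk = d.pop(frozenset((j, k2)))
            d[frozenset((next_id, k2))] = (size[i] * dik + size[j] * djk) / (
                size[i] + size[j]
            )
        del d[pair]
        active.add(next_id)
        next_id += 1
    root = active.pop()
    return newick[root] + ";"


def _nj_newick(dist: DistanceMatrixT) -> str:
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    tree = nj(SkbioDM(dist.matrix, ids=dist.labels))
    return str(tree).strip()


def build_tree(dist: DistanceMatrixT, method: str = "upgma") -> str:
    """Cluster a species distance matrix into a Newick tree string.

    UPGMA (default) yields an ultrametric tree with the documented
    lexicographic tie-break; ``method='nj'`` runs neighbour joining
    (scikit-bio).
    """
    if len(dist.labels) < 3:
        raise ValueError("tree building needs >= 3 labels")
    if method == "upgma":
        return _upgma_newick(dist)
    if method == "nj":
        return _nj_newick(dist)
    raise ValueError("method must be 'upgma' or 'nj'")
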