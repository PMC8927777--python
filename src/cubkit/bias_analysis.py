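"""Inferential layer: ENC-plot table, PR2 coordinates, neutrality regression,
correlation matrix, and ΔRSCU-based optimal-codon determination.

The scientific logic: if synonymous codon choice were shaped by mutation
pressure alone, per-gene ENC would sit on the expected-ENC curve as a function
of GC3, PR2 points would sit at (0.5, 0.5) (intra-strand parity A=T, G=C at
third positions), and GC12 would track GC3s with slope ~1. Departures —
ENC below the curve, off-centre PR2 clouds, a shallow neutrality slope —
indicate translational selection. Optimal codons are the synonymous codons
over-used by the most biased (lowest-ENC) genes relative to the least biased:
pooled-RSCU difference ΔRSCU above a threshold (default 0.08) between the two
10% ENC tails.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .codon_stats import (
    CodonCounts,
    CompositionProfile,
    RscuTable,
    expected_enc,
    pool_counts,
    rscu,
)
from .genetic_codes import CODONS, GeneticCode

__all__ = [
    "NeutralityFit",
    "OptimalCodonReport",
    "Pr2Point",
    "correlation_matrix",
    "enc_plot_table",
    "neutrality_fit",
    "optimal_codons",
    "pr2_point",
    "shared_optimal_codons",
]

logger = logging.getLogger(__name__)


def enc_plot_table(profiles: Sequence[CompositionProfile]) -> pd.DataFrame:
    """Per-gene (gc3, enc, expected_enc, enc_ratio) table for the ENC plot.

    ``enc_ratio = enc / expected_enc(gc3)``; genes with undefined ENC are
    dropped (count logged).
    """
    rows = []
    dropped = 0
    for p in profiles:
        if p.enc is None:
            dropped += 1
            continue
        exp = expected_enc(p.gc3)
        rows.append(
            {
                "gene_id": p.gene_id,
                "gc3": p.gc3,
                "enc": p.enc,
                "expected_enc": exp,
                "enc_ratio": p.enc / exp,
            }
        )
    if dropped:
        logger.info("enc_plot_table: dropped %d genes with undefined ENC", dropped)
    return pd.DataFrame(rows, columns=["gene_id", "gc3", "enc", "expected_enc", "enc_ratio"])


@dataclass(frozen=True)
class Pr2Point:
    """Parity-rule-2 coordinates of one gene.

    ``x = G3/(G3+C3)`` (GC bias), ``y = A3/(A3+T3)`` (AT bias) at third
    codon positions; either is ``None`` when its denominator is zero.
    """

    gene_id: str
    x: Optional[float]
    y: Optional[float]


def _fourfold_box_codons(code: GeneticCode) -> Set[str]:
    """Codons of fully degenerate boxes: four synonymous codons sharing the
    first two bases (includes the NNN boxes inside 6-fold families)."""
    out: Set[str] = set()
    for prefix in {c[:2] for c in CODONS}:
        box = [prefix + b for b in "TCAG"]
        aas = {code.codon_to_aa[c] for c in box}
        if len(aas) == 1 and "*" not in aas:
            out.update(box)
    return out


def pr2_point(
    counts: CodonCounts, code: GeneticCode, site_set: str = "all_third"
) -> Pr2Point:
    """PR2 coordinates from a gene's codon counts.

    ``site_set='all_third'`` uses the third position of every counted sense
    codon; ``'fourfold_third'`` restricts to fully degenerate (NNN) boxes,
    where third-position composition is untouched by amino-acid content
    (Sueoka's original convention).
    """
    if site_set == "all_third":
        keep = [c for c in CODONS if c not in code.stop_codons]
    elif site_set == "fourfold_third":
        keep = sorted(_fourfold_box_codons(code))
    else:
        raise ValueError("site_set must be 'all_third' or 'fourfold_third'")
    base = {b: 0 for b in "ACGT"}
    for c in keep:
        base[c[2]] += counts[c]
    gc = base["G"] + base["C"]
    at = base["A"] + base["T"]
    return Pr2Point(
        gene_id=counts.gene_id,
        x=base["G"] / gc if gc else None,
        y=base["A"] / at if at else None,
    )


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3s with its Pearson correlation."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n_genes: int


def neutrality_fit(profiles: Sequence[CompositionProfile]) -> NeutralityFit:
    """Neutrality-plot regression: ordinary least squares of GC12 on GC3s."""
    pts = [(p.gc3s, p.gc12) for p in profiles if p.gc3s is not None]
    if len(pts) < 3:
        raise ValueError(f"neutrality fit needs >= 3 genes with defined GC3s, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("neutrality fit undefined: GC3s has zero variance")
    res = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_genes=len(pts),
    )


DEFAULT_CORR_VARIABLES = ("enc", "gc", "gc3s", "gc12", "a3s", "t3s", "c3s", "g3s")


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame

    def starred(self) -> pd.DataFrame:
        """r values annotated with significance stars (* p<0.05, ** p<0.01)."""
        def star(rv, pv):
            if pd.isna(rv):
                return ""
            s = "**" if pv < 0.01 else "*" if pv < 0.05 else ""
            return f"{rv:.3f}{s}"

        return pd.DataFrame(
            {
                col: [star(self.r.loc[i, col], self.p.loc[i, col]) for i in self.r.index]
                for col in self.r.columns
            },
            index=self.r.index,
        )


def correlation_matrix(
    profiles: Sequence[CompositionProfile],
    variables: Sequence[str] = DEFAULT_CORR_VARIABLES,
    method: str = "pearson",
) -> CorrelationMatrix:
    """Pairwise correlations (with two-sided p-values) between bias indices.

    Pairwise-complete genes are used per variable pair; a constant variable
    yields NaN for its off-diagonal pairs.
    """
    if len(profiles) < 3:
        raise ValueError("correlation matrix needs >= 3 genes")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    data = pd.DataFrame(
        {v: [getattr(p, v) for p in profiles] for v in variables}, dtype=float
    )
    k = len(variables)
    r = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for i, vi in enumerate(variables):
        r[i, i], pmat[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            sub = data[[vi, variables[j]]].dropna()
            if len(sub) < 3 or sub.iloc[:, 0].nunique() < 2 or sub.iloc[:, 1].nunique() < 2:
                continue
            res = corr(sub.iloc[:, 0], sub.iloc[:, 1])
            r[i, j] = r[j, i] = float(res.statistic)
            pmat[i, j] = pmat[j, i] = float(res.pvalue)
    idx = list(variables)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(pmat, index=idx, columns=idx),
    )


@dataclass
class OptimalCodonReport:
    """High/low-bias pooled RSCU comparison for one species."""

    species: str
    n_genes: int
    decile_size: int
    high_set_ids: List[str]
    low_set_ids: List[str]
    rscu_high: RscuTable
    rscu_low: RscuTable
    delta_rscu: Dict[str, Optional[float]]
    optimal: Set[str]
    threshold: float
    code: GeneticCode = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, d in self.delta_rscu.items():
            rows.append(
                {
                    "codon": c,
                    "codon_rna": c.replace("T", "U"),
                    "amino_acid": self.code.codon_to_aa[c] if self.code else "",
                    "rscu_high": self.rscu_high[c],
                    "rscu_low": self.rscu_low[c],
                    "delta_rscu": d,
                    "optimal": c in self.optimal,
                }
            )
        return pd.DataFrame(rows)


def optimal_codons(
    counts_by_gene: Mapping[str, CodonCounts],
    enc_by_gene: Mapping[str, Optional[float]],
    code: GeneticCode,
    species: str = "",
    tail_fraction: float = 0.10,
    threshold: float = 0.08,
    require_high_rscu_gt1: bool = False,
) -> OptimalCodonReport:
    """Determine optimal codons from the ENC tails of a gene set.

    Genes are ranked by ENC ascending (ties broken by gene id, logged); the
    first ``ceil(tail_fraction * n)`` genes (most biased) and the last as many
    (least biased) are pooled into high- and low-bias RSCU tables. Codons with
    ``ΔRSCU = RSCU_high - RSCU_low > threshold`` are flagged optimal; with
    ``require_high_rscu_gt1`` they must also satisfy RSCU_high > 1.
    """
    ranked = sorted(
        (g for g, e in enc_by_gene.items() if e is not None), key=lambda g: (enc_by_gene[g], g)
    )
    n = len(ranked)
    if n < 20:
        raise ValueError(
            f"optimal-codon determination needs >= 20 genes with defined ENC (got {n}); "
            "each 10% tail must hold at least 2 genes"
        )
    enc_vals = [enc_by_gene[g] for g in ranked]
    if len(set(enc_vals)) < n:
        logger.info("optimal_codons: ENC ties broken by gene id")
    d = max(2, math.ceil(tail_fraction * n))
    high_ids, low_ids = ranked[:d], ranked[n - d :]
    rscu_high = rscu(pool_counts([counts_by_gene[g] for g in high_ids], "high"), code)
    rscu_low = rscu(pool_counts([counts_by_gene[g] for g in low_ids], "low"), code)

    delta: Dict[str, Optional[float]] = {}
    optimal: Set[str] = set()
    for c, hi in rscu_high.values.items():
        lo = rscu_low.values[c]
        if hi is None or lo is None:
            delta[c] = None
            continue
        delta[c] = hi - lo
        if delta[c] > threshold and (not require_high_rscu_gt1 or hi > 1.0):
            optimal.add(c)

    return OptimalCodonReport(
        species=species,
        n_genes=n,
        decile_size=d,
        high_set_ids=high_ids,
        low_set_ids=low_ids,
        rscu_high=rscu_high,
        rscu_low=rscu_low,
        delta_rscu=delta,
        optimal=optimal,
        threshold=threshold,
        code=code,
    )


def shared_optimal_codons(reports: Sequence[OptimalCodonReport]) -> Set[str]:
    """Codons flagged optimal in every report (the cross-species consensus)."""
    if len(reports) < 2:
        raise ValueError("shared optimal codons need >= 2 reports")
    shared = set(reports[0].optimal)
    for rep in reports[1:]:
        shared &= rep.optimal
    return shared
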