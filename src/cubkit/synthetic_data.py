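"""Synthetic CDS generator with known composition and selection structure.

The generator emulates the statistical regime of AT-rich ciliate macronuclear
gene sets: hundreds of start/stop-delimited genes with a controllable
per-gene GC3s distribution, a linear GC12-GC3s coupling (the neutrality-plot
slope), and an optional within-family preference for a designated set of
"optimal" codons in a high-bias gene subpopulation. Every emitted codon is
recorded in a ledger, so each downstream statistic can be checked against
ground truth.

Mechanics per gene: an interior length L and a target synonymous-GC3 value g
are drawn; codon counts follow a hierarchical multinomial (stratum totals
first, then codons within strata) whose GC12 target t = a*gc3s + b + eps is
coupled to the gene's *realized* GC3s — see :func:`_draw_gene_counts`.
Amino-acid (family) usage mixes a GC12-rich and a GC12-poor family pool so
that the expected first+second-position GC equals t exactly given the gene's
actual within-family codon probabilities; within a family, codon weights are
the third-position base weight implied by g times ``exp(s)`` for designated
codons of biased genes. Generation is fully determined by the seed (one
global stream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np

from .cds_filter import CodingSequence
from .genetic_codes import CODONS, GeneticCode, get_code

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate",
    "nine_species_scenario",
    "NINE_SPECIES_SHARED_OPTIMAL",
]

#: Shared designated optimal set for the nine-species scenario: AT-ending
#: codons in eight distinct synonymous families (Phe, Tyr, Pro, Val, Ala,
#: Arg, Ser, Thr — one codon per family, so the shared preference is
#: identifiable from each family's RSCU shift), DNA alphabet.
NINE_SPECIES_SHARED_OPTIMAL: Tuple[str, ...] = (
    "TTT", "TAT", "CCT", "GTT", "GCA", "AGA", "AGT", "ACT",
)

# Per-species private preferred codon pairs: drawn from families outside the
# shared set's families, all sense under tables 6 and 10.
_PRIVATE_CANDIDATES = (
    "TTA", "ATT", "CAT", "AAT", "AAA", "GAT", "GAA", "GGA", "TGT",
    "CAA", "CTT", "ATA", "CAC", "AAC", "AAG", "GAC", "GAG", "GGT",
)


@dataclass
class SimConfig:
    """Generator parameters; defaults emulate one AT-rich ciliate-like gene set.

    ``length_codons`` bounds the interior codon count (start/stop added on
    top); ``gc3_mean/gc3_sd`` set the across-gene synonymous-GC3 target
    distribution; ``neutrality_slope``/``gc12_intercept``/``noise_sd`` define
    the GC12 coupling gc12 = a*gc3 + b + N(0, noise_sd); ``optimal_set``
    codons receive an extra within-family log-weight ``preference_strength``
    in the first ``bias_fraction`` of genes.
    """

    n_genes: int = 400
    length_codons: Tuple[int, int] = (100, 300)
    code: int = 6
    gc3_mean: float = 0.30
    gc3_sd: float = 0.05
    neutrality_slope: float = 0.4
    gc12_intercept: float = 0.20
    noise_sd: float = 0.02
    optimal_set: Tuple[str, ...] = ()
    preference_strength: float = 0.0
    bias_fraction: float = 0.10
    species: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        code = get_code(self.code)
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.length_codons
        if not 1 <= lo <= hi:
            raise ValueError(f"bad length_codons range {self.length_codons}")
        if not 0.0 <= self.bias_fraction <= 1.0:
            raise ValueError("bias_fraction must lie in [0, 1]")
        if self.preference_strength < 0:
            raise ValueError("preference_strength must be >= 0")
        if not 0.0 < self.gc3_mean < 1.0:
            raise ValueError("gc3_mean must lie in (0, 1)")
        for c in self.optimal_set:
            if c not in CODONS:
                raise ValueError(f"optimal_set contains non-codon {c!r}")
            if c in code.stop_codons:
                raise ValueError(f"optimal_set codon {c} is a stop under table {self.code}")
            if code.degeneracy_of(c) < 2:
                raise ValueError(f"optimal_set codon {c} has no synonymous alternative")


@dataclass
class GeneTruth:
    gene_id: str
    length_codons: int
    gc3_target: float
    gc12_target: float
    gc12_achieved: float
    biased: bool


@dataclass
class SimTruth:
    """Ground truth of one generated gene set."""

    config: SimConfig
    genes: List[GeneTruth]
    #: codon emission counts matching ``count_codons`` conventions: interior
    #: codons plus the ATG start, terminal stop excluded.
    ledger: np.ndarray = field(repr=False, default=None)

    def ledger_dict(self) -> Dict[str, int]:
        return {c: int(n) for c, n in zip(CODONS, self.ledger) if n}

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "genes": [asdict(g) for g in self.genes],
            "ledger": self.ledger_dict(),
        }


class _GenArrays:
    """Static per-code arrays for the generator."""

    def __init__(self, code: GeneticCode):
        sense = [c for c in CODONS if c not in code.stop_codons]
        self.codons = np.array(sense)
        self.idx64 = np.array([CODONS.index(c) for c in sense])
        fams = code.families
        fam_index = {fam.amino_acid: i for i, fam in enumerate(fams)}
        self.fam_id = np.array([fam_index[code.codon_to_aa[c]] for c in sense])
        self.n_fam = len(fams)
        self.third_gc = np.array([c[2] in "GC" for c in sense], dtype=float)
        self.gc12_codon = np.array(
            [(c[0] in "GC") * 0.5 + (c[1] in "GC") * 0.5 for c in sense]
        )
        # family pools by first+second-position GC at uniform codon weights
        fam_mu_uniform = np.zeros(self.n_fam)
        for i in range(self.n_fam):
            fam_mu_uniform[i] = self.gc12_codon[self.fam_id == i].mean()
        self.rich = fam_mu_uniform >= 0.5
        self.poor = ~self.rich
        # sampling strata: synonymous GC3-enders / synonymous AT3-enders /
        # one-fold codons; stratum totals are drawn first so the gene's
        # realized GC3s is known before families are placed
        deg = np.array([len(fams[self.fam_id[i]].codons) for i in range(len(sense))])
        stratum = np.where(deg < 2, 2, np.where(self.third_gc > 0, 0, 1))
        self.stratum_idx = [np.flatnonzero(stratum == k) for k in range(3)]


def _gen_arrays(code: GeneticCode) -> _GenArrays:
    if not hasattr(_gen_arrays, "_cache"):
        _gen_arrays._cache = {}
    if code.table_id not in _gen_arrays._cache:
        _gen_arrays._cache[code.table_id] = _GenArrays(code)
    return _gen_arrays._cache[code.table_id]


def _gene_codon_probs(
    arrs: _GenArrays, g: float, t: float, s: float, opt_mask: np.ndarray, biased: bool
) -> np.ndarray:
    """Codon probability vector over sense codons for one gene."""
    w3 = np.where(arrs.third_gc > 0, g, 1.0 - g)
    v = w3 * np.exp(s * opt_mask) if (biased and s > 0) else w3
    fam_sum = np.bincount(arrs.fam_id, weights=v, minlength=arrs.n_fam)
    p_in_fam = v / fam_sum[arrs.fam_id]
    # per-family expected first+second-position GC under these codon weights
    fam_mu = np.bincount(
        arrs.fam_id, weights=p_in_fam * arrs.gc12_codon, minlength=arrs.n_fam
    )
    mu_rich = fam_mu[arrs.rich].mean()
    mu_poor = fam_mu[arrs.poor].mean()
    if mu_rich - mu_poor < 1e-9:
        w = 0.5
    else:
        w = float(np.clip((t - mu_poor) / (mu_rich - mu_poor), 0.0, 1.0))
    fam_prob = np.where(
        arrs.rich, w / arrs.rich.sum(), (1.0 - w) / arrs.poor.sum()
    )
    return fam_prob[arrs.fam_id] * p_in_fam


def _draw_gene_counts(
    rng: np.random.Generator,
    arrs: "_GenArrays",
    L: int,
    g: float,
    config: "SimConfig",
    opt_mask: np.ndarray,
    biased: bool,
) -> Tuple[np.ndarray, float]:
    """Hierarchical multinomial draw of one gene's codon counts.

    Stratum totals (synonymous GC3 / synonymous AT3 / one-fold codons) are
    drawn first, which fixes the gene's realized GC3s; the GC12 target is
    then coupled to that *realized* value — gc12 = a*gc3s + b + eps — before
    families and codons are placed within the strata. Coupling to the
    realized rather than the drawn target keeps the recoverable neutrality
    slope equal to the configured one (no errors-in-variables attenuation),
    while within-family codon identities stay multinomial, which is what
    Wright's ENC estimator assumes. Returns (counts, gc12 target used).
    """
    t0 = config.neutrality_slope * g + config.gc12_intercept
    p0 = _gene_codon_probs(
        arrs, g, t0, config.preference_strength, opt_mask, biased
    )
    mass = np.array([p0[idx].sum() for idx in arrs.stratum_idx])
    n_str = rng.multinomial(L, mass / mass.sum())
    n_syn = int(n_str[0] + n_str[1])
    gc3s_real = float(n_str[0] / n_syn) if n_syn else g
    t = config.neutrality_slope * gc3s_real + config.gc12_intercept + float(
        rng.normal(0.0, config.noise_sd)
    )
    p1 = _gene_codon_probs(
        arrs, g, t, config.preference_strength, opt_mask, biased
    )
    counts = np.zeros(len(p1), dtype=np.int64)
    for k, idx in enumerate(arrs.stratum_idx):
        if n_str[k] == 0:
            continue
        q = p1[idx]
        counts[idx] = rng.multinomial(int(n_str[k]), q / q.sum())
    return counts, t


def generate(config: SimConfig) -> Tuple[List[CodingSequence], SimTruth]:
    """Generate a CDS set plus its ground truth.

    Every emitted gene passes the strict CDS filter by construction: ATG
    start, canonical terminator, no internal stop under the configured code,
    interior length above the default 300-nt threshold.
    """
    config.validate()
    code = get_code(config.code)
    arrs = _gen_arrays(code)
    rng = np.random.default_rng(config.seed)
    opt_mask = np.isin(arrs.codons, list(config.optimal_set)).astype(float)
    stops = sorted(code.stop_codons)

    n_biased = int(round(config.bias_fraction * config.n_genes))
    lo, hi = config.length_codons
    records: List[CodingSequence] = []
    genes: List[GeneTruth] = []
    ledger = np.zeros(64, dtype=np.int64)
    atg64 = CODONS.index("ATG")
    width = len(str(config.n_genes))

    for i in range(config.n_genes):
        L = int(rng.integers(lo, hi + 1))
        g = float(np.clip(rng.normal(config.gc3_mean, config.gc3_sd), 0.02, 0.98))
        biased = i < n_biased
        counts, t = _draw_gene_counts(rng, arrs, L, g, config, opt_mask, biased)
        order = np.repeat(np.arange(len(counts)), counts)
        rng.shuffle(order)
        body = "".join(arrs.codons[order])
        stop = stops[int(rng.integers(len(stops)))]
        gene_id = f"{config.species}_g{i:0{width}d}"
        records.append(
            CodingSequence(id=gene_id, seq="ATG" + body + stop, species=config.species)
        )
        np.add.at(ledger, arrs.idx64, counts)
        ledger[atg64] += 1  # start codon, counted as Met downstream
        achieved = float((counts * arrs.gc12_codon).sum() / L)
        genes.append(GeneTruth(gene_id, L, g, t, achieved, biased))

    return records, SimTruth(config=config, genes=genes, ledger=ledger)


def nine_species_scenario(
    base_seed: int,
    n_genes: int = 250,
    length_codons: Tuple[int, int] = (120, 360),
    preference_strength: float = 2.0,
    gc3_sd: float = 0.03,
) -> Tuple[Dict[str, Tuple[List[CodingSequence], SimTruth]], dict]:
    """Nine AT-rich species sharing one designated 8-codon optimal set.

    Mirrors the multi-species design the analysis targets: per-species GC3
    means spread over [0.18, 0.40], a common 8-codon preferred set plus two
    private preferred codons per species, eight species on the ciliate
    nuclear code (table 6) and one on the euplotid code (table 10). Returns
    ``(datasets, meta)`` where ``datasets`` maps species label to (records,
    truth) and ``meta`` records the shared set, private sets, and per-species
    code ids.
    """
    gc3_means = np.linspace(0.18, 0.40, 9)
    seeds = (np.random.SeedSequence(base_seed).generate_state(9) % (2**31)).tolist()
    datasets: Dict[str, Tuple[List[CodingSequence], SimTruth]] = {}
    privates: Dict[str, Tuple[str, str]] = {}
    codes: Dict[str, int] = {}
    for i in range(9):
        label = f"species_{i + 1}"
        table = 10 if i == 8 else 6
        private = (_PRIVATE_CANDIDATES[2 * i], _PRIVATE_CANDIDATES[2 * i + 1])
        cfg = SimConfig(
            n_genes=n_genes,
            length_codons=length_codons,
            code=table,
            gc3_mean=float(gc3_means[i]),
            gc3_sd=gc3_sd,
            optimal_set=NINE_SPECIES_SHARED_OPTIMAL + private,
            preference_strength=preference_strength,
            bias_fraction=0.10,
            species=label,
            seed=int(seeds[i]),
        )
        datasets[label] = generate(cfg)
        privates[label] = private
        codes[label] = table
    meta = {
        "shared_optimal": set(NINE_SPECIES_SHARED_OPTIMAL),
        "private_by_species": privates,
        "codes_by_species": codes,
        "base_seed": base_seed,
    }
    return datasets, meta
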