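import numpy as np
import pytest

from cubkit.codon_stats import CODON_INDEX, CodonCounts
from cubkit.genetic_codes import get_code


@pytest.fixture(scope="session")
def code1():
    return get_code(1)


@pytest.fixture(scope="session")
def code6():
    return get_code(6)


@pytest.fixture(scope="session")
def code10():
    return get_code(10)


def counts_from(d: dict, gene_id: str = "g") -> CodonCounts:
    """Build a CodonCounts from a {codon: count} dict."""
    v = np.zeros(64, dtype=np.int64)
    for codon, n in d.items():
        v[CODON_INDEX[codon]] = n
    return CodonCounts(gene_id=gene_id, counts=v)


def random_gene_counts(rng: np.random.Generator, code, n_codons: int) -> CodonCounts:
    """Random counts over the code's sense codons (skewed Dirichlet usage)."""
    sense = code.sense_codons
    p = rng.dirichlet(np.full(len(sense), 0.5))
    draws = rng.multinomial(n_codons, p)
    return counts_from(dict(zip(sense, draws)))
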