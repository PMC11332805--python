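import numpy as np
import pytest

from codonvar import simulate
from codonvar.codes import CODONS


@pytest.fixture
def rng():
    return np.random.default_rng(20240805)


def random_coding_sequence(rng, n_codons: int, ambiguous_rate: float = 0.0) -> str:
    """A random in-frame sequence, optionally salted with N bases."""
    bases = rng.choice(list("ACGT"), size=3 * n_codons)
    if ambiguous_rate:
        mask = rng.random(bases.size) < ambiguous_rate
        bases[mask] = "N"
    return "".join(bases)


@pytest.fixture(scope="session")
def small_collection():
    """One modest default-design collection, shared across read-only tests."""
    return simulate.simulate_collection(
        simulate.default_config(n_genomes=120, genes_per_genome=60, seed=7)
    )


@pytest.fixture
def toy_fasta(tmp_path):
    """Three-gene CDS FASTA in the bracketed header dialect."""
    text = (
        ">g1 [gene=tuf] [product=elongation factor EF-Tu]\n"
        "atgaaataa\n"
        ">g2 [pseudo=true]\n"
        "ATGCCCTAA\n"
        ">g3 [product=hypothetical protein]\n"
        "ATGGGGAAATAA\n"
    )
    path = tmp_path / "toy.fna"
    path.write_text(text)
    return path
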