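import numpy as np
import pytest

from orf2pep.seqio import GenomeRecord, PeptideRecord
from orf2pep.synthetic_data import (GenomeSimSpec, PeptideSimSpec,
                                    make_orf_dataset, simulate_genome,
                                    simulate_peptides)


@pytest.fixture(scope="session")
def small_genome():
    """10 kb synthetic genome with 10 strongly biased genes plus truth."""
    return simulate_genome(GenomeSimSpec(length=10_000, n_genes=10, seed=11))


@pytest.fixture(scope="session")
def peptide_set():
    spec = PeptideSimSpec(n_pos=200, n_neg=200, seed=702)
    return simulate_peptides(spec)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
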