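import numpy as np
import pytest

from unilocus.seqio import SequenceRecord
from unilocus.synthetic_data import GenomeSpec, generate_genome

BASES = np.array(list("ACGT"))


def random_sequence(rng, n, gc=0.38):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=n, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_genome():
    """A compact planted genome reused across pipeline tests:
    2 x 12 kb scaffolds, 8 planted SSRs, 2 of them duplicated."""
    spec = GenomeSpec(seed=11, n_scaffolds=2, scaffold_length=12_000,
                      n_ssrs=8, frac_duplicated=0.25)
    return generate_genome(spec)


def write_fasta_text(path, text):
    path.write_text(text)
    return str(path)


@pytest.fixture
def make_record():
    def _make(seq, name="s1"):
        return SequenceRecord(id=name, residues=seq)
    return _make
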