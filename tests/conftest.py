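import numpy as np
import pytest

from seedquant.align import progressive_msa
from seedquant.seqsim import SequenceSimParams, simulate_sequence_family

N_FAMILIES = 50


@pytest.fixture(scope="session")
def simulated_families():
    """Fifty default sequence families with their progressive MSAs.

    Shared across tree-recovery, clade and site-scan tests because the
    pairwise alignments dominate runtime.
    """
    out = []
    for seed in range(N_FAMILIES):
        fam = simulate_sequence_family(SequenceSimParams(rng_seed=seed))
        aln = progressive_msa(list(fam.records))
        out.append((fam, aln))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
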