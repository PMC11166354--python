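"""Shared fixtures: one synthetic haplotype (and its indexes) per session."""

import numpy as np
import pytest

from repeatloop import simulate, workflows


@pytest.fixture(scope="session")
def sim_hap():
    return simulate.generate_haplotype(rng=1)


@pytest.fixture(scope="session")
def indexes(sim_hap):
    """(genome, collapsed, structural) SequenceIndex triple."""
    return workflows.haplotype_indexes(sim_hap)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
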