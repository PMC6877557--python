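import random

import pytest
from hypothesis import settings

from repeatspan.connection_assembly import connect_contigs
from repeatspan.overlap_model import Params
from repeatspan.synthetic_data import (fragment_into_contigs,
                                       naive_overlap_detect, simulate_genome,
                                       simulate_reads)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_params():
    # small-genome settings: anchors from 20 kb, 10 kb end window
    return Params(seed=7, anchor_min_len=20_000, l_se=10_000)


@pytest.fixture(scope="session")
def tiny_fixture(tiny_params):
    """Error-free desk fixture: U-R-U-R'(96%)-U genome, 25x exact reads.

    At 96% copy identity every cross-copy overlap falls below the default
    identity cutoff, so both repeat gaps are assembled exactly.
    """
    rng = random.Random(7)
    spec = [("unique", 30_000), ("repeat", "R", 12_000), ("unique", 28_000),
            ("copy", "R", 0.96), ("unique", 30_000)]
    truth = simulate_genome(spec, rng)
    contigs = fragment_into_contigs(truth, into_repeat=2_000)
    reads = simulate_reads(truth, depth=25, mean_len=5_000, err_rate=0.0,
                           rng=rng)
    paf = naive_overlap_detect(list(contigs) + reads)
    return truth, contigs, reads, paf


@pytest.fixture(scope="session")
def tiny_result(tiny_fixture, tiny_params):
    truth, contigs, reads, paf = tiny_fixture
    return connect_contigs(contigs, reads, paf, tiny_params)
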