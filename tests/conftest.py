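import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from sap.index import build_index
from sap.io_formats import ReferenceSeq
from sap.simulator import random_reference


@pytest.fixture(scope="session")
def small_ref() -> ReferenceSeq:
    return random_reference(3_000, seed=11, name="chrT")


@pytest.fixture(scope="session")
def small_index(small_ref):
    return build_index([small_ref], k=15)


@pytest.fixture(scope="session")
def bench_table():
    """One shared end-to-end benchmark for the acceptance tests.

    A 250 kb synthetic reference, the five read-length/coverage cells the
    reported results hinge on, two replicates; both mapping modes.
    """
    from sap.evaluate import run_benchmark

    ref = random_reference(250_000, seed=424242)
    cells = [(75, 5), (75, 20), (150, 5), (1000, 5), (1000, 20)]
    return run_benchmark(ref, cells, replicates=2, seed=90210)
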