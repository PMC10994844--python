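import numpy as np
import pytest

from txatlas.demo import build_demo
from txatlas.evaluate import annotate_genome
from txatlas.models import CoverageSet, Gene, GenomeBundle


@pytest.fixture(scope="session")
def demo_bundle():
    """One fully generated demo dataset shared across the suite."""
    return build_demo(seed=7)


@pytest.fixture(scope="session")
def demo_annotation(demo_bundle):
    return annotate_genome(demo_bundle.genome, demo_bundle.coverage)


@pytest.fixture()
def empty_coverage():
    def make(length=5000, replicon="replicon1"):
        return CoverageSet({replicon: length})

    return make


@pytest.fixture()
def small_genome():
    rng = np.random.default_rng(123)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 6000))
    genes = [
        Gene("gA", "replicon1", 2000, 3000, "+"),
        Gene("gB", "replicon1", 3500, 4200, "+"),
    ]
    return GenomeBundle(replicons={"replicon1": seq}, genes=genes)
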