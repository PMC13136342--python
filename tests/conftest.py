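import pytest

from tdrprof.synthetic import (
    demo_bundle,
    simulate_library,
    sperm_library_spec,
)


@pytest.fixture(scope="session")
def bundle():
    return demo_bundle()


@pytest.fixture(scope="session")
def small_library(bundle):
    """2,000-read sperm-like library with truth labels (fixed seed)."""
    spec = sperm_library_spec(2000, seed=7)
    return simulate_library(spec, bundle=bundle)


@pytest.fixture(scope="session")
def classified(bundle, small_library):
    from tdrprof.classify import sequential_classify

    reads, truth = small_library
    assignments = sequential_classify(reads, bundle)
    reads_by_id = {r.read_id: r for r in reads}
    return assignments, reads_by_id, truth
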