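import pytest

from adekb import RandomKbParams, build_paper_fixture, random_kb


@pytest.fixture(scope="session")
def paper_kb():
    """The curated worked-example knowledge base (read-only in tests)."""
    return build_paper_fixture()


#: Small generator shape used by oracle-comparison tests: ~480 association
#: draws per knowledge base keeps brute-force scans fast.
SMALL_PARAMS = dict(n_drugs=5, n_aes=6, n_diseases=3, n_moa_classes=5, hierarchy_depth=3)


def small_random_kb(seed, assoc_prob=0.08):
    return random_kb(RandomKbParams(seed=seed, assoc_prob=assoc_prob, **SMALL_PARAMS))
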