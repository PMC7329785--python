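import pytest

import cdr3kit as ck


@pytest.fixture(scope="session")
def cdr3_scheme():
    """The six-codon XBBXBX-biased scheme, NNS MRN MRN NNS MRN NNS."""
    return ck.xbbxbx_scheme()


@pytest.fixture(scope="session")
def xbbxbx():
    return ck.parse_pattern("XBBXBX")


@pytest.fixture(scope="session")
def gzzprkx():
    return ck.parse_pattern("GZZP(R/K)X")


@pytest.fixture(scope="session")
def big_clean_library(cdr3_scheme, xbbxbx):
    """100k clones sampled with zero corruption, shared across Monte-Carlo
    checks (full-length rate at the stop-free ceiling)."""
    config = ck.SimulationConfig(
        scheme=cdr3_scheme,
        n_clones=100_000,
        seed=20_201,
        full_length_rate=float(
            ck.diversity(cdr3_scheme).stop_free_fraction_exact
        ),
    )
    return ck.sample_library(config, [xbbxbx])
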