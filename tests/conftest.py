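import pytest

from cnvreport.simulate import (
    CorpusSimConfig,
    InterpSimConfig,
    simulate_corpus,
    simulate_interpretation_fixtures,
    toy_cytobands,
)


@pytest.fixture(scope="session")
def cytobands():
    return toy_cytobands()


@pytest.fixture(scope="session")
def seed1_corpus():
    """The benchmark corpus: 500 reports, default noise, seed 1."""
    return simulate_corpus(CorpusSimConfig(seed=1, n_reports=500))


@pytest.fixture(scope="session")
def small_corpus():
    """A quick corpus for unit tests that train models."""
    return simulate_corpus(CorpusSimConfig(seed=3, n_reports=120))


@pytest.fixture(scope="session")
def interp_fixtures():
    """The interpretation benchmark: 200 planted CNVs, seed 7."""
    return simulate_interpretation_fixtures(InterpSimConfig(seed=7, n_cnvs=200))
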