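import numpy as np
import pandas as pd
import pytest

from phoscoreg import (
    RegulationMatrix,
    SimulationConfig,
    SiteKey,
    corpus_matrix,
    simulate_corpus,
)


def make_matrix(states_by_site, condition_pmids):
    """Build a RegulationMatrix from {SiteKey: [states...]} and {condition: pmid}."""
    conditions = list(condition_pmids)
    df = pd.DataFrame(
        {c: [states_by_site[s][j] for s in states_by_site] for j, c in enumerate(conditions)},
        index=pd.Index(list(states_by_site)),
        dtype=object,
    )
    return RegulationMatrix(states=df, condition_pmids=dict(condition_pmids))


ANCHOR = SiteKey("PKN1", "S", 562)
PARTNER = SiteKey("MAPT", "T", 548)


@pytest.fixture
def toy_matrix():
    """Six-condition toy: anchor UUDNUN vs partner UDDNNU -> a,b,c,d = 1,2,1,2."""
    return make_matrix(
        {ANCHOR: list("UUDNUN"), PARTNER: list("UDDNNU")},
        {"E1": "P1", "E2": "P1", "E3": "P2", "E4": "P2", "E5": "P3", "E6": "P3"},
    )


@pytest.fixture(scope="session")
def default_corpus():
    return simulate_corpus(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_matrix(default_corpus):
    return corpus_matrix(default_corpus)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
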