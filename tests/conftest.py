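import numpy as np
import pandas as pd
import pytest

from optenrich.library import (
    EffectModel,
    build_library,
    default_efficacies,
    simulate_population,
)
from optenrich.scoring import CountTable


@pytest.fixture(scope="session")
def small_library():
    """10 single-TSS genes x 10 sgRNAs + 5 nontargeting controls."""
    return build_library(10, 0, 10, 5, seed=0)


@pytest.fixture(scope="session")
def screen_library():
    """The canonical screening library: 544 genes, 6,092 sgRNAs."""
    return build_library(481, 63, 10, 22, seed=0)


@pytest.fixture(scope="session")
def small_population(small_library):
    effects = EffectModel(sgrna_efficacy=default_efficacies(small_library, seed=0))
    return simulate_population(small_library, effects, 50, 0.95, seed=3)


@pytest.fixture()
def toy_count_table():
    """Three-sgRNA toy table: one enriched sgRNA and two nontargeting."""
    frame = pd.DataFrame(
        {
            "gene": ["GA", "NONTARGETING", "NONTARGETING"],
            "tss": ["GA_T1", "", ""],
            "sample": [8, 1, 1],
            "reference": [2, 1, 1],
        },
        index=pd.Index(["A", "NT1", "NT2"], name="sgrna_id"),
    )
    return CountTable(frame)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
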