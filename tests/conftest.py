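import numpy as np
import pandas as pd
import pytest

from retidiv import (
    SimSeqConfig,
    SurveyDataset,
    simulate_reference_panel,
)


@pytest.fixture(scope="session")
def small_panel_and_queries():
    """3-species panel with a clear barcode gap, plus labeled queries."""
    cfg = SimSeqConfig(
        n_species=3,
        refs_per_species=3,
        queries_per_species=5,
        seq_length=300,
        between_divergence=0.06,
        within_divergence=0.006,
        seed=11,
    )
    return simulate_reference_panel(cfg)


@pytest.fixture(scope="session")
def small_panel(small_panel_and_queries):
    return small_panel_and_queries[0]


@pytest.fixture
def tiny_survey():
    """Hand-built 3-site survey with tabulation worked out by hand.

    s1, s2 north in county cA; s3 south in county cB.
    Samples: s1 {sp1, sp2}, s2 {sp1}, s3 {sp1, sp2, sp2}.
    """
    sites = pd.DataFrame(
        {
            "site_id": ["s1", "s2", "s3"],
            "x": [1.0, 2.0, 3.0],
            "y": [10.0, 11.0, 1.0],
            "county_id": ["cA", "cA", "cB"],
            "stratum": ["north", "north", "south"],
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"m{i}" for i in range(1, 7)],
            "site_id": ["s1", "s1", "s2", "s3", "s3", "s3"],
            "species": ["sp1", "sp2", "sp1", "sp1", "sp2", "sp2"],
        }
    )
    return SurveyDataset(sites, samples)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
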