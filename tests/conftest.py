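import warnings

import numpy as np
import pytest

from reefpam.synthetic import ScenarioConfig, default_sites


@pytest.fixture(autouse=True)
def _quiet_model_warnings():
    # MixedLM emits convergence chatter on boundary fits; the fits themselves
    # are checked explicitly where it matters
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        warnings.filterwarnings("ignore", message=".*[Cc]onverge.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20210201)


@pytest.fixture
def tiny_scenario():
    """Two couplets, one year, short segments: fast end-to-end fixture."""
    return ScenarioConfig(
        sites=default_sites()[:4],
        years=["2021"],
        n_days_per_site=1,
        segment_minutes_per_period=0.05,
        seed=42,
    )


@pytest.fixture(scope="session")
def demo_corpus(tmp_path_factory):
    """Small on-disk campaign shared by ingest/pipeline tests."""
    from reefpam.synthetic import simulate_campaign

    scenario = ScenarioConfig(
        sites=default_sites()[:4],
        years=["2015", "2021"],
        n_days_per_site=1,
        segment_minutes_per_period=0.05,
        seed=7,
    )
    out = tmp_path_factory.mktemp("corpus")
    result = simulate_campaign(scenario, out)
    result["scenario"] = scenario
    return result
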