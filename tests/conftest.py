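import numpy as np
import pytest

from echoclick.pipeline import click_table_to_events, snippet_run
from echoclick.simulate import SimConfig, default_templates, generate_dataset


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def small_dataset():
    """Default event/encounter design with shortened click trains."""
    cfg = SimConfig(clicks_per_event_median=20, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_click_table(small_dataset):
    return snippet_run(small_dataset)


@pytest.fixture(scope="session")
def small_event_table(small_click_table):
    return click_table_to_events(small_click_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
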