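import numpy as np
import pandas as pd
import pytest

from psylink import AffinityPanel, Testimonial


@pytest.fixture
def toy_corpus() -> list[Testimonial]:
    """Three tiny reports over two drugs with hand-countable tokens."""
    return [
        Testimonial("t1", "drugA", "Universe universe voices love, love love!"),
        Testimonial("t2", "drugA", "Walls melting; colors breathing... colors"),
        Testimonial("t3", "drugB", "Deep peace and love under the stars"),
    ]


@pytest.fixture
def toy_panel() -> AffinityPanel:
    ki = pd.DataFrame(
        {
            "5-HT2A": [10.0, 250.0],
            "D2": [1000.0, np.nan],
            "NMDA": [np.nan, 50.0],
        },
        index=["drugA", "drugB"],
    )
    return AffinityPanel(ki)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
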