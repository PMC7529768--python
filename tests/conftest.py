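import numpy as np
import pandas as pd
import pytest

from scapd.geometry import disc, ellipse
from scapd.io import colonies_to_table


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def disc_pattern():
    return disc()


@pytest.fixture
def ellipse_pattern():
    return ellipse()


def pooled_table(finals) -> pd.DataFrame:
    """Flatten final colony snapshots into the standard cell table."""
    return colonies_to_table(finals)
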