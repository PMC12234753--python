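import numpy as np
import pandas as pd
import pytest

from descnet.io import DescriptionTable


@pytest.fixture
def hand_table():
    """2 participants x 1 video x 3 pauses, 6 records."""
    rows = [
        ("p1", "v1", 1, 1, "kind"),
        ("p1", "v1", 2, 1, "smart"),
        ("p1", "v1", 3, 1, "happy"),
        ("p2", "v1", 1, 1, "kind"),
        ("p2", "v1", 2, 1, "funny"),
        ("p2", "v1", 3, 1, "kind"),
    ]
    df = pd.DataFrame(rows, columns=["participant", "video", "pause", "position", "word"])
    return DescriptionTable(df, provenance="hand fixture")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
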