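import numpy as np
import pandas as pd
import pytest

from scorekit import default_catalog


def rows_frame(*rows):
    """Build an item DataFrame from python lists (None = missing)."""
    return pd.DataFrame(
        [[np.nan if x is None else x for x in row] for row in rows],
        columns=[f"item_{j + 1:03d}" for j in range(len(rows[0]))],
        dtype=float,
    )


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def fes_frame():
    """A small hand-written cohesion-subscale table with known missingness
    per row: 0, 1, 2, 0 missing items."""
    data = {
        "participant_id": ["P1", "P2", "P3", "P4"],
        "session_id": ["s01"] * 4,
    }
    items = [
        [1, 0, 1, 1, 0, 1, 1, 1, 0],
        [0, 1, None, 1, 0, 0, 1, 1, 0],
        [1, None, 0, 1, None, 1, 0, 1, 1],
        [0, 0, 0, 1, 1, 1, 0, 1, 1],
    ]
    for j in range(9):
        data[f"fc_p_fes__cohes_{j + 1:03d}"] = [
            np.nan if row[j] is None else float(row[j]) for row in items
        ]
    return pd.DataFrame(data)
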