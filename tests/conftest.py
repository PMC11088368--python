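import numpy as np
import pandas as pd
import pytest

from chemprofile import AlignedPeakMatrix, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One study-shaped synthetic dataset (20 samples + 7 blanks)."""
    return generate_dataset(SimConfig(), seed=1234)


@pytest.fixture()
def toy_matrix():
    """5 samples (1 blank) x 6 substances: 1 blank-borne, 2 singleton columns.

    Columns: rt 5.0 contaminant (present in the blank), rt 6.0 and 7.0
    singletons (one biological sample each), rt 8.0-10.0 ordinary substances.
    """
    data = pd.DataFrame(
        [
            # 5.0  6.0  7.0  8.0  9.0  10.0
            [0.0, 9.0, 0.0, 60.0, 30.0, 10.0],  # s1
            [2.0, 0.0, 0.0, 40.0, 30.0, 30.0],  # s2
            [0.0, 0.0, 4.0, 10.0, 0.0, 90.0],  # s3
            [1.0, 0.0, 0.0, 25.0, 25.0, 50.0],  # s4
            [3.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # blank
        ],
        index=["s1", "s2", "s3", "s4", "blank1"],
        columns=[5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
    )
    return AlignedPeakMatrix(data, stage="aligned")


@pytest.fixture()
def toy_metadata():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4", "blank1"],
            "sex": ["female", "female", "male", "male", "not-applicable"],
            "pair_id": [None, None, None, None, None],
            "days_after_laying": [1.0, 5.0, 10.0, 20.0, np.nan],
            "is_blank": [False, False, False, False, True],
        }
    )


@pytest.fixture()
def paired_metadata():
    """Study-shaped metadata: 9 F + 11 M, four complete female/male pairs."""
    rows = []
    for i in range(9):
        rows.append(("F%02d" % (i + 1), "female", f"P{i+1}" if i < 4 else None, 3 + i, False))
    for i in range(11):
        rows.append(("M%02d" % (i + 1), "male", f"P{i+1}" if i < 4 else None, 3 + i, False))
    return pd.DataFrame(
        rows, columns=["sample_id", "sex", "pair_id", "days_after_laying", "is_blank"]
    )
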