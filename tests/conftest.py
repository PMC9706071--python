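import numpy as np
import pandas as pd
import pytest

from headingbias import ObserverParams, simulate_cohort


@pytest.fixture(scope="session")
def exp1_cohort() -> pd.DataFrame:
    """Small noisy exp1-style cohort shared across tests."""
    return simulate_cohort(
        ["symmetric_wide_uniform", "right_shifted_narrow_uniform"],
        6,
        ObserverParams(slope_s=0.8, noise_sigma=2.0),
        seed=42,
        slope_sd=0.05,
    )


@pytest.fixture()
def identity_table() -> pd.DataFrame:
    """Deterministic PH == AH table, two participants, one condition."""
    headings = np.array([-15.0, -9.0, -3.0, 3.0, 9.0, 15.0])
    rows = []
    for pid in ("p1", "p2"):
        ah = np.tile(headings, 4)
        rows.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "condition": "sym",
                    "trial": np.arange(1, ah.size + 1),
                    "ah_deg": ah,
                    "ph_deg": ah,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
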