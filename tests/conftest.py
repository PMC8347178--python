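import numpy as np
import pandas as pd
import pytest

from junctionkit import simulate
from junctionkit.localize import LOCALIZATION_COLUMNS, LocalizationTable


@pytest.fixture(scope="session")
def small_geometry():
    """4-cell junction network in a 6.4 µm field."""
    return simulate.generate_junction_network(4, (6400.0, 6400.0), seed=2)


@pytest.fixture(scope="session")
def medium_geometry():
    """6-cell junction network in a 12.8 µm field."""
    return simulate.generate_junction_network(6, (12800.0, 12800.0), seed=3)


def table_from_points(points: np.ndarray, pixel_nm: float = 80.0) -> LocalizationTable:
    """Wrap bare coordinates as a localization table for spatial ops."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    records = pd.DataFrame(
        {
            "frame": np.full(n, 30),
            "x_nm": points[:, 0],
            "y_nm": points[:, 1],
            "amplitude": np.ones(n),
            "sigma_nm": np.full(n, 130.0),
            "offset": np.zeros(n),
            "err_x_nm": np.full(n, 5.0),
            "err_y_nm": np.full(n, 5.0),
        },
        columns=LOCALIZATION_COLUMNS,
    )
    return LocalizationTable(records=records, pixel_nm=pixel_nm)
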