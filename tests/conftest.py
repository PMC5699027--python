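import numpy as np
import pandas as pd
import pytest

import povgp


@pytest.fixture(scope="session")
def small_config():
    return povgp.SyntheticConfig(
        n_communes=25,
        n_urban=5,
        n_regions=3,
        map_extent_km=200.0,
        subscribers_per_commune=(4, 8),
        events_per_month_mean=25.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_map(small_config):
    return povgp.generate_commune_map(small_config)


@pytest.fixture(scope="session")
def small_antennas(small_config, small_map):
    return povgp.place_antennas(small_map, small_config)


def make_log(rows):
    """Event log from (subscriber, antenna, timestamp, kind, direction, peer)."""
    df = pd.DataFrame(
        rows,
        columns=["subscriber_id", "antenna_id", "timestamp", "kind", "direction", "peer_id"],
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["duration_s"] = np.where(df["kind"] == "call", 60.0, np.nan)
    return df[
        ["subscriber_id", "antenna_id", "timestamp", "kind", "duration_s", "direction", "peer_id"]
    ]
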