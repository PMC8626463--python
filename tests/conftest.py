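import numpy as np
import pandas as pd
import pytest

from brushdom import scenario_default, simulate_herd

T0 = pd.Timestamp("2021-03-01")


def ts(text: str) -> pd.Timestamp:
    return pd.Timestamp(text)


def make_roster(cow_ids, entry="2021-02-20", calving="2021-06-01",
                excluded=()) -> pd.DataFrame:
    return pd.DataFrame({
        "cow_id": list(cow_ids),
        "entry_time": pd.Timestamp(entry),
        "calving_time": pd.Timestamp(calving),
        "parity": 3,
        "excluded": [c in excluded for c in cow_ids],
        "exclusion_reason": ["health event" if c in excluded else ""
                             for c in cow_ids],
    })


def make_visits(rows) -> pd.DataFrame:
    """rows: (cow_id, bin_id, bin_type, start, end) with ISO strings."""
    df = pd.DataFrame(rows, columns=["cow_id", "bin_id", "bin_type",
                                     "start_time", "end_time"])
    df["start_time"] = pd.to_datetime(df["start_time"])
    df["end_time"] = pd.to_datetime(df["end_time"])
    return df


def random_visit_log(rng: np.random.Generator, n_visits=120, n_bins=5,
                     n_cows=8) -> pd.DataFrame:
    """Random non-overlapping visit log: per bin, a chain of visits with
    random gaps (many below 26 s) and random cows."""
    rows = []
    for b in range(n_bins):
        t = int(rng.integers(0, 600))
        for _ in range(int(n_visits / n_bins)):
            dur = int(rng.integers(30, 600))
            cow = f"C{rng.integers(n_cows):02d}"
            rows.append((cow, f"F{b:02d}", "feed",
                         T0 + pd.Timedelta(seconds=t),
                         T0 + pd.Timedelta(seconds=t + dur)))
            t += dur + int(rng.integers(0, 80))
    df = pd.DataFrame(rows, columns=["cow_id", "bin_id", "bin_type",
                                     "start_time", "end_time"])
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))
                     ).reset_index(drop=True)


@pytest.fixture(scope="session")
def small_sim():
    """One 21-day herd simulation shared by read-only tests."""
    return simulate_herd(scenario_default(sim_days=21, seed=11))


@pytest.fixture(scope="session")
def default_sim():
    """The default 60-day scenario (hierarchy-recovery scale)."""
    return simulate_herd(scenario_default(seed=20210301))
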