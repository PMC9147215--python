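import numpy as np
import pandas as pd
import pytest

from panelcast import (
    PanelSeries,
    SyntheticConfig,
    generate_panel,
    generate_toy_system,
    fit_standardizer,
    sequential_split,
)


@pytest.fixture(scope="session")
def default_panel() -> PanelSeries:
    """One synthetic patient at generator defaults (42 visits / 369 days)."""
    return generate_panel(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def toy_split_stats():
    """Preprocessed noiseless toy trajectory: (split, stats)."""
    toy = generate_toy_system(739, seed=11)
    split = sequential_split(toy)
    return split, fit_standardizer(split.train)


@pytest.fixture()
def small_panel() -> PanelSeries:
    """Hand-built 5-visit panel with two indices for arithmetic fixtures."""
    dates = pd.to_datetime(["2020-01-01", "2020-01-03", "2020-01-04", "2020-01-07", "2020-01-09"])
    values = np.array(
        [
            [2.0, 10.0],
            [np.nan, 10.0],
            [4.0, np.nan],
            [5.0, 10.0],
            [6.0, 12.0],
        ]
    )
    return PanelSeries(dates=dates, values=values, index_names=("A", "B"))


def make_series(values: np.ndarray):
    """Wrap a plain array as a RegularSeries on a 0.5-day grid."""
    from panelcast import RegularSeries

    values = np.asarray(values, dtype=float)
    names = tuple(f"I{j}" for j in range(values.shape[1]))
    return RegularSeries(t0=pd.Timestamp("2020-01-01"), step=0.5, values=values, index_names=names)
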