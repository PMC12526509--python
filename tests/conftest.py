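import numpy as np
import pandas as pd
import pytest

import smctex as st


@pytest.fixture(scope="session")
def small_dataset():
    """A 24-plot synthetic trial, cheap enough for pipeline tests."""
    cfg = st.SyntheticConfig(n_plots=24, plot_px=32, seed=7)
    plots, smc = st.generate_dataset(cfg)
    return cfg, plots, smc


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Masked textures of the 24-plot trial."""
    _, plots, _ = small_dataset
    masked = [st.vegetation_mask(p) for p in plots]
    return st.textures_for_plots(masked)


@pytest.fixture(scope="session")
def random_position_table():
    """A plots x 48-positions table of synthetic feature values (n=96)."""
    rng = np.random.default_rng(123)
    labels = [p.label for p in st.all_positions()]
    X = rng.normal(size=(96, len(labels))) * 2 + 5  # keep away from zero
    table = pd.DataFrame(X, columns=labels,
                         index=[f"P{i:03d}" for i in range(96)])
    table.index.name = "plot_id"
    return table


def make_plot(pixels, mask=None, plot_id="t"):
    return st.ReflectancePlot(plot_id, pixels, mask=mask)
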