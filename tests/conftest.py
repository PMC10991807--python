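import numpy as np
import pandas as pd
import pytest

from panelnet.data_io import default_meta


@pytest.fixture(scope="session")
def meta():
    return default_meta()


def make_wave_frame(ids, rng, meta, base=None):
    """Random Likert wave table in the questionnaire input schema."""
    vals = rng.integers(1, 6, size=(len(ids), len(meta.item_labels))) if base is None else base
    df = pd.DataFrame(vals, columns=list(meta.item_labels))
    df.insert(0, "id", ids)
    return df


@pytest.fixture
def wave_csvs(tmp_path, meta):
    """Two small wave CSVs sharing 3 of 5 participant IDs."""
    rng = np.random.default_rng(42)
    w1 = make_wave_frame(["a", "b", "c", "d", "e"], rng, meta)
    w2 = make_wave_frame(["c", "d", "e", "f", "g"], rng, meta)
    p1, p2 = tmp_path / "w1.csv", tmp_path / "w2.csv"
    w1.to_csv(p1, index=False)
    w2.to_csv(p2, index=False)
    return p1, p2


@pytest.fixture(scope="session")
def small_study():
    """One simulated study reused across tests (n=500, fixed seed)."""
    from panelnet.synthetic_data import simulate_study

    return simulate_study(n=500, seed=123)
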