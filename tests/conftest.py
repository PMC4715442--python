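import numpy as np
import pandas as pd
import pytest

from cesdexp import ModelParams, default_scenario, generate_survey
from cesdexp.scoring import ALL_ITEMS, item_columns


@pytest.fixture(scope="session")
def small_survey() -> pd.DataFrame:
    """A small default-scenario survey shared across pipeline tests."""
    return generate_survey(default_scenario(n_per_bin=400, seed=11))


@pytest.fixture()
def exact_counts():
    """Counts exactly proportional to model probabilities (P=0.2, r=0.5)."""
    from cesdexp import CategoryCounts

    return CategoryCounts(650, 200, 100, 50)


def make_row(values) -> dict[int, int]:
    """Build a raw-response row from a 20-vector or a constant."""
    if isinstance(values, int):
        values = [values] * 20
    return dict(zip(ALL_ITEMS, values))


@pytest.fixture()
def make_matrix():
    """Factory for tiny response matrices from raw row dicts."""

    def _make(rows, ages=None, sexes=None):
        n = len(rows)
        data = {
            "respondent_id": np.arange(n),
            "age": ages if ages is not None else [30] * n,
            "sex": sexes if sexes is not None else ["F"] * n,
        }
        for i, col in zip(ALL_ITEMS, item_columns()):
            data[col] = [row.get(i, np.nan) for row in rows]
        return pd.DataFrame(data)

    return _make


def random_valid_params(rng: np.random.Generator) -> ModelParams:
    """Uniformly draw a valid (P, r) pair: r first, then P below its bound."""
    r = rng.uniform(0.05, 2.0)
    bound = 1.0 / (r * r + r + 1.0)
    P = rng.uniform(1e-6, bound)
    return ModelParams(P, r)
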