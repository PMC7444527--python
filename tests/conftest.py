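import numpy as np
import pandas as pd
import pytest

from labelbias import SimConfig, fixture_small, simulate_raters, simulate_survey


@pytest.fixture(scope="session")
def fixture_df() -> pd.DataFrame:
    return fixture_small()


@pytest.fixture(scope="session")
def small_survey():
    """A 20-volunteer-per-variant survey with default generative parameters."""
    config = SimConfig(n_volunteers_per_variant=20, seed=42)
    truth = simulate_raters(config)
    return config, truth, simulate_survey(truth)


def make_records(same_ratings, diff_ratings, volunteer="v1") -> pd.DataFrame:
    """Minimal valid control-variant response frame from two rating lists."""
    rows = []
    for i, r in enumerate(same_ratings):
        rows.append((volunteer, "control", "none", f"s{i}", "same", "none", r, False))
    for i, r in enumerate(diff_ratings):
        rows.append((volunteer, "control", "none", f"d{i}", "different", "none", r, False))
    return pd.DataFrame(
        rows,
        columns=["volunteer_id", "variant", "version", "item_id", "truth",
                 "prior_label", "rating", "is_catch"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
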