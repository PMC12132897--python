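import numpy as np
import pandas as pd
import pytest

from cacscreen import (
    GeneratorConfig,
    generate_cohort,
    score_cohort,
    train_cac_model,
)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One default-sized synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n=4564, seed=123))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort) -> pd.DataFrame:
    """Default cohort with PCE categories and honest self-report scores."""
    scored = score_cohort(default_cohort)
    model = train_cac_model(scored, threshold=100.0, seed=7)
    scored = scored.copy()
    scored["selfreport_probability"] = model.cv_probability
    return scored


def make_toy_cohort(probabilities, cacs, **extra) -> pd.DataFrame:
    """Minimal scored cohort for strategy unit tests."""
    n = len(probabilities)
    df = pd.DataFrame(
        {
            "id": [f"T{i:03d}" for i in range(n)],
            "selfreport_probability": np.asarray(probabilities, dtype=float),
            "cacs": np.asarray(cacs, dtype=float),
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df
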