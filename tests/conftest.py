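import numpy as np
import pytest
from hypothesis import settings

from breakoff import CohortConfig, SurveyTemplate, Item, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def tiny_template() -> SurveyTemplate:
    """10 items in 3 contiguous sections with mixed sensitivity."""
    layout = [
        ("s0", [0, 0, 1, 1]),
        ("s1", [0, 2]),
        ("s2", [0, 1, 0, 0]),
    ]
    items, j = [], 0
    for sec, codes in layout:
        for c in codes:
            items.append(Item(index=j, item_id=f"q{j:03d}", section_id=sec, sensitivity=c))
            j += 1
    return SurveyTemplate(tuple(items))


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-respondent default-condition cohort with ground truth."""
    cfg = CohortConfig(n_respondents=400, seed=11)
    matrix, covariates, truth = simulate_cohort(cfg)
    return cfg, matrix, covariates, truth


def survey_rows(rng: np.random.Generator, n_rows: int, max_len: int = 20):
    """Random rows from the survey missingness process (quit + MAR skips)."""
    for _ in range(n_rows):
        n = int(rng.integers(1, max_len + 1))
        t = int(rng.integers(0, n + 1))
        skip = rng.uniform(0, 0.3)
        row = (np.arange(n) >= t).astype(np.int8)
        row[(np.arange(n) < t) & (rng.random(n) < skip)] = 1
        yield row
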