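import numpy as np
import pandas as pd
import pytest

from mateperm.trait_model_io import CohortTable, TraitRegistry, TraitSpec


@pytest.fixture
def single_trait_registry():
    return TraitRegistry([TraitSpec("extraversion", "personality", 2, 14)])


@pytest.fixture
def worked_example_cohort(single_trait_registry):
    """Two respondents: partners scoring (11, 13) and (5, 10, 7, 14)."""
    df = pd.DataFrame({
        "respondent_id": ["A", "A", "B", "B", "B", "B"],
        "partner_ordinal": [1, 2, 1, 2, 3, 4],
        "is_father": [0, 1, 0, 0, 0, 1],
        "extraversion": [11, 13, 5, 10, 7, 14],
    })
    return CohortTable(df, single_trait_registry)


@pytest.fixture
def three_pair_cohort(single_trait_registry):
    """3 respondents x 2 partners with values (2,2), (5,5), (8,8)."""
    df = pd.DataFrame({
        "respondent_id": ["A", "A", "B", "B", "C", "C"],
        "partner_ordinal": [1, 2] * 3,
        "is_father": [0, 1] * 3,
        "extraversion": [2.0, 2.0, 5.0, 5.0, 8.0, 8.0],
    })
    return CohortTable(df, single_trait_registry)


def random_cohort(n_respondents: int, seed: int, trait: str = "extraversion",
                  lo: float = 2, hi: float = 14, max_partners: int = 5) -> CohortTable:
    """Small unstructured cohort for brute-force comparisons."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_respondents):
        p = int(rng.integers(2, max_partners + 1))
        for j in range(p):
            rows.append({
                "respondent_id": f"R{i}", "partner_ordinal": j + 1,
                "is_father": int(j == p - 1),
                trait: float(rng.integers(lo, hi + 1)),
            })
    reg = TraitRegistry([TraitSpec(trait, "personality", lo, hi)])
    return CohortTable(pd.DataFrame(rows), reg)
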