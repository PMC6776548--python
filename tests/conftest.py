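import numpy as np
import pandas as pd
import pytest

from pharmseg import Cohort, ResponseTable, standardize


def make_table(drug_id: str, ids, log_ic50, auc) -> ResponseTable:
    return ResponseTable(
        drug_id=drug_id,
        data=pd.DataFrame(
            {"log_ic50": np.asarray(log_ic50, float), "auc": np.asarray(auc, float)},
            index=pd.Index(list(ids), name="cell_line_id"),
        ),
    )


def random_cohort(n: int, seed: int, standardized: bool = True) -> Cohort:
    """Unstructured standardized cohort used for numerical oracles."""
    rng = np.random.default_rng(seed)
    drp = np.column_stack(
        [
            rng.normal(0.5, 1.5, n),
            rng.uniform(0.05, 0.95, n),
            rng.normal(0.5, 1.5, n),
            rng.uniform(0.05, 0.95, n),
        ]
    )
    cohort = Cohort(
        cell_line_ids=[f"CL{i:04d}" for i in range(n)],
        drp=drp,
        drug_a_id="A",
        drug_b_id="B",
    )
    return standardize(cohort) if standardized else cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    return random_cohort(12, seed=3)
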