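import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sepsisprog.preprocess import ExpressionMatrix, SampleTable
from sepsisprog.signatures import GeneSignature, builtin_signatures
from sepsisprog.synthdata import SimConfig, simulate_multicohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("sepsisprog").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def four_signatures():
    return builtin_signatures()


@pytest.fixture()
def toy_signature():
    return GeneSignature("toy", up={"A", "B"}, down={"C"})


@pytest.fixture()
def toy_matrix():
    """3 genes x 2 samples, log2 scale: A=3, B=5, C=2 in both samples."""
    df = pd.DataFrame({"s1": [3.0, 5.0, 2.0], "s2": [3.0, 5.0, 2.0]},
                      index=["A", "B", "C"])
    return ExpressionMatrix(df, scale="log2")


@pytest.fixture(scope="session")
def sim_cohorts():
    """Five simulated cohorts, default study-shaped configuration."""
    return simulate_multicohort(SimConfig(seed=42))


def make_sample_table(sample_ids, mortality, cohort="C1", severity=None,
                      time_h=None):
    n = len(sample_ids)
    return SampleTable(pd.DataFrame({
        "sample_id": sample_ids,
        "cohort_id": cohort,
        "mortality_30d": mortality,
        "severity_value": severity if severity is not None else [np.nan] * n,
        "time_from_admission_h": time_h if time_h is not None else [0.0] * n,
    }))
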