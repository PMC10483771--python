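import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from lgiscore.endpoints import add_endpoint_columns
from lgiscore.lgi import LGIScorer
from lgiscore.synth import CohortConfig, generate_cohort, records_to_frame


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (n=876) as a list of records."""
    return generate_cohort(CohortConfig(n_patients=876, seed=42))


@pytest.fixture(scope="session")
def analysis_frame(default_cohort):
    """Default cohort scored and endpoint-annotated: the analysis-ready frame."""
    df = records_to_frame(default_cohort)
    scored = LGIScorer(add_quartiles=True).fit(df).transform(df)
    return add_endpoint_columns(scored)


def simulate_quartile_cohort(
    n: int,
    log_ors=(0.0, 0.0, 0.0),
    intercept: float = -1.0,
    seed: int = 0,
    outcome: str = "poor_90d",
) -> pd.DataFrame:
    """Minimal quartile-exposure cohort with known log-odds per quartile.

    Serves as the ground-truth bench for parameter-recovery and null
    checks: quartile drawn uniformly, outcome Bernoulli with logit
    intercept + log_ors[q-2] for quartiles 2..4 (quartile 1 is reference).
    """
    rng = np.random.default_rng(seed)
    q = rng.integers(1, 5, n)
    beta = np.array([0.0, *log_ors])
    p = expit(intercept + beta[q - 1])
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame({"lgi_quartile": q, outcome: y})
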