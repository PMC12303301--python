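import warnings

import numpy as np
import pandas as pd
import pytest

from hybridcox.catalog import Variable, VariableCatalog
from hybridcox.cohort import CohortTable
from hybridcox.simulate import (
    CovariateSpec,
    SimParams,
    default_params,
    simulate,
)

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_cohort_large():
    """One large draw from the default study conditions (marginal checks)."""
    params = default_params(n=100_000)
    cohort, truth = simulate(params, seed=202)
    return params, cohort, truth


@pytest.fixture(scope="session")
def default_cohort_small():
    """A small draw from the default study conditions (plumbing checks)."""
    params = default_params(n=4_000)
    cohort, truth = simulate(params, seed=101)
    return params, cohort, truth


def no_signal_params(n: int, n_covariates: int = 5) -> SimParams:
    """Covariates that carry no effect on the hazard at all."""
    covs = [
        CovariateSpec(f"x{i}", "numeric", "lab", mean=0.0, sd=1.0)
        for i in range(n_covariates)
    ]
    return SimParams(n=n, covariates=covs, beta={}, baseline_scale=30.0,
                     dropout_rate=0.05, horizon_years=15.0)


@pytest.fixture(scope="session")
def no_signal_cohort():
    params = no_signal_params(5_000)
    cohort, truth = simulate(params, seed=77)
    return params, cohort, truth


def toy_cohort_table(times, events, **features) -> CohortTable:
    """Hand-built wide cohort with an inferred catalog."""
    variables = []
    for name, values in features.items():
        vals = np.asarray(values, float)
        kind = "binary" if set(np.unique(vals[~np.isnan(vals)])) <= {0.0, 1.0} else "numeric"
        variables.append(Variable(name, kind, "lab" if kind == "numeric" else "disease_history"))
    df = pd.DataFrame({"subject_id": np.arange(len(times)),
                       "followup_years": np.asarray(times, float),
                       "event": np.asarray(events, int), **features})
    return CohortTable(df, VariableCatalog(variables))
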