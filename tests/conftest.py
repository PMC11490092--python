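import numpy as np
import pytest

from psarank import markov_case_study as mcs
from psarank.psa_core import PSAResult, StrategyOutcomes


def make_psa(inb_values, draws=None, param_names=None, k=1.0, population=1.0):
    """PSAResult whose intervention QALY gain equals ``inb_values`` (zero costs)."""
    inb_values = np.asarray(inb_values, dtype=float)
    n = inb_values.size
    if draws is None:
        draws = inb_values[:, None]
        param_names = param_names or ("x",)
    draws = np.asarray(draws, dtype=float)
    if param_names is None:
        param_names = tuple(f"p{j}" for j in range(draws.shape[1]))
    zero = np.zeros(n)
    return PSAResult(
        draws=draws,
        param_names=tuple(param_names),
        outcomes=(StrategyOutcomes("A", zero, zero),
                  StrategyOutcomes("B", inb_values, zero)),
        k=k,
        incident_population=population,
    )


def quiet_markov_values(**overrides):
    """All-zero model parameter values (no transitions, no costs, no AEs)."""
    values = {key: 0.0 for key in mcs.default_config().values}
    values["utility_well"] = 1.0
    values["utility_local_recurrence"] = 1.0
    values.update(overrides)
    return values


def quiet_markov_config(value_overrides=None, **kwargs):
    values = quiet_markov_values(**(value_overrides or {}))
    defaults = dict(start_age=60.0, horizon=10, cycle_length=1.0,
                    discount_rate_qalys=0.0, discount_rate_costs=0.0,
                    k=13_000.0, incident_population=1.0)
    defaults.update(kwargs)
    return mcs.MarkovConfig(values=values, ae_alpha=mcs.default_config().ae_alpha,
                            **defaults)


@pytest.fixture(scope="session")
def case_study_psa():
    """One shared medium-size PSA from the bundled case-study model."""
    config = mcs.default_config()
    specs = mcs.default_parameter_specs(config)
    return mcs.sample_psa(config, specs, n_draws=4000, seed=20240)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
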