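import numpy as np
import pandas as pd
import pytest

from plymod import (
    PopulationConfig,
    generate_base_population,
    generate_donor_pool,
    match_economic_data,
)


def recovery_se(cases, donors, sd, n_sims):
    """Analytic Monte-Carlo SE of the recovery point estimate around the
    design truth: case sampling + finite donor pool (shared cell means) +
    assignment noise averaged over replicates."""
    w = cases["weight"].to_numpy(float)
    a = w / w.sum()
    keys = list(zip(cases["sex"], cases["age_group"], cases["education"]))
    dkeys = pd.Series(list(zip(donors["sex"], donors["age_group"], donors["education"])))
    dw = donors["weight"].to_numpy(float)
    pool_term = 0.0
    for cell in set(keys):
        a_c = sum(a[i] for i, k in enumerate(keys) if k == cell)
        mask = (dkeys == cell).to_numpy()
        if not mask.any():
            continue
        p = dw[mask] / dw[mask].sum()
        pool_term += a_c**2 * (p**2).sum()
    out = {}
    for outcome, (sc, sdn) in {
        "income": (sd["case_income"], sd["donor_income"]),
        "welfare": (sd["case_welfare"], 0.0),
        "tax": (0.0, sd["donor_tax"]),
    }.items():
        var = sc**2 * (a**2).sum() + sdn**2 * pool_term + sdn**2 * (a**2).sum() / n_sims
        out[outcome] = float(np.sqrt(var))
    return out


@pytest.fixture(scope="session")
def pop_config():
    return PopulationConfig(n_records=4000, n_donors=4000)


@pytest.fixture(scope="session")
def base(pop_config):
    return generate_base_population(pop_config, seed=11)


@pytest.fixture(scope="session")
def donors(pop_config):
    return generate_donor_pool(pop_config, seed=12)


@pytest.fixture(scope="session")
def imputed(base, donors):
    return match_economic_data(base, donors, seed=13)
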