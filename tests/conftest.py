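import numpy as np
import pandas as pd
import pytest

from uaiscore import SimulationConfig, simulate_trial


@pytest.fixture(scope="session")
def small_trial():
    """A 200-patient, 120-gene trial with strong planted effects."""
    cfg = SimulationConfig(
        n_patients=200,
        n_genes_total=120,
        n_prognostic=8,
        n_predictive_protective=8,
        n_predictive_risk=8,
        low_variation_fraction=0.3,
        seed=11,
    )
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def default_trial():
    """The default study conditions (728 patients, 2,000 genes)."""
    return simulate_trial(SimulationConfig(seed=5))


@pytest.fixture
def toy_surv():
    """Six samples with a hand-computable Kaplan-Meier table.

    Times 1,2+,3,4,4,5+ (''+'' censored): product-limit survival
    S(1)=5/6, S(3)=5/6*3/4=0.625, S(4)=0.625*1/3~=0.2083, flat after.
    """
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 4.0, 5.0],
            "event": [1, 0, 1, 1, 1, 0],
        }
    )
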