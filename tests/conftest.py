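import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import neckteeth as nt

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_records():
    """One default-configuration simulation of the main experiment."""
    return nt.simulate_main_experiment(nt.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_effectivity():
    return nt.simulate_effectivity_experiment(nt.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def tiny_defense_frame():
    """Small single-factor defense dataset for fast sampler tests."""
    import pandas as pd

    rng = np.random.default_rng(42)
    rows = []
    for m in range(6):
        kair = m >= 3
        eta_n = -1.0 + 2.0 * kair + rng.normal(0, 0.3)
        eta_p = 1.5 * kair + rng.normal(0, 0.3)
        for _ in range(10):
            k = rng.binomial(5, 1 / (1 + np.exp(-eta_n)))
            pa = 1 / (1 + np.exp(-(0.5 - eta_p)))
            pb = 1 / (1 + np.exp(-(2.0 - eta_p))) - pa
            u = rng.random()
            ped = "A" if u < pa else ("B" if u < pa + pb else "C")
            rows.append(
                {
                    "kairomone": kair,
                    "mother_uid": f"m{m}",
                    "neckteeth": int(k),
                    "pedestal": ped,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def fitted_instar2(default_records):
    """A reduced-preset fit of the instar-2 defense model, shared by the
    summary/evidence/diagnostics tests."""
    model = nt.DefenseTraitModel.from_records(default_records, instar=2)
    return model.fit(dataclasses.replace(nt.PRESETS["ci_fast"], seed=7))
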