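import numpy as np
import pandas as pd
import pytest

from adproteo import IntensityMatrix, SampleTable, SimulationConfig, simulate_study


def make_sample_table(n_ad=3, n_control=3, regions=("HP",), reps=1, seed=0):
    """Small hand-buildable sample table for unit tests."""
    rng = np.random.default_rng(seed)
    rows = []
    brains = [f"AD{i:02d}" for i in range(1, n_ad + 1)] + [f"CT{i:02d}" for i in range(1, n_control + 1)]
    groups = ["AD"] * n_ad + ["control"] * n_control
    for b, g in zip(brains, groups):
        sex = rng.choice(["M", "F"])
        age = float(rng.uniform(60, 90))
        pmi = float(rng.uniform(2, 10))
        for region in regions:
            for r in range(1, reps + 1):
                sid = f"{b}_{region}" + (f"_r{r}" if reps > 1 else "")
                rows.append(
                    dict(sample_id=sid, brain_id=b, region=region, group=g,
                         sex=sex, age=age, pmi=pmi, tech_rep=r)
                )
    return SampleTable(pd.DataFrame(rows))


def make_matrix(values, sample_ids, feature_ids=None, layer="protein", scale="raw"):
    values = np.asarray(values, float)
    feature_ids = feature_ids or [f"F{i}" for i in range(values.shape[0])]
    return IntensityMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids), layer, scale)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_proteins=300, n_phospho=200, n_acetyl_sites=60, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)
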