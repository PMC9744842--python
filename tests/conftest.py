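import numpy as np
import pandas as pd
import pytest

from sexallometry import SyntheticTraitSpec


@pytest.fixture
def base_spec():
    """A realistic null (NS) trait: equal sexes, modest noise, batch effects."""
    def make(**overrides):
        defaults = dict(
            trait_name="trait_x",
            intercept_f=1.0,
            intercept_m=1.0,
            slope_f=0.3,
            slope_m=0.3,
            sd_f=0.12,
            sd_m=0.12,
            n_f=500,
            n_m=500,
            n_batches=10,
            var_batch_intercept=0.004,
            seed=42,
        )
        defaults.update(overrides)
        return SyntheticTraitSpec(**defaults)

    return make


@pytest.fixture
def noise_free_spec(base_spec):
    """Exact two-line data: no noise, no random effects."""
    def make(**overrides):
        defaults = dict(
            sd_f=0.0, sd_m=0.0, n_batches=1, var_batch_intercept=0.0,
            n_f=100, n_m=100, slope_f=0.5, slope_m=0.5,
        )
        defaults.update(overrides)
        return base_spec(**defaults)

    return make


@pytest.fixture
def measurement_csv(tmp_path):
    """Write a small measurement table to CSV and return its path."""
    def write(df: pd.DataFrame, name: str = "data.csv"):
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path

    return write


@pytest.fixture
def raw_rows():
    """Hand-built 10-row single-trait table exercising each cleaning rule."""
    def make(n=10, **overrides):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "animal_id": [f"a{i}" for i in range(n)],
                "sex": (["female", "male"] * n)[:n],
                "weight": rng.uniform(18, 30, n).round(2),
                "weight_age_days": 70,
                "trait_name": "lean_mass",
                "trait_value": rng.uniform(5, 9, n).round(3),
                "batch": (["b1", "b2"] * n)[:n],
                "metadata_group": "mg1",
                "substrain": "C57BL/6N",
                "centre": "ctr",
                "procedure_name": "DEXA",
                "functional_group": "morphology",
            }
        )
        for col, values in overrides.items():
            df[col] = values
        return df

    return make
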