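import numpy as np
import pandas as pd
import pytest

from lesionmap import SimConfig, generate_cohort


def tiny_config(**overrides) -> SimConfig:
    """Small, fast cohort: 16^3 grid, 4 mm voxels, 10 regions."""
    defaults = dict(
        n_patients=6,
        grid_shape=(16, 16, 16),
        voxel_size=(4.0, 4.0, 4.0),
        n_gm_regions_per_hemi=3,
        n_wm_regions_per_hemi=2,
        lesion_volume_log_mean=np.log(5.0),
        lesion_volume_log_sd=0.5,
        seed=123,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_config())


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(tiny_config(adc_lesion_sd=0.0, adc_normal_sd=0.0, seed=7))


def random_feature_table(
    n: int,
    n_regions: int,
    seed: int,
    effect_betas: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Feature-level synthetic table: skewed pct columns, covariates, and a
    logistic outcome over any supplied per-region betas."""
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(64, 12, n), 18, 80)
    nihss = rng.integers(10, 26, n).astype(float)
    volume = rng.lognormal(np.log(20), 1.0, n)
    # region percentages: mostly zero, occasionally substantial
    pct = rng.exponential(5.0, (n, n_regions)) * (rng.random((n, n_regions)) < 0.4)
    pct = np.clip(pct, 0, 100)
    lp = np.zeros(n)
    if effect_betas:
        for rid, beta in effect_betas.items():
            col = pct[:, rid - 1]
            sd = col.std() or 1.0
            lp += beta * (col - col.mean()) / sd
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    # guard: both classes present
    if y.min() == y.max():
        y[0] = 1 - y[0]
    data = {
        "patient_id": [f"p{i:04d}" for i in range(n)],
        "age": age,
        "nihss": nihss,
        "mrs_binary": y,
        "volume_ml": volume,
        "hemisphere": rng.choice(["left", "right"], n),
    }
    for r in range(n_regions):
        data[f"pct_{r + 1}"] = pct[:, r]
    return pd.DataFrame(data)
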