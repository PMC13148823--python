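import numpy as np
import pytest

from mitoflux.config import GeneratorConfig, GroupConfig, study_preset

LADDER_BENIGN = {"E": 1.0, "PM": 2.5, "PMD": 6.0, "PMDG": 7.0, "PMDGS": 10.0,
                 "M": 1.5, "MD": 2.0, "MDPC": 6.0}
LADDER_TUMOR = {"E": 6.0, "PM": 15.0, "PMD": 40.0, "PMDG": 50.0, "PMDGS": 70.0,
                "M": 8.0, "MD": 10.0, "MDPC": 50.0}


def make_config(noise_sd=0.0, biological_cv=0.0, dropout=0.0, n_samples=3,
                n_omics=4, n_features=200, frac_mito=0.5, sigma=0.0, seed=0,
                **kwargs):
    """Small, fast generator config; noiseless by default."""
    groups = {
        "benign": GroupConfig(
            name="benign", n_samples=n_samples, true_jo2=dict(LADDER_BENIGN),
            coupling_fraction=0.55, residual_fraction=0.02, noise_sd=noise_sd,
            biological_cv=biological_cv, amount_mg=18.0, n_omics_samples=n_omics,
            content_scale=1.0, detection_dropout_rate=dropout,
            protein_ug_per_mg=40.0, protein_cv=0.0,
        ),
        "tumor": GroupConfig(
            name="tumor", n_samples=n_samples, true_jo2=dict(LADDER_TUMOR),
            coupling_fraction=0.80, residual_fraction=0.02, noise_sd=noise_sd,
            biological_cv=biological_cv, amount_mg=3.0, n_omics_samples=n_omics,
            content_scale=0.65, detection_dropout_rate=dropout,
            protein_ug_per_mg=100.0, protein_cv=0.0,
        ),
    }
    return GeneratorConfig(
        groups=groups, n_features=n_features, frac_mito=frac_mito,
        abundance_sigma=sigma, state_duration_s=120.0, seed=seed, **kwargs
    ).validate()


@pytest.fixture
def noiseless_config():
    return make_config()


@pytest.fixture
def preset_config():
    return study_preset(seed=7)


def ols_slope_oracle(t, y):
    """Independent textbook least-squares slope."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tm, ym = t.mean(), y.mean()
    return float(np.sum((t - tm) * (y - ym)) / np.sum((t - tm) ** 2))
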