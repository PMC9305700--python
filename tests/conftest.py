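import numpy as np
import pandas as pd
import pytest

from erpmkl.features import build_feature_table
from erpmkl.pipeline import simulate_averaged_cohort
from erpmkl.synthetic import (
    CohortConfig,
    ComponentSpec,
    default_components,
)


def make_classification_table(
    seed: int,
    n: int = 100,
    n_informative: int = 10,
    n_noise: int = 90,
    effect_size: float = 1.5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian two-class table with planted mean-shift features."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [-1] * (n - n // 2))
    X = rng.normal(size=(n, n_informative + n_noise))
    X[:, :n_informative] += effect_size * (y[:, None] == 1)
    cols = [f"inf{i}" for i in range(n_informative)] + [
        f"noise{i}" for i in range(n_noise)
    ]
    return pd.DataFrame(X, columns=cols), y


def make_gaussian_toy(seed: int, n: int = 40, sep: float = 2.0):
    """Seeded two-class 2-D Gaussian blobs with ±1 labels."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [
            rng.normal(loc=(-sep / 2, 0), size=(half, 2)),
            rng.normal(loc=(+sep / 2, 0), size=(n - half, 2)),
        ]
    )
    y = np.array([-1.0] * half + [1.0] * (n - half))
    cols = ["f0", "f1"]
    return pd.DataFrame(X, columns=cols), y


@pytest.fixture(scope="session")
def tiny_cohort_config() -> CohortConfig:
    """Small, low-noise two-group cohort used across tests."""
    hc = default_components(amplitude_sd_uV=0.5, latency_sd_ms=5.0)
    sz = default_components(
        amplitude_sd_uV=0.5,
        latency_sd_ms=5.0,
        p300_amplitude_scale=0.5,
        p300_latency_shift_ms=30.0,
    )
    return CohortConfig(
        n_per_group=6,
        components_by_group={"HC": hc, "SZ": sz},
        noise_sd_uV=5.0,
        n_trials_per_class=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    return simulate_averaged_cohort(tiny_cohort_config)


@pytest.fixture(scope="session")
def tiny_feature_table(tiny_cohort):
    return build_feature_table(tiny_cohort)


@pytest.fixture()
def single_bump() -> list[ComponentSpec]:
    return [
        ComponentSpec(
            label="P300",
            polarity=1,
            mean_latency_ms=300.0,
            latency_sd_ms=0.0,
            mean_amplitude_uV=10.0,
            amplitude_sd_uV=0.0,
            width_ms=40.0,
        )
    ]
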