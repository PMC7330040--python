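import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tmenet import SyntheticCohortConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """A scaled-down cohort for fast unit tests: 3 planted modules."""
    base = dict(
        n_genes=300,
        module_sizes=(60, 50, 40),
        n_background_genes=150,
        samples_per_group={"AN": 4, "CNM": 8, "CWM": 10, "CLM": 10},
        celltype_module_map={"fibroblast": (0,), "endothelial": (1,),
                             "leukocyte": (2,)},
        seed=seed,
    )
    base.update(overrides)
    return SyntheticCohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def factor_module_expression(
    rng: np.random.Generator,
    loadings: np.ndarray,
    n_samples: int,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """One-factor expression block with known loadings; returns (expr, factor)."""
    f = rng.standard_normal(n_samples)
    noise = rng.normal(0.0, noise_sd, size=(len(loadings), n_samples))
    X = loadings[:, None] * f[None, :] + noise
    genes = [f"g{i:03d}" for i in range(len(loadings))]
    return pd.DataFrame(X, index=genes,
                        columns=[f"s{j:03d}" for j in range(n_samples)]), f
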