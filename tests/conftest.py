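import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cordmediate.synthetic_cohort import SimulationConfig, generate_cohort
from cordmediate.transcriptome import FLAG_NAMES, ExpressionMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=20240101)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


def make_matrix(values: np.ndarray, samples=None, genes=None, panel="embryonal_growth") -> ExpressionMatrix:
    """Build a fully reliable expression matrix from a plain array."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if samples is None:
        samples = [f"s{i + 1:03d}" for i in range(n_samp)]
    if genes is None:
        genes = [f"G{i + 1:05d}" for i in range(n_feat)]
    index = pd.Index([f"P{i + 1:05d}" for i in range(n_feat)])
    vals = pd.DataFrame(values, index=index, columns=samples)
    flags = {name: pd.DataFrame(True, index=index, columns=samples) for name in FLAG_NAMES}
    ann = pd.DataFrame(
        {
            "gene_symbol": genes,
            "transcript": [f"T{i + 1:05d}" for i in range(n_feat)],
            "panels": panel,
        },
        index=index,
    )
    return ExpressionMatrix(values=vals, flags=flags, annotation=ann)
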