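import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from stemtrace import oclr, synthetic

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg() -> synthetic.SimulationConfig:
    """A scaled-down study configuration for fast unit tests."""
    return synthetic.SimulationConfig(
        n_genes=300,
        n_signature_genes=30,
        n_prolif_genes=20,
        n_senesc_genes=20,
        n_stem_train=20,
        n_diff_train=40,
        n_subjects=120,
        tissues=(
            synthetic.TissueSpec("alpha", n_samples=80),
            synthetic.TissueSpec("beta", n_samples=80, beta_age=0.02, has_sex=False),
            synthetic.TissueSpec("gamma", n_samples=80, beta_age=0.0, shared_factor_loading=0.0),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_signature(small_cfg) -> oclr.StemnessSignature:
    X, labels = synthetic.simulate_training_cohort(small_cfg)
    return oclr.train_signature(X, labels)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return synthetic.simulate_cohort(small_cfg)


@pytest.fixture()
def tiny_expression() -> pd.DataFrame:
    """4 genes x 3 samples with distinct, hand-checkable values."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0], [2.0, 1.0, 5.0]],
        index=pd.Index(["A", "B", "C", "D"], name="gene_id"),
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240404)
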