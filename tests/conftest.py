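import numpy as np
import pytest

import atnfuse as af


@pytest.fixture(scope="session")
def small_dataset():
    """Small tri-modal cohort with batch effects and known truth."""
    cfg = af.SimulationConfig(n_subjects=180, n_modalities=3,
                              features_per_modality=250, k_true=4,
                              snr=5.0, n_sites=9, n_scanners=2, seed=7)
    return af.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return af.grouped_split(small_dataset.site, seed=7)


@pytest.fixture(scope="session")
def small_fit(small_dataset, small_split):
    """Fitted fusion model on the small cohort (shared across tests)."""
    hp = af.FusionHyperparams(max_epochs=60, patience=15, seed=7)
    return af.SupervisedFusion(small_dataset, small_split, 4, hp).fit()


def make_single_modality_dataset(X, y=None, site=None, seed=0):
    """Wrap a raw matrix as a one-modality dataset with a minimal phenotype."""
    import pandas as pd
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    if y is None:
        y = np.zeros(n)
    if site is None:
        site = np.array([f"s{i % 5}" for i in range(n)])
    pheno = pd.DataFrame({
        "target": y, "site": site, "scanner": np.array(["sc0"] * n),
        "diagnosis": np.array(["CN"] * n), "carrier": np.zeros(n, dtype=int),
        "age": 70 + rng.standard_normal(n), "sex": np.array(["F"] * n),
        "csf_abeta42": np.full(n, np.nan), "csf_ptau181": np.full(n, np.nan),
        "csf_offset_days": np.full(n, np.nan),
    }, index=pd.Index([f"sub{i:04d}" for i in range(n)], name="subject_id"))
    return af.MultimodalDataset(X=[X], pheno=pheno, modalities=["GM"])


def all_train_split(n):
    """SplitAssignment placing every subject in the training split."""
    return af.SplitAssignment(split=np.array(["train"] * n), site_to_split={},
                              fractions=(1.0, 0.0, 0.0), seed=0)
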