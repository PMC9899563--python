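import dataclasses

import numpy as np
import pytest

import prognet as pn


@pytest.fixture(scope="session")
def tiny_cohort():
    """Complete (no missingness) small multi-study cohort with signal."""
    cfg = dataclasses.replace(
        pn.default_cohort_config(seed=42), missing_rate=0.0,
        n_per_study=[150, 150, 150, 90, 90, 90],
    )
    return pn.generate_multi_study(cfg)


@pytest.fixture(scope="session")
def tiny_train(tiny_cohort):
    return [t for t in tiny_cohort if t.role == "train"]


@pytest.fixture
def fast_options():
    """Pipeline options sized for unit tests: fixed network penalties and a
    small elastic-net grid."""
    return pn.PipelineOptions(
        fgl=pn.FglOptions(lambda1_grid=[8.0], lambda2_grid=[4.0], cv_folds=3),
        enr=pn.EnrOptions(alpha_grid=[0.5, 1.0], n_lambda=10, folds=4),
    )


@pytest.fixture(scope="session")
def toy_network():
    """3-node toy network: w12 = 0.5, w13 = -0.2, w23 = 0.3."""
    W = np.array([[0.0, 0.5, -0.2], [0.5, 0.0, 0.3], [-0.2, 0.3, 0.0]])
    return W


def random_correlation(p: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((p, p + 4))
    C = A @ A.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)
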