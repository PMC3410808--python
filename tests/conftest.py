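import numpy as np
import pytest

from survperf import SimConfig, SurvivalDataset, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_censored_instance(rng, n, censor_frac=0.3, tie_times=False):
    """Small random survival instance with scores, for oracle comparisons."""
    if tie_times:
        times = rng.integers(1, max(3, n // 2), size=n).astype(float)
    else:
        times = rng.exponential(5.0, size=n) + 1e-3
    events = (rng.uniform(size=n) > censor_frac).astype(int)
    scores = rng.normal(size=n)
    return times, events, scores


@pytest.fixture
def toy_dataset():
    """8 subjects, 3 genes, 2 clinical covariates, mixed censoring."""
    rng = np.random.default_rng(7)
    n = 8
    return SurvivalDataset(
        ids=[f"s{i}" for i in range(n)],
        time=np.array([2.0, 3.5, 1.2, 6.0, 4.4, 7.1, 0.9, 5.5]),
        event=np.array([1, 0, 1, 1, 0, 1, 1, 0]),
        clinical=rng.normal(size=(n, 2)),
        clinical_names=["age", "grade"],
        expression=rng.normal(size=(n, 3)),
        gene_names=["g1", "g2", "g3"],
    )


@pytest.fixture
def small_cohort():
    """Moderate synthetic cohort with real signal, shared across tests."""
    cfg = SimConfig(n_train=60, n_test=30, n_genes=50, n_signal_genes=5,
                    beta_gene=0.5, gene_block_rho=0.4, beta_clinical=0.5,
                    censoring_rate_target=0.3, seed=11)
    return generate(cfg)
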