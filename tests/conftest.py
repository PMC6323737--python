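import numpy as np
import pytest

from dnbpipe import TimeCourseDataset


def make_dataset(values, times, reps, gene_prefix="g"):
    """Build a TimeCourseDataset from a raw matrix and per-sample labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    return TimeCourseDataset(
        gene_ids=tuple(f"{gene_prefix}{i}" for i in range(n_genes)),
        values=values,
        sample_ids=tuple(f"s{j}" for j in range(n_samples)),
        sample_time=np.asarray(times, dtype=float),
        sample_replicate=np.asarray(reps, dtype=int),
    )


@pytest.fixture
def small_dataset():
    """3 genes x 6 samples, 2 time points x 3 replicates."""
    rng = np.random.default_rng(0)
    return make_dataset(
        rng.normal(size=(3, 6)),
        times=[0, 0, 0, 1, 1, 1],
        reps=[1, 2, 3, 1, 2, 3],
    )


def grid_dataset(n_genes, n_timepoints, n_replicates, seed=0, scale=1.0):
    """Stationary Gaussian dataset on an integer time grid."""
    rng = np.random.default_rng(seed)
    n = n_timepoints * n_replicates
    return make_dataset(
        scale * rng.normal(size=(n_genes, n)),
        times=np.repeat(np.arange(n_timepoints), n_replicates),
        reps=np.tile(np.arange(1, n_replicates + 1), n_timepoints),
    )
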