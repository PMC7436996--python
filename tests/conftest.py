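import numpy as np
import pandas as pd
import pytest

from reprospec.datasets import NON_REPRODUCTIVE, REPRODUCTIVE, CountDataset


def make_dataset(counts: np.ndarray, tissues: list[str], classes: list[str],
                 batches: list[str] | None = None,
                 lengths: np.ndarray | None = None) -> CountDataset:
    """Hand-rolled dataset from a plain array; one sample per tissue entry."""
    n_genes, n_samples = counts.shape
    genes = [f"g{i}" for i in range(n_genes)]
    cols = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "tissue": tissues,
            "class": classes,
            "batch": batches or ["b1"] * n_samples,
            "species": "human",
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return CountDataset(
        counts=pd.DataFrame(counts, index=genes, columns=cols),
        samples=meta,
        lengths=None if lengths is None else pd.Series(lengths, index=genes),
    )


def two_group_dataset(counts_a: np.ndarray, counts_b: np.ndarray) -> CountDataset:
    """Reproductive group A vs non-reproductive group B."""
    na, nb = counts_a.shape[1], counts_b.shape[1]
    return make_dataset(
        np.hstack([counts_a, counts_b]),
        tissues=["A"] * na + ["B"] * nb,
        classes=[REPRODUCTIVE] * na + [NON_REPRODUCTIVE] * nb,
    )


def null_nb_dataset(seed: int, n_genes: int = 2000, n: int = 5,
                    phi_median: float = 0.05) -> CountDataset:
    """Two groups drawn from the same NB distribution (no true DE)."""
    rng = np.random.default_rng(seed)
    mu0 = np.exp(rng.normal(np.log(80), 1.0, n_genes))
    phi = phi_median * np.exp(rng.normal(0, 0.7, n_genes))
    lib = np.exp(rng.uniform(np.log(3e5), np.log(8e5), 2 * n))
    mix = rng.gamma(1 / phi[:, None], phi[:, None], (n_genes, 2 * n))
    counts = rng.poisson(mu0[:, None] * (lib / lib.mean())[None, :] * mix)
    return two_group_dataset(counts[:, :n], counts[:, n:])


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic dataset, shared across tests."""
    from reprospec.simulate import SimConfig, generate_counts

    return generate_counts(SimConfig(n_genes=2000, rng_seed=11))
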