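import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from phenoinfo import (
    MineConfig,
    PairedDataset,
    PairedSimSpec,
    preprocess,
    sample_paired_dataset,
)
from phenoinfo.decomposition import per_gene_mi, sri_matrix, sri_pair
from phenoinfo.setsearch import greedy_search, random_sets


@pytest.fixture(scope="session")
def fast_config():
    """A budget estimator config for structural tests (not calibration)."""
    return MineConfig(
        hidden_units=64,
        n_iterations=2000,
        batch_size=128,
        n_replicates=2,
        n_jackknife=0,
        seed=7,
    )


@pytest.fixture(scope="session")
def deep_config():
    """Longer-trained budget config for fixtures with real information."""
    return MineConfig(
        hidden_units=64,
        n_iterations=4000,
        batch_size=128,
        n_replicates=2,
        n_jackknife=0,
        seed=7,
    )


# ---------------------------------------------------------------------------
# planted-structure simulations (shared across decomposition, search and
# acceptance tests so the expensive estimates are computed once)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def coupled_sim():
    """Small paired dataset with one strongly coupled gene pair (redundant).

    Genes 0 and 1 share the same latent loading (planted redundancy), gene 2
    is weakly coupled, remaining genes are independent of the trace.  High
    dispersion and baseline keep count noise low so the two identically
    loaded genes are near-deterministic readouts of the same latent (true
    redundancy, not two complementary noisy measurements).
    """
    loading = np.zeros((6, 2))
    loading[0, 0] = 0.9
    loading[1, 0] = 0.9
    loading[2, 0] = 0.35
    trace_loading = np.zeros((2, 4))
    trace_loading[0, 1] = 0.7  # latent 0 drives log-frequency
    spec = PairedSimSpec(
        n_cells=1500,
        n_genes=6,
        n_timepoints=40,
        n_latent=2,
        gene_loading=loading,
        trace_loading=trace_loading,
        baseline_log_mean=float(np.log(50.0)),
        dispersion=50.0,
        trace_noise_sd=0.05,
        seed=21,
    )
    ds, truth = sample_paired_dataset(spec)
    return preprocess(ds), truth


@pytest.fixture(scope="session")
def independent_sim():
    """Counts and traces statistically independent by construction."""
    spec = PairedSimSpec(n_cells=1000, n_genes=4, n_timepoints=30, n_latent=2, seed=5)
    ds, truth = sample_paired_dataset(spec)
    return preprocess(ds), truth


@pytest.fixture(scope="session")
def dominant_sim():
    """Four genes; gene 0 carries essentially all the trace coupling."""
    gl = np.zeros((4, 2))
    gl[0, 0] = 1.0
    gl[1, 0] = 0.25
    tl = np.zeros((2, 4))
    tl[0, 1] = 0.7
    spec = PairedSimSpec(
        n_cells=1500, n_genes=4, n_timepoints=30, n_latent=2,
        gene_loading=gl, trace_loading=tl,
        baseline_log_mean=float(np.log(50.0)), dispersion=50.0,
        trace_noise_sd=0.05, seed=33,
    )
    ds, truth = sample_paired_dataset(spec)
    return preprocess(ds), truth


@pytest.fixture(scope="session")
def xor_dataset():
    """Binary XOR phenotype: trace = x1 XOR x2 (+noise), genes uniform bits."""
    rng = np.random.default_rng(42)
    n = 4000
    bits = rng.integers(0, 2, size=(n, 3))  # third gene: pure distractor
    xor = np.logical_xor(bits[:, 0], bits[:, 1]).astype(float)
    traces = xor[:, None] + 0.05 * rng.standard_normal((n, 2))
    ds = PairedDataset.from_arrays(bits.astype(int), traces, gene_labels=["x1", "x2", "z"])
    return preprocess(ds)


@pytest.fixture(scope="session")
def xor_config():
    return MineConfig(
        hidden_units=64, n_iterations=4000, batch_size=256,
        n_replicates=2, n_jackknife=0, seed=3,
    )


@pytest.fixture(scope="session")
def xor_cache():
    """Shared single-gene MI cache so XOR tests reuse constituents."""
    return {}


@pytest.fixture(scope="session")
def xor_pair(xor_dataset, xor_config, xor_cache):
    return sri_pair(xor_dataset, "x1", "x2", xor_config, single_cache=xor_cache)


# ---------------------------------------------------------------------------
# shared expensive results
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def pg_result(coupled_sim, deep_config):
    ds, _ = coupled_sim
    return per_gene_mi(ds, deep_config)


@pytest.fixture(scope="session")
def pg_independent(independent_sim, deep_config):
    ds, _ = independent_sim
    return per_gene_mi(ds, deep_config)


@pytest.fixture(scope="session")
def sri_result(coupled_sim, deep_config, pg_result):
    ds, _ = coupled_sim
    return sri_matrix(ds, deep_config, per_gene=pg_result)


@pytest.fixture(scope="session")
def upper_trace(dominant_sim, deep_config):
    return greedy_search(dominant_sim[0], deep_config, "maximize")


@pytest.fixture(scope="session")
def lower_trace(dominant_sim, deep_config):
    return greedy_search(dominant_sim[0], deep_config, "minimize")


@pytest.fixture(scope="session")
def random_trace(dominant_sim, deep_config):
    return random_sets(dominant_sim[0], deep_config, samples_per_size=2)


@pytest.fixture(scope="session")
def discrete_greedy(deep_config):
    """Greedy search on a 5-gene binary fixture, with its exact-MI oracle.

    The phenotype is y = 2*g0 + g1 so the exact best subsets are known:
    I(g0;y)=1, I(g1;y)=1, I({g0,g1};y)=2 bits, the rest pure distractors.
    """
    from oracles import brute_force_best_subsets

    rng = np.random.default_rng(50)
    n = 3000
    bits = rng.integers(0, 2, size=(n, 5))
    y = 2.0 * bits[:, 0] + bits[:, 1]
    ds = preprocess(
        PairedDataset.from_arrays(
            bits, np.column_stack([y + 0.05 * rng.standard_normal(n)] * 2)
        )
    )
    trace = greedy_search(ds, deep_config, "maximize", max_size=3)
    oracle = brute_force_best_subsets(bits, np.round(y).astype(int))
    return ds, bits, y, trace, oracle
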