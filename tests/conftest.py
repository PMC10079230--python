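"""Shared fixtures.

The expensive simulation/inference artefacts (stationary samples, the
tree benchmark table, the cells-per-timepoint sweep and the 4-gene-chain
self-consistency loop) are session-scoped so unit tests and the
acceptance tests can share one computation.
"""

import numpy as np
import pytest

import burstnet as bn
from burstnet.io import RunConfig, loop, write_counts


@pytest.fixture(scope="session")
def saturated_gene():
    """One unregulated gene bursting at its maximal frequency.

    Benchmark kinetics: k1 = 2/h, d0 = 0.5/h, burst size 50, so the
    stationary mRNA law is Gamma(shape 4, scale 50) and counts are
    NB(4, 1/51).
    """
    return bn.make_parameters(1, beta=50.0)


@pytest.fixture(scope="session")
def stationary_sample(saturated_gene):
    """2000 stationary cells of the saturated gene: (M values, counts)."""
    M, _ = bn.stationary_states(saturated_gene, 2000, seed=0)
    counts = bn.poisson_layer(M, seed=1)
    return M[:, 0], counts[:, 0]


@pytest.fixture(scope="session")
def chain2_params():
    """Two-gene cascade: Stimulus -> 1 -> 2, strong activations."""
    theta = np.zeros((3, 3))
    theta[1, 0] = 10.0
    theta[2, 1] = 10.0
    return bn.make_parameters(2, theta=theta, beta=-5.0)


@pytest.fixture(scope="session")
def chain2_data(chain2_params):
    return bn.simulate_snapshots(chain2_params, bn.SimulationSchedule(), seed=0)


@pytest.fixture(scope="session")
def chain4_params():
    """Four-gene cascade: Stimulus -> 1 -> 2 -> 3 -> 4."""
    theta = np.zeros((5, 5))
    for k in range(4):
        theta[k + 1, k] = 10.0
    return bn.make_parameters(4, theta=theta, beta=-5.0)


@pytest.fixture(scope="session")
def chain4_loop(chain4_params, tmp_path_factory):
    """Self-consistency loop on a seeded 4-gene chain dataset."""
    root = tmp_path_factory.mktemp("loop")
    data = bn.simulate_snapshots(chain4_params, bn.SimulationSchedule(), seed=7)
    write_counts(data, root / "counts.tsv")
    config = RunConfig(
        counts_path=str(root / "counts.tsv"), d0=0.5, seed=7, out_dir=str(root / "out")
    )
    return loop(config)


@pytest.fixture(scope="session")
def tree_benchmark_table():
    """Five seeded Tree(10) datasets scored by the calibration method and
    the Pearson baseline under the reference snapshot protocol."""
    nets = []
    for k in range(5):
        net = bn.random_tree(10, seed=np.random.default_rng(k))
        nets.append(bn.BenchmarkNetwork(f"Tree10_{k}", net.params, net.truth))
    return bn.run_benchmark(
        nets, methods=("cardamom_like", "pearson"), n_replicates=1, seed=11
    )


@pytest.fixture(scope="session")
def cells_sweep_table():
    """Cells-per-timepoint design sweep (10, 50, 100) on Tree(10)."""
    return bn.design_sweep(
        "cells", (10, 50, 100), n_replicates=3, methods=("cardamom_like",), seed=5
    )
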