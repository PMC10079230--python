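"""Network zoo, AUPR scoring and the benchmark/design-sweep machinery."""

import numpy as np
import pandas as pd
import pytest

import burstnet as bn
from burstnet.benchmark import _rebuild_schedule
from burstnet.simulate import SimulationSchedule


class TestZoo:
    def test_fn4_has_four_genes_and_an_inhibition(self):
        net = bn.make_network("FN4")
        assert net.params.n_genes == 4
        assert np.any(net.truth < 0)

    def test_cn5_is_a_cycle(self):
        net = bn.make_network("CN5")
        gene_block = net.truth[1:, 1:]
        assert np.all((gene_block != 0).sum(axis=0) == 1)  # one out-edge each
        assert np.all((gene_block != 0).sum(axis=1) == 1)  # one in-edge each

    def test_bn8_contains_a_toggle_switch(self):
        net = bn.make_network("BN8")
        t = net.truth
        pairs = [
            (i, j)
            for i in range(1, 9)
            for j in range(i + 1, 9)
            if t[i, j] < 0 and t[j, i] < 0
        ]
        assert pairs  # at least one mutual-inhibition pair

    def test_truth_matches_theta_pattern(self):
        for name in ("FN4", "CN5", "FN8", "BN8"):
            net = bn.make_network(name)
            off = ~np.eye(net.truth.shape[0], dtype=bool)
            np.testing.assert_array_equal(
                (net.truth != 0)[off], (net.params.theta != 0)[off]
            )

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            bn.make_network("XX9")


class TestRandomTree:
    def test_single_gene_tree(self):
        net = bn.random_tree(1, seed=0)
        assert net.truth[1, 0] == 1 and np.count_nonzero(net.truth) == 1

    def test_all_nodes_reachable_from_stimulus(self):
        for s in range(5):
            net = bn.random_tree(8, seed=s)
            # each gene has exactly one incoming edge and the graph is a tree
            assert np.all((net.truth != 0).sum(axis=1)[1:] == 1)
            assert np.count_nonzero(net.truth) == 8

    def test_uniform_over_labelled_trees(self):
        """Cayley: 4^2 = 16 labelled trees on 4 nodes, each with equal
        probability under the Pruefer construction."""
        rng = np.random.default_rng(42)
        counts = {}
        n_draws = 16_000
        for _ in range(n_draws):
            net = bn.random_tree(3, seed=rng)
            edges = frozenset(
                (min(i, j), max(i, j))
                for i in range(4)
                for j in range(4)
                if net.truth[i, j] != 0
            )
            counts[edges] = counts.get(edges, 0) + 1
        assert len(counts) == 16
        expected = n_draws / 16
        se = np.sqrt(expected * (1 - 1 / 16))
        for c in counts.values():
            assert abs(c - expected) < 4 * se


class TestAupr:
    def test_perfect_scorer_scores_one(self):
        for name in ("FN4", "CN5", "FN8", "BN8"):
            truth = bn.make_network(name).truth
            assert bn.aupr(np.abs(truth), truth, directed=True) == 1.0
            assert bn.aupr(np.abs(truth), truth, directed=False) == 1.0

    def test_hand_enumerated_toy(self):
        # candidates (1,0), (1,2), (2,0), (2,1) with scores .9/.5/.1/0 and
        # truth 1/0/1/0; stepping thresholds by hand gives AUPR = 5/6
        scores = np.zeros((3, 3))
        truth = np.zeros((3, 3))
        scores[1, 0], scores[1, 2], scores[2, 0], scores[2, 1] = 0.9, 0.5, 0.1, 0.0
        truth[1, 0], truth[2, 0] = 1.0, 1.0
        assert bn.aupr(scores, truth, directed=True) == pytest.approx(5.0 / 6.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bn.aupr(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_symmetric_scorer_never_better_directed(self, tree_benchmark_table):
        t = tree_benchmark_table
        pe = t[t.method == "pearson"].pivot(
            index=["network", "replicate"], columns="directed", values="aupr"
        )
        assert np.all(pe[True] <= pe[False] + 1e-12)


class TestPearsonBaseline:
    def test_duplicated_column_scores_one(self, chain2_data):
        from burstnet.simulate import SnapshotDataset

        counts = chain2_data.counts.copy()
        counts[:, 2] = counts[:, 1]
        dup = SnapshotDataset(counts=counts, time=chain2_data.time)
        assert bn.pearson_baseline(dup)[1, 2] == pytest.approx(1.0)

    def test_independent_genes_score_low(self):
        p = bn.make_parameters(5, beta=50.0)
        data = bn.simulate_snapshots(
            p, SimulationSchedule(timepoints=(0.0, 6.0), cells_per_timepoint=500), seed=0
        )
        scores = bn.pearson_baseline(data)
        gene_block = scores[1:, 1:]
        assert gene_block.max() <= 0.15

    def test_constant_gene_scores_zero(self):
        from burstnet.simulate import SnapshotDataset

        rng = np.random.default_rng(0)
        counts = np.column_stack(
            [
                np.ones(100, dtype=np.int64),
                np.full(100, 7, dtype=np.int64),
                rng.poisson(20.0, 100),
            ]
        )
        data = SnapshotDataset(counts=counts, time=np.repeat([0.0, 6.0], 50))
        scores = bn.pearson_baseline(data)
        assert np.all(scores[1] == 0) and np.all(scores[:, 1] == 0)


class TestRunBenchmark:
    @pytest.fixture(scope="class")
    def tiny_setup(self, chain2_params):
        net = bn.BenchmarkNetwork(
            "chain2", chain2_params, np.sign(chain2_params.theta)
        )
        sched = SimulationSchedule(timepoints=(0.0, 6.0, 12.0), cells_per_timepoint=40)
        return net, sched

    def test_zero_replicates_gives_empty_table(self, tiny_setup):
        net, sched = tiny_setup
        table = bn.run_benchmark([net], n_replicates=0, schedule=sched, seed=0)
        assert table.empty
        assert list(table.columns[:5]) == ["network", "method", "replicate", "directed", "aupr"]

    def test_same_seed_identical_tables(self, tiny_setup):
        net, sched = tiny_setup
        a = bn.run_benchmark([net], methods=("pearson", "random"), n_replicates=2, schedule=sched, seed=4)
        b = bn.run_benchmark([net], methods=("pearson", "random"), n_replicates=2, schedule=sched, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_aupr_within_unit_interval(self, tree_benchmark_table):
        assert tree_benchmark_table.aupr.between(0, 1).all()

    def test_summarize_reports_quartiles(self, tree_benchmark_table):
        summary = bn.summarize(tree_benchmark_table)
        assert {"median", "q1", "q3", "mean"} <= set(summary.columns)
        assert (summary["q1"] <= summary["median"]).all()
        assert (summary["median"] <= summary["q3"]).all()


class TestDesignSweep:
    def test_gap_schedule_arithmetic(self):
        sched = _rebuild_schedule("gap", 48.0, SimulationSchedule())
        assert sched.timepoints == (0.0, 48.0, 96.0)

    def test_budget_conservation(self):
        base = SimulationSchedule()
        for axis, value in (("period_length", 48.0), ("gap", 24.0)):
            sched = _rebuild_schedule(axis, value, base)
            assert int(sched.cohort_sizes().sum()) == 1000

    def test_infeasible_schedule_rejected(self):
        base = SimulationSchedule(timepoints=(0.0, 6.0), cells_per_timepoint=1)
        with pytest.raises(ValueError):
            _rebuild_schedule("gap", 1.0, base)

    def test_table_carries_axis_annotation(self, cells_sweep_table):
        assert set(cells_sweep_table["axis"]) == {"cells"}
        assert set(cells_sweep_table["value"]) == {10, 50, 100}
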