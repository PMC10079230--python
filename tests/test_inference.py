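"""Mixture calibration, binarization and network regression."""

import numpy as np
import pytest
from scipy import stats

import burstnet as bn
from burstnet.inference import EdgeScoreMatrix, GeneMixtureFit, top_edges
from burstnet.simulate import SimulationSchedule, SnapshotDataset


@pytest.fixture(scope="module")
def saturated_two_timepoints(saturated_gene):
    sched = SimulationSchedule(timepoints=(0.0, 6.0), cells_per_timepoint=1000)
    return bn.simulate_snapshots(saturated_gene, sched, seed=3)


class TestMixtureFit:
    def test_parameter_recovery_single_gene(self, saturated_two_timepoints):
        """An unregulated gene at kon/d0 = 4, burst size 50 should be
        recovered within 15% from 2000 cells."""
        fit = bn.fit_gene_mixtures(saturated_two_timepoints, seed=0)
        # single-mode data may split across the two components: the
        # weight-averaged shape is the effective burst-frequency estimate
        w = fit.weights[:, 0].mean()
        a_hat = w * fit.a1[0] + (1 - w) * fit.a0[0]
        assert a_hat == pytest.approx(4.0, rel=0.15)
        assert fit.b[0] == pytest.approx(1.0 / 51.0, rel=0.15)

    def test_off_then_on_gene_weights(self):
        rng = np.random.default_rng(1)
        n = 400
        t0 = np.zeros(n, dtype=np.int64)  # off: no expression
        t1 = rng.negative_binomial(4.0, 1.0 / 51.0, n)  # on
        counts = np.zeros((2 * n, 2), dtype=np.int64)
        counts[:, 0] = np.repeat([0, 1], n)
        counts[:, 1] = np.concatenate([t0, t1])
        data = SnapshotDataset(
            counts=counts, time=np.repeat([0.0, 6.0], n), gene_names=["Stimulus", "G"]
        )
        fit = bn.fit_gene_mixtures(data, seed=2)
        assert fit.weights[0, 0] < 0.05
        assert fit.weights[1, 0] > 0.95
        assert fit.a1[0] == pytest.approx(4.0, rel=0.25)

    def test_all_zero_gene_flagged_degenerate(self):
        counts = np.zeros((40, 2), dtype=np.int64)
        counts[20:, 0] = 1
        data = SnapshotDataset(
            counts=counts, time=np.repeat([0.0, 6.0], 20), gene_names=["Stimulus", "G"]
        )
        fit = bn.fit_gene_mixtures(data, seed=0)
        assert fit.degenerate[0]
        assert fit.a0[0] == 0.0 and fit.a1[0] == 0.0


class TestBinarize:
    def _toy_fit(self):
        return GeneMixtureFit(
            a0=np.array([0.05]),
            a1=np.array([4.0]),
            b=np.array([1.0 / 51.0]),
            weights=np.array([[0.5], [0.5]]),
            timepoints=np.array([0.0, 6.0]),
            gene_names=["Stimulus", "G"],
            degenerate=np.array([False]),
        )

    def _toy_data(self, values):
        values = np.asarray(values, dtype=np.int64)
        counts = np.column_stack([np.ones_like(values), values])
        return SnapshotDataset(
            counts=counts,
            time=np.full(values.shape[0], 6.0),
            gene_names=["Stimulus", "G"],
        )

    def test_posterior_matches_explicit_bayes_ratio(self):
        fit = self._toy_fit()
        grid = np.arange(0, 400)
        data = self._toy_data(grid)
        post = bn.binarize(data, fit)[:, 1]
        f0 = stats.nbinom(0.05, 1.0 / 51.0).pmf(grid)
        f1 = stats.nbinom(4.0, 1.0 / 51.0).pmf(grid)
        expected = 0.5 * f1 / (0.5 * f1 + 0.5 * f0)
        np.testing.assert_allclose(post, expected, atol=1e-6)

    def test_posterior_saturates(self):
        fit = self._toy_fit()
        post = bn.binarize(self._toy_data([0, 350]), fit)[:, 1]
        assert post[0] <= 0.01  # zero count, well-separated modes
        assert post[1] >= 0.99  # count far above both mode means

    def test_hard_binarization_ties_go_high(self):
        fit = self._toy_fit()
        data = self._toy_data([0, 350])
        hard = bn.binarize(data, fit, hard=True)[:, 1]
        assert set(hard) <= {0.0, 1.0}

    def test_stimulus_column_passes_through(self):
        fit = self._toy_fit()
        data = self._toy_data([0, 10, 350])
        out = bn.binarize(data, fit)
        np.testing.assert_array_equal(out[:, 0], data.counts[:, 0])


class TestInferNetwork:
    def test_chain_sign_and_ranking_recovery(self, chain2_params):
        """On Stimulus -> 1 -> 2 data, both true edges must be positive and
        outrank every absent edge in at least 8 of 10 seeded replicates."""
        wins = 0
        for s in range(10):
            data = bn.simulate_snapshots(chain2_params, SimulationSchedule(), seed=s)
            _, scores = bn.infer_network(data, d0=chain2_params.d0, seed=s)
            th = scores.theta_hat
            true_low = min(th[1, 0], th[2, 1])
            absent_high = max(abs(th[1, 2]), abs(th[2, 0]))
            wins += th[1, 0] > 0 and th[2, 1] > 0 and true_low > absent_high
        assert wins >= 8

    def test_null_network_scores_below_true_edges(self, chain2_params, chain2_data):
        null = chain2_params.null_network()
        null_data = bn.simulate_snapshots(null, SimulationSchedule(), seed=0)
        _, null_scores = bn.infer_network(null_data, d0=null.d0, seed=0)
        _, chain_scores = bn.infer_network(chain2_data, d0=chain2_params.d0, seed=0)
        mask = ~np.eye(3, dtype=bool)
        mask[0] = False
        null_mean = np.abs(null_scores.theta_hat[mask]).mean()
        true_mean = np.mean([chain_scores.theta_hat[1, 0], chain_scores.theta_hat[2, 1]])
        assert null_mean <= true_mean

    def test_cell_permutation_invariance(self, chain2_data, chain2_params):
        perm = np.random.default_rng(0).permutation(chain2_data.n_cells)
        shuffled = SnapshotDataset(
            counts=chain2_data.counts[perm],
            time=chain2_data.time[perm],
            gene_names=list(chain2_data.gene_names),
        )
        _, a = bn.infer_network(chain2_data, d0=chain2_params.d0, seed=0)
        _, b = bn.infer_network(shuffled, d0=chain2_params.d0, seed=0)
        np.testing.assert_allclose(a.theta_hat, b.theta_hat, atol=1e-5)

    def test_stimulus_row_exactly_zero(self, chain4_loop):
        assert np.all(chain4_loop.scores.theta_hat[0] == 0)
        assert np.all(chain4_loop.params.theta[0] == 0)

    def test_fewer_timepoints_fewer_edges(self, chain2_data, chain2_params):
        keep = np.isin(chain2_data.time, (0.0, 6.0))
        truncated = SnapshotDataset(
            counts=chain2_data.counts[keep],
            time=chain2_data.time[keep],
            gene_names=list(chain2_data.gene_names),
        )
        _, full = bn.infer_network(chain2_data, d0=chain2_params.d0, seed=0)
        _, trunc = bn.infer_network(truncated, d0=chain2_params.d0, seed=0)
        assert np.count_nonzero(trunc.theta_hat) <= np.count_nonzero(full.theta_hat)

    def test_too_few_timepoints_rejected(self, chain2_data):
        keep = chain2_data.time == 0.0
        single = SnapshotDataset(
            counts=chain2_data.counts[keep],
            time=chain2_data.time[keep],
            gene_names=list(chain2_data.gene_names),
        )
        with pytest.raises(ValueError):
            bn.infer_network(single, d0=0.5)

    def test_inferred_parameters_are_simulable(self, chain4_loop):
        assert bn.validate(chain4_loop.params) == []

    def test_recovery_beats_prevalence_on_trees(self, tree_benchmark_table):
        t = tree_benchmark_table
        sub = t[(t.method == "cardamom_like") & t.directed]
        assert (sub.aupr > sub.prevalence).sum() >= 4  # of 5 replicates


class TestSelfConsistency:
    def test_resimulation_matches_most_marginals(self, chain4_loop):
        """Simulate -> calibrate -> re-simulate: most gene x timepoint
        marginals should be statistically indistinguishable from the
        original data (KS at 5%)."""
        assert chain4_loop.report.green_fraction() >= 0.8


class TestEdgeOperations:
    def _scores(self):
        stack = np.zeros((3, 3, 3))
        stack[:, 1, 0] = [0.0, 3.0, 1.0]
        stack[:, 2, 1] = [2.0, 2.0, 0.0]
        return EdgeScoreMatrix(
            theta_hat=np.max(stack, axis=0),
            beta_hat=np.zeros(2),
            per_timepoint=stack,
            transitions=np.array([6.0, 12.0, 24.0]),
        )

    def test_edges_assigned_to_strongest_transition(self):
        decomp = dict(
            ((edge, t) for edge, t, _ in bn.temporal_decomposition(self._scores()))
        )
        assert decomp[(1, 0)] == 12.0  # max at the second transition
        assert decomp[(2, 1)] == 6.0  # tie resolved to the earliest

    def test_zero_edges_not_listed(self):
        edges = [e for e, _, _ in bn.temporal_decomposition(self._scores())]
        assert (2, 0) not in edges

    def test_missing_stack_raises(self):
        scores = EdgeScoreMatrix(theta_hat=np.zeros((3, 3)), beta_hat=np.zeros(2))
        with pytest.raises(ValueError):
            bn.temporal_decomposition(scores)

    def test_top_edges_keeps_strongest_per_sign(self):
        theta = np.zeros((5, 5))
        theta[1] = [5.0, 0.0, 1.0, -3.0, -0.1]
        pruned = top_edges(theta, fraction=0.2)  # ceil(0.2*5) = 1 per sign
        np.testing.assert_allclose(pruned[1], [5.0, 0.0, 0.0, -3.0, 0.0])

    def test_top_edges_identity_at_full_fraction(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(size=(4, 4))
        pruned = top_edges(theta, fraction=1.0)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(pruned[off], theta[off])
        assert np.all(np.diag(pruned) == 0)

    def test_top_edges_zero_rows_stay_zero(self):
        assert np.all(top_edges(np.zeros((3, 3)), 0.5) == 0)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            top_edges(np.zeros((3, 3)), 0.0)
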