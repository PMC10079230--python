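"""Benchmarking network inference on simulated ground-truth networks.

Provides a small zoo of canonical network structures (feedback-loop,
cycling and branching topologies plus uniformly random activation
trees), snapshot simulation from them, and AUPR scoring of inferred
edge matrices against the known truth.  Precision-recall is preferred
over ROC because true edges are sparse: only a small fraction of the
possible ordered gene pairs carry an interaction, so controlling false
positives matters most.  Self-regulations (diagonal entries) and edges
pointing *into* the stimulus are excluded from scoring.

The zoo's exact edge weights are a documented package convention
(magnitude 10, inhibitions negative); the scoring is purely rank-based
so only the sign pattern matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .inference import infer_network
from .network import GRNParameters, make_parameters
from .simulate import SimulationSchedule, SnapshotDataset, simulate_snapshots

__all__ = [
    "BenchmarkNetwork",
    "make_network",
    "random_tree",
    "aupr",
    "prevalence",
    "pearson_baseline",
    "run_benchmark",
    "design_sweep",
    "summarize",
]

DEFAULT_EDGE_MAGNITUDE = 10.0
DEFAULT_BASAL = -5.0

# Canonical zoo topologies as (regulator, target, sign) triples; node 0 is
# the stimulus.  Reconstructed from their structural descriptions: FN4 is a
# 4-gene branching structure with an inhibition feedback loop, CN5 a 5-gene
# cycle, FN8 an 8-gene double branch with two feedback loops, BN8 an 8-gene
# branching network dominated by a toggle switch (mutual inhibition).
ZOO_EDGES = {
    "FN4": [(0, 1, +1), (1, 2, +1), (1, 3, +1), (2, 4, +1), (4, 1, -1)],
    "CN5": [(0, 1, +1), (1, 2, +1), (2, 3, +1), (3, 4, +1), (4, 5, +1), (5, 1, +1)],
    "FN8": [
        (0, 1, +1),
        (1, 2, +1),
        (2, 3, +1),
        (3, 4, +1),
        (1, 5, +1),
        (5, 6, +1),
        (6, 7, +1),
        (7, 8, +1),
        (4, 1, -1),
        (8, 5, -1),
    ],
    "BN8": [
        (0, 1, +1),
        (1, 2, +1),
        (1, 3, +1),
        (2, 3, -1),
        (3, 2, -1),
        (2, 4, +1),
        (2, 5, +1),
        (3, 6, +1),
        (3, 7, +1),
        (6, 8, +1),
    ],
}


@dataclass
class BenchmarkNetwork:
    """A ground-truth network: its name, simulable parameters, and the
    signed adjacency used as scoring truth (diagonal excluded)."""

    name: str
    params: GRNParameters
    truth: np.ndarray


def _params_from_edges(n_genes: int, edges, magnitude: float) -> GRNParameters:
    theta = np.zeros((n_genes + 1, n_genes + 1))
    for src, dst, sign in edges:
        theta[dst, src] = sign * magnitude
    return make_parameters(n_genes, theta=theta, beta=DEFAULT_BASAL)


def make_network(name: str, magnitude: float = DEFAULT_EDGE_MAGNITUDE) -> BenchmarkNetwork:
    """Build a canonical zoo network (FN4, CN5, FN8 or BN8)."""
    if name not in ZOO_EDGES:
        raise ValueError(f"unknown network {name!r}; choose from {sorted(ZOO_EDGES)}")
    edges = ZOO_EDGES[name]
    n_genes = max(max(s, d) for s, d, _ in edges)
    params = _params_from_edges(n_genes, edges, magnitude)
    truth = np.sign(params.theta)
    np.fill_diagonal(truth, 0)
    return BenchmarkNetwork(name, params, truth)


def random_tree(n_genes: int, seed=None, magnitude: float = DEFAULT_EDGE_MAGNITUDE) -> BenchmarkNetwork:
    """A uniformly random labelled activation tree on ``n_genes + 1`` nodes.

    The tree is drawn uniformly over labelled trees (Pruefer-sequence
    construction), rooted at the stimulus (node 0) with edges directed
    away from the root; all edges are activations.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = nx.random_labeled_tree(n_genes + 1, seed=int(rng.integers(2**31)))
    edges = [
        (src, dst, +1) for src, dst in nx.bfs_edges(tree, 0)
    ]
    params = _params_from_edges(n_genes, edges, magnitude)
    truth = np.sign(params.theta)
    np.fill_diagonal(truth, 0)
    return BenchmarkNetwork(f"Tree{n_genes}", params, truth)


def _candidate_mask(n1: int) -> np.ndarray:
    """Scored entries: off-diagonal, excluding edges into the stimulus."""
    mask = ~np.eye(n1, dtype=bool)
    mask[0, :] = False
    return mask


def _symmetrise(mat: np.ndarray) -> np.ndarray:
    a = np.abs(mat)
    return np.maximum(a, a.T)


def aupr(scores: np.ndarray, truth: np.ndarray, directed: bool = True) -> float:
    """Area under the precision-recall curve of ranked candidate edges.

    Candidates are the off-diagonal entries (self-regulation excluded),
    omitting entries that would point into the stimulus; truth is
    binarised by dropping signs.  In undirected mode both matrices are
    symmetrised by the max of the two directions and unordered pairs are
    scored.  The area uses the standard step-wise sum over thresholds,
    with tied scores collapsing into a single threshold step.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if scores.shape != truth.shape or scores.shape[0] != scores.shape[1]:
        raise ValueError("scores and truth must be square matrices of equal shape")
    n1 = scores.shape[0]
    if directed:
        mask = _candidate_mask(n1)
        y = (np.abs(truth) > 0)[mask].astype(int)
        s = np.abs(scores)[mask]
    else:
        S = _symmetrise(scores)
        T = _symmetrise(truth)
        iu = np.triu_indices(n1, k=1)
        y = (T[iu] > 0).astype(int)
        s = S[iu]
    if y.sum() == 0:
        raise ValueError("truth contains no edges among the candidates")
    return float(average_precision_score(y, s))


def prevalence(truth: np.ndarray, directed: bool = True) -> float:
    """Fraction of candidate edges that are true: the random-scorer baseline."""
    truth = np.asarray(truth, dtype=float)
    n1 = truth.shape[0]
    if directed:
        mask = _candidate_mask(n1)
        y = (np.abs(truth) > 0)[mask]
    else:
        T = _symmetrise(truth)
        iu = np.triu_indices(n1, k=1)
        y = T[iu] > 0
    return float(np.mean(y))


def pearson_baseline(data: SnapshotDataset) -> np.ndarray:
    """Symmetric edge scores: |Pearson correlation| between count columns.

    Cells are pooled over all timepoints and the stimulus indicator is
    included as a column; zero-variance genes score 0; the diagonal is
    zeroed.
    """
    counts = data.counts.astype(float)
    if counts.shape[0] < 2:
        raise ValueError("need at least two cells")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(counts, rowvar=False)
    corr = np.nan_to_num(np.abs(corr))
    np.fill_diagonal(corr, 0.0)
    return corr


def _score(method: str, data: SnapshotDataset, net: BenchmarkNetwork, seed) -> np.ndarray:
    if method == "pearson":
        return pearson_baseline(data)
    if method == "random":
        rng = np.random.default_rng(seed)
        return rng.integers(0, 2, size=net.truth.shape).astype(float)
    if method == "cardamom_like":
        _, scores = infer_network(data, d0=net.params.d0, seed=seed)
        return np.abs(scores.theta_hat)
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(
    networks,
    methods=("cardamom_like", "pearson", "random"),
    n_replicates: int = 10,
    schedule: SimulationSchedule | None = None,
    seed=0,
) -> pd.DataFrame:
    """Simulate datasets from ground-truth networks and score each method.

    For every network x replicate, a snapshot dataset is simulated with
    a fresh seed, every method produces an edge-score matrix, and both
    directed and undirected AUPR are recorded.  Returns a tidy table
    with columns network, method, replicate, directed, aupr,
    prevalence.  Results are deterministic in the root seed.
    """
    if schedule is None:
        schedule = SimulationSchedule()
    rows = []
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for net in networks:
        for rep in range(n_replicates):
            sim_seed, *method_seeds = ss.spawn(1 + len(methods))
            data = simulate_snapshots(net.params, schedule, seed=np.random.default_rng(sim_seed))
            for method, mseed in zip(methods, method_seeds):
                scores = _score(method, data, net, np.random.default_rng(mseed))
                for directed in (True, False):
                    rows.append(
                        {
                            "network": net.name,
                            "method": method,
                            "replicate": rep,
                            "directed": directed,
                            "aupr": aupr(scores, net.truth, directed=directed),
                            "prevalence": prevalence(net.truth, directed=directed),
                        }
                    )
    return pd.DataFrame(rows, columns=["network", "method", "replicate", "directed", "aupr", "prevalence"])


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Box-plot style summary: median and quartiles per network/method."""
    group_cols = [c for c in ("network", "method", "directed", "axis", "value") if c in table.columns]
    g = table.groupby(group_cols)["aupr"]
    return g.agg(median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75), mean="mean").reset_index()


def _rebuild_schedule(axis: str, value, base: SimulationSchedule) -> SimulationSchedule:
    tp = np.asarray(base.timepoints)
    budget = int(base.cohort_sizes().sum())
    if axis == "cells":
        return SimulationSchedule(
            timepoints=tuple(tp),
            cells_per_timepoint=int(value),
            burnin=base.burnin,
            rate_scale_after=base.rate_scale_after,
        )
    gaps = np.diff(tp)
    gap = float(gaps[0])
    if axis == "period_length":
        new_tp = np.arange(0.0, float(value) + gap / 2, gap)
    elif axis == "gap":
        final = float(tp[-1])
        new_tp = np.arange(0.0, final + float(value) / 2, float(value))
    else:
        raise ValueError(f"unknown sweep axis {axis!r}")
    ntp = len(new_tp)
    if ntp > budget:
        raise ValueError("more timepoints than budgeted cells")
    sizes = np.full(ntp, budget // ntp)
    sizes[: budget % ntp] += 1  # rounding spillover to the earliest timepoints
    return SimulationSchedule(
        timepoints=tuple(new_tp),
        cells_per_timepoint=tuple(int(s) for s in sizes),
        burnin=base.burnin,
        rate_scale_after=base.rate_scale_after,
    )


def design_sweep(
    axis: str,
    values,
    base_schedule: SimulationSchedule | None = None,
    n_genes: int = 10,
    n_replicates: int = 10,
    methods=("cardamom_like", "pearson"),
    seed=0,
) -> pd.DataFrame:
    """Experiment-design sweep over sampling parameters on random trees.

    ``axis`` is one of ``cells`` (cells per timepoint, timepoints
    fixed), ``period_length`` (final time, gap and total cell budget
    fixed) or ``gap`` (spacing, final time and total cell budget
    fixed).  For the two budget-conserving axes the total number of
    cells is redistributed evenly over the rebuilt timepoints, spillover
    going to the earliest ones.  Each replicate draws a fresh random
    tree, reused across values so comparisons are paired.
    """
    if base_schedule is None:
        base_schedule = SimulationSchedule()
    ss = np.random.SeedSequence(seed)
    rep_seqs = ss.spawn(n_replicates)
    frames = []
    for rep, rseq in enumerate(rep_seqs):
        tree_seq, *value_seqs = rseq.spawn(1 + len(values))
        net = random_tree(n_genes, seed=np.random.default_rng(tree_seq))
        net = BenchmarkNetwork(f"{net.name}_r{rep}", net.params, net.truth)
        for value, vseq in zip(values, value_seqs):
            sched = _rebuild_schedule(axis, value, base_schedule)
            sub = run_benchmark(
                [net], methods=methods, n_replicates=1, schedule=sched, seed=vseq
            )
            sub["replicate"] = rep
            sub["axis"] = axis
            sub["value"] = value
            frames.append(sub)
    return pd.concat(frames, ignore_index=True)
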