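"""Exact stochastic simulation of the bursty GRN model.

The model is a piecewise-deterministic Markov process.  Between bursts,
mRNA of gene ``i`` decays exponentially,

    M_i(t0 + dt) = M_i(t0) * exp(-d0_i dt),

and protein follows ``dP_i/dt = s1_i M_i - d1_i P_i``, which has the
closed form

    P_i(t0 + dt) = P_i(t0) e^{-d1 dt} + s1 M_i(t0) (e^{-d0 dt} - e^{-d1 dt}) / (d1 - d0)

(with the removable singularity at ``d0 = d1`` handled by its limit
``s1 M_i(t0) dt e^{-d0 dt}``).  At a burst of gene ``i``, ``M_i`` jumps
by an exponential draw with mean ``burst_size_mean_i``.

Burst times are sampled exactly by thinning: candidate events are
proposed at the constant majorising rate ``sum_i k1_i`` (gene chosen
proportionally to ``k1_i``) and a candidate for gene ``i`` at time ``t``
is accepted with probability ``kon_i(P(t)) / k1_i``, with ``P(t)``
evaluated in closed form at the candidate time.  Because every step is
closed-form, the scheme involves no numerical integration and is exact.

Measured counts are produced by an extra Poisson layer: each observed
count is a Poisson draw whose mean is the simulated mRNA level, which
turns the Gamma-shaped continuous marginals into negative binomials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .network import GRNParameters, STIMULUS_NAME, burst_frequency

__all__ = [
    "CellState",
    "SimulationSchedule",
    "SnapshotDataset",
    "Trajectory",
    "simulate_cell",
    "stationary_cell",
    "stationary_states",
    "poisson_layer",
    "simulate_snapshots",
    "nb_moments",
    "PAPER_TIMEPOINTS",
]

#: Snapshot timepoints (hours) of the reference benchmark protocol.
PAPER_TIMEPOINTS = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0, 84.0, 96.0)


@dataclass
class CellState:
    """State of one cell: time ``t`` (hours), mRNA vector ``M`` (copies,
    continuous, length ``n``) and protein vector ``P`` (length ``n+1``,
    index 0 = stimulus level in {0, 1})."""

    t: float
    M: np.ndarray
    P: np.ndarray

    def copy(self) -> "CellState":
        return CellState(self.t, self.M.copy(), self.P.copy())


@dataclass
class SimulationSchedule:
    """Snapshot sampling protocol.

    ``timepoints`` are strictly increasing sampling times (hours);
    ``cells_per_timepoint`` is an integer or one integer per timepoint;
    ``burnin`` is the pre-stimulus equilibration time; if
    ``rate_scale_after = (t_star, f)`` is set, burst frequencies and the
    synthesis/degradation rates (but not the burst size) are multiplied
    by ``f`` for ``t >= t_star``, a time-rescaling that accelerates the
    dynamics while preserving the stationary law.
    """

    timepoints: tuple = PAPER_TIMEPOINTS
    cells_per_timepoint: int | tuple = 100
    burnin: float | None = None
    rate_scale_after: tuple | None = None

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0 or np.any(np.diff(tp) <= 0) or tp[0] < 0:
            raise ValueError("timepoints must be strictly increasing and nonnegative")
        self.timepoints = tuple(tp)
        if self.rate_scale_after is not None and self.rate_scale_after[1] <= 0:
            raise ValueError("rate scale factor must be positive")

    def cohort_sizes(self) -> np.ndarray:
        sizes = np.broadcast_to(
            np.asarray(self.cells_per_timepoint, dtype=int), (len(self.timepoints),)
        ).copy()
        if np.any(sizes <= 0):
            raise ValueError("cells_per_timepoint must be positive")
        return sizes


@dataclass
class SnapshotDataset:
    """Time-stamped single-cell count matrix.

    ``counts`` is ``cells x (n_genes + 1)`` of nonnegative integers;
    column 0 is the stimulus indicator (0 for pre-stimulus cells, 1
    after).  ``time`` holds one time label (hours) per cell.
    """

    counts: np.ndarray
    time: np.ndarray
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.time = np.asarray(self.time, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.time.shape[0]:
            raise ValueError("counts and time have inconsistent shapes")
        if not self.gene_names:
            n = self.counts.shape[1] - 1
            self.gene_names = [STIMULUS_NAME] + [f"Gene{i}" for i in range(1, n + 1)]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def timepoints(self) -> np.ndarray:
        return np.unique(self.time)

    def counts_at(self, t: float) -> np.ndarray:
        return self.counts[self.time == t]

    def gene_counts(self) -> np.ndarray:
        """Counts without the stimulus column."""
        return self.counts[:, 1:]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.gene_names)
        df.insert(0, "time", self.time)
        df.insert(0, "cell_id", [f"cell{i}" for i in range(self.n_cells)])
        return df


# ---------------------------------------------------------------------------
# closed-form state advance


def _advance_arrays(M, P, dt, d0, d1, s1):
    """Advance mRNA/protein arrays in place by per-row durations ``dt``.

    ``M`` is (C, n), ``P`` is (C, n+1) (column 0 untouched), ``dt`` is
    (C,) or scalar.
    """
    dt = np.asarray(dt, dtype=float)
    if dt.ndim == 0:
        dt = np.full(M.shape[0], float(dt))
    e0 = np.exp(-np.outer(dt, d0))
    e1 = np.exp(-np.outer(dt, d1))
    denom = d1 - d0
    safe = np.where(np.abs(denom) > 1e-12, denom, 1.0)
    coef = np.where(
        np.abs(denom) > 1e-12,
        s1 * (e0 - e1) / safe,
        s1 * dt[:, None] * e0,
    )
    P[:, 1:] = P[:, 1:] * e1 + M * coef
    M *= e0


def _run_cells(M, P, duration, params: GRNParameters, rng, scale: float = 1.0) -> None:
    """Advance every cell (rows of M, P) by ``duration`` hours in place.

    All cells share the parameter set; the stimulus column ``P[:, 0]``
    is held constant.  ``scale`` multiplies burst frequencies and the
    synthesis/degradation rates (burst size is untouched).
    """
    if duration <= 0:
        return
    n = params.n_genes
    k0 = params.k0 * scale
    k1 = params.k1 * scale
    d0 = params.d0 * scale
    d1 = params.d1 * scale
    s1 = params.s1 * scale
    K = k1.sum()
    if K <= 0:
        _advance_arrays(M, P, duration, d0, d1, s1)
        return
    gene_prob = k1 / K
    remaining = np.full(M.shape[0], float(duration))
    active = np.arange(M.shape[0])
    while active.size:
        gaps = rng.exponential(1.0 / K, active.size)
        rem = remaining[active]
        done = gaps >= rem  # candidate falls beyond this cell's horizon
        dt = np.where(done, rem, gaps)
        Ma = M[active]
        Pa = P[active]
        _advance_arrays(Ma, Pa, dt, d0, d1, s1)
        M[active] = Ma
        P[active] = Pa
        remaining[active] = rem - dt
        live = active[~done]
        if live.size:
            genes = rng.choice(n, size=live.size, p=gene_prob)
            rows = params.theta[genes + 1]
            x = params.beta[genes] + np.einsum("ij,ij->i", rows, P[live])
            kon = k0[genes] + (k1[genes] - k0[genes]) * expit(x)
            accept = rng.random(live.size) * k1[genes] < kon
            hit = live[accept]
            g = genes[accept]
            if hit.size:
                M[hit, g] += rng.exponential(params.burst_size_mean[g])
        active = live


# ---------------------------------------------------------------------------
# single-cell trajectory


@dataclass
class Trajectory:
    """A single-cell realisation: initial state, the ordered burst events
    ``(time, gene index 1..n, burst size)``, and the final state.  The
    state at any intermediate time is reconstructed in closed form."""

    params: GRNParameters
    initial: CellState
    events: list
    final: CellState

    @property
    def n_bursts(self) -> int:
        return len(self.events)

    def state_at(self, t: float) -> CellState:
        if not (self.initial.t <= t <= self.final.t):
            raise ValueError("query time outside the simulated interval")
        M = self.initial.M.copy()[None, :]
        P = self.initial.P.copy()[None, :]
        now = self.initial.t
        p = self.params
        for et, gene, size in self.events:
            if et > t:
                break
            _advance_arrays(M, P, et - now, p.d0, p.d1, p.s1)
            M[0, gene - 1] += size
            now = et
        _advance_arrays(M, P, t - now, p.d0, p.d1, p.s1)
        return CellState(t, M[0], P[0])


def simulate_cell(
    params: GRNParameters,
    t_final: float,
    initial: CellState,
    seed=None,
) -> Trajectory:
    """Simulate one cell exactly from ``initial`` up to ``t_final``.

    Burst times are generated by thinning at the constant majorising
    rate ``sum_i k1_i``; the acceptance probability is evaluated at the
    candidate time using the closed-form state.
    """
    if t_final <= initial.t:
        raise ValueError("t_final must exceed the initial time")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = params.n_genes
    K = params.k1.sum()
    gene_prob = params.k1 / K if K > 0 else None
    M = initial.M.copy()[None, :]
    P = initial.P.copy()[None, :]
    t = initial.t
    events: list = []
    while True:
        if K <= 0:
            break
        gap = rng.exponential(1.0 / K)
        if t + gap > t_final:
            break
        _advance_arrays(M, P, gap, params.d0, params.d1, params.s1)
        t += gap
        gene = int(rng.choice(n, p=gene_prob)) + 1
        kon = burst_frequency(params, P[0], gene)
        if rng.random() * params.k1[gene - 1] < kon:
            size = rng.exponential(params.burst_size_mean[gene - 1])
            M[0, gene - 1] += size
            events.append((t, gene, size))
        if not np.all(np.isfinite(M)) or not np.all(np.isfinite(P)):
            raise FloatingPointError("non-finite cell state: check rate units")
    _advance_arrays(M, P, t_final - t, params.d0, params.d1, params.s1)
    return Trajectory(params, initial.copy(), events, CellState(t_final, M[0], P[0]))


def default_burnin(params: GRNParameters) -> float:
    """Default pre-stimulus equilibration time: several protein half-lives."""
    return 4.0 / float(np.min(params.d1))


def stationary_states(
    params: GRNParameters, n_cells: int, burnin: float | None = None, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n_cells`` independent cells at the stimulus-off steady state.

    Returns arrays ``M`` of shape (n_cells, n) and ``P`` of shape
    (n_cells, n+1) after simulating ``burnin`` hours from the empty state
    with the stimulus protein held at 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if burnin is None:
        burnin = default_burnin(params)
    if burnin <= 0:
        raise ValueError("burnin must be positive")
    n = params.n_genes
    M = np.zeros((n_cells, n))
    P = np.zeros((n_cells, n + 1))
    _run_cells(M, P, burnin, params, rng)
    return M, P


def stationary_cell(params: GRNParameters, burnin: float | None = None, seed=None) -> CellState:
    """One cell drawn from the stimulus-off stochastic steady state.

    For an unregulated gene with constant burst frequency ``kon`` the
    marginal law of ``M_i`` is Gamma(shape ``kon/d0``, scale
    ``burst_size_mean``); for coupled genes the state is an exact sample
    of the full process after the burn-in.
    """
    M, P = stationary_states(params, 1, burnin=burnin, seed=seed)
    return CellState(0.0, M[0], P[0])


def poisson_layer(expression: np.ndarray, seed=None) -> np.ndarray:
    """Sample integer counts entrywise: Poisson with the given mean matrix."""
    expression = np.asarray(expression, dtype=float)
    if np.any(expression < 0) or not np.all(np.isfinite(expression)):
        raise ValueError("expression means must be finite and nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(expression)


def simulate_snapshots(
    params: GRNParameters, schedule: SimulationSchedule, seed=None
) -> SnapshotDataset:
    """Generate a time-stamped snapshot dataset.

    Each sampled cell is independent: it starts from its own draw of
    the stimulus-off steady state, the stimulus protein switches to 1
    at t = 0, the cell evolves to its sampling time and is then
    measured (destructively) through the Poisson layer.  Cells sampled
    at t = 0 are measured just before stimulus onset, so their stimulus
    column is 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tp = np.asarray(schedule.timepoints)
    sizes = schedule.cohort_sizes()
    C = int(sizes.sum())
    n = params.n_genes
    M, P = stationary_states(params, C, burnin=schedule.burnin, seed=rng)

    cohort = np.repeat(np.arange(len(tp)), sizes)
    expr = np.zeros((C, n))
    stim_col = np.ones(C)

    k = 0
    if tp[0] == 0.0:
        sel = cohort == 0
        expr[sel] = M[sel]
        stim_col[sel] = 0.0
        k = 1
    # stimulus on for everyone still evolving
    P[:, 0] = 1.0

    # piecewise segments between sampling times, split at the rate-change time
    boundaries = list(tp[k:])
    t_star = None
    factor = 1.0
    if schedule.rate_scale_after is not None:
        t_star, factor = schedule.rate_scale_after
    now = 0.0
    for t_next in boundaries:
        alive = cohort >= k  # cells not yet sampled
        seg_start, seg_end = now, float(t_next)
        cuts = [seg_start, seg_end]
        if t_star is not None and seg_start < t_star < seg_end:
            cuts = [seg_start, float(t_star), seg_end]
        for a, b in zip(cuts[:-1], cuts[1:]):
            scale = factor if (t_star is not None and a >= t_star) else 1.0
            Ma = M[alive]
            Pa = P[alive]
            _run_cells(Ma, Pa, b - a, params, rng, scale=scale)
            M[alive] = Ma
            P[alive] = Pa
        sel = cohort == k
        expr[sel] = M[sel]
        now = seg_end
        k += 1

    counts = np.zeros((C, n + 1), dtype=np.int64)
    counts[:, 0] = stim_col.astype(np.int64)
    counts[:, 1:] = poisson_layer(expr, seed=rng)
    time = tp[cohort]
    return SnapshotDataset(counts=counts, time=time, gene_names=list(params.gene_names))


def nb_moments(a: float, b: float) -> tuple[float, float, float]:
    """Moments of the negative binomial NB(shape ``a``, scale-prob ``b``).

    Returns ``(mean, variance, CV^2)`` with ``m = a(1-b)/b``,
    ``v = a(1-b)/b^2`` and ``CV^2 = v/m^2 = 1/(a(1-b)) = (1/b)(1/m)``;
    the last identity is the mean-variability scaling law characteristic
    of single-cell count data.
    """
    if a <= 0 or not (0 < b < 1):
        raise ValueError("require a > 0 and 0 < b < 1")
    m = a * (1 - b) / b
    v = a * (1 - b) / b**2
    return m, v, v / m**2
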