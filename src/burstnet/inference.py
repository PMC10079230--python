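"""Calibration of the bursty GRN model from time-stamped count data.

The procedure has two steps, mirroring the structure of the generative
model:

1. *Mixture fitting.*  Under the model, the count marginal of each gene
   is a two-component negative-binomial mixture: a low-burst-frequency
   mode and a high-burst-frequency mode sharing the same scale
   probability ``b_i`` (the burst size does not depend on regulators),
   with only the mode weights varying over time.  An EM algorithm fits,
   per gene, the two shapes ``a0_i < a1_i`` (burst frequencies in units
   of the mRNA degradation rate ``d0_i``), the shared ``b_i`` and one
   high-mode weight per timepoint.

2. *Network regression.*  Each cell/gene pair is softly *binarized*
   into its posterior probability of sitting in the high-frequency
   mode.  These mode indicators serve as dimensionless protein
   surrogates, going forward in time: protein integrates mRNA over
   roughly one timepoint gap and cells are statistically independent,
   so the surrogate for regulator ``j`` seen by a cell sampled at
   ``t_m`` is the population mean mode occupancy of ``j`` at the
   previous timepoint (the stimulus, whose protein level is known
   exactly, uses the cell's own 0/1 indicator).  For each transition
   between consecutive timepoints and each target gene, a penalised
   logistic regression predicts the gene's own indicator from these
   surrogates, pooling the cells of both endpoint timepoints.  An L1
   penalty keeps the network sparse and a proximal ridge ties each
   transition's coefficients to the previous ones, so an edge is
   detected at the transition where its regulator's occupancy shift
   explains the target's mode shift.  The consolidated score of an
   edge is its strongest (signed) value across transitions.  An
   optional within-cell blend mixes the cell's own regulator
   indicators into the surrogates, exposing cell-level covariation
   (useful for mutual-inhibition structures) at the cost of
   confounding by co-regulated genes.

Degradation rates are inputs (taken from the literature), not
estimates: they set the timescale that converts dimensionless shapes
into burst frequencies per hour.  The output is both an edge-score
matrix and a full simulable parameter set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

from .network import GRNParameters, normalised_s1
from .simulate import SnapshotDataset

__all__ = [
    "GeneMixtureFit",
    "EdgeScoreMatrix",
    "fit_gene_mixtures",
    "binarize",
    "infer_network",
    "temporal_decomposition",
    "top_edges",
]

_A_FLOOR = 1e-4
_B_EPS = 1e-6


@dataclass
class GeneMixtureFit:
    """Per-gene two-mode negative-binomial mixture.

    ``a0``/``a1`` are the low/high-mode shapes (dimensionless burst
    frequencies, i.e. ``k/d0``), ``b`` the shared scale probability
    (``koff/(koff+s0)``), ``weights[t, i]`` the high-mode weight of
    gene ``i`` at timepoint index ``t``.  A gene whose marginal is
    unimodal (by BIC against a single negative binomial) is collapsed
    to ``a0 == a1``; ``degenerate`` flags all-zero genes, which carry
    no information and are excluded downstream.
    """

    a0: np.ndarray
    a1: np.ndarray
    b: np.ndarray
    weights: np.ndarray
    timepoints: np.ndarray
    gene_names: list[str] = field(default_factory=list)
    degenerate: np.ndarray | None = None
    loglik: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return self.a0.shape[0]

    @property
    def burst_size_mean(self) -> np.ndarray:
        """Estimated mean burst size ``(1-b)/b``."""
        return (1.0 - self.b) / self.b

    def burst_rates(self, d0) -> tuple[np.ndarray, np.ndarray]:
        """Estimated minimal/maximal burst frequencies ``(k0_hat, k1_hat)``
        once per-gene mRNA degradation rates ``d0`` (per hour) are supplied."""
        d0 = np.broadcast_to(np.asarray(d0, dtype=float), (self.n_genes,))
        return self.a0 * d0, self.a1 * d0

    def posterior_high(self, counts: np.ndarray, gene: int, t_index: np.ndarray) -> np.ndarray:
        """Posterior probability that each count of ``gene`` (0-based gene
        column, stimulus excluded) came from the high-frequency mode."""
        if self.degenerate is not None and self.degenerate[gene]:
            return np.zeros(np.asarray(counts).shape[0])
        w = np.clip(self.weights[t_index, gene], 1e-9, 1.0 - 1e-9)
        l0 = _nb_logpmf(counts, self.a0[gene], self.b[gene])
        l1 = _nb_logpmf(counts, self.a1[gene], self.b[gene])
        return expit(np.log(w) - np.log1p(-w) + l1 - l0)


@dataclass
class EdgeScoreMatrix:
    """Directed signed edge scores.

    ``theta_hat`` is the consolidated ``(n+1) x (n+1)`` matrix (row 0 —
    nothing regulating the stimulus — is exactly zero, as is the
    diagonal); ``per_timepoint`` stacks one matrix per inter-timepoint
    transition, labelled by ``transitions`` (the later timepoint of each
    pair).
    """

    theta_hat: np.ndarray
    beta_hat: np.ndarray
    per_timepoint: np.ndarray | None = None
    transitions: np.ndarray | None = None
    gene_names: list[str] = field(default_factory=list)


def _nb_logpmf(x, a, b):
    """log pmf of NB(shape a, scale-prob b): mean a(1-b)/b."""
    x = np.asarray(x, dtype=float)
    a = np.maximum(a, _A_FLOOR)
    b = np.clip(b, _B_EPS, 1 - _B_EPS)
    return (
        gammaln(x + a) - gammaln(a) - gammaln(x + 1) + a * np.log(b) + x * np.log1p(-b)
    )


def _nb_logpmf_grad(x, a, b):
    from scipy.special import digamma

    x = np.asarray(x, dtype=float)
    da = digamma(x + a) - digamma(a) + np.log(b)
    db = a / b - x / (1 - b)
    return da, db


def _weighted_nb_mle(x, r, a0, a1, b):
    """Maximise the expected complete-data log-likelihood over (a0, a1, b).

    ``r`` are high-mode responsibilities.  Parameters are optimised on
    log/logit scales with analytic gradients.
    """

    def unpack(w):
        return np.exp(w[0]), np.exp(w[1]), expit(w[2])

    def negq(w):
        a0_, a1_, b_ = unpack(w)
        a0_ = max(a0_, _A_FLOOR)
        a1_ = max(a1_, _A_FLOOR)
        b_ = min(max(b_, _B_EPS), 1 - _B_EPS)
        l0 = _nb_logpmf(x, a0_, b_)
        l1 = _nb_logpmf(x, a1_, b_)
        q = np.sum((1 - r) * l0 + r * l1)
        da0, db0 = _nb_logpmf_grad(x, a0_, b_)
        da1, db1 = _nb_logpmf_grad(x, a1_, b_)
        g0 = np.sum((1 - r) * da0) * a0_
        g1 = np.sum(r * da1) * a1_
        gb = (np.sum((1 - r) * db0) + np.sum(r * db1)) * b_ * (1 - b_)
        return -q, -np.array([g0, g1, gb])

    w0 = np.array(
        [np.log(max(a0, _A_FLOOR)), np.log(max(a1, _A_FLOOR)), np.log(b / (1 - b))]
    )
    res = minimize(negq, w0, jac=True, method="L-BFGS-B", options={"maxiter": 60})
    return unpack(res.x)


def fit_gene_mixtures(
    data: SnapshotDataset,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed=0,
) -> GeneMixtureFit:
    """Fit, for every gene, a two-mode NB mixture with shared scale and
    per-timepoint mode weights, by maximum likelihood (EM).

    Initialisation is a method-of-moments split of the cells at the
    gene's median positive count, plus seeded multiplicative jitter for
    the restarts; the best restart by log-likelihood wins.  All-zero
    genes are flagged degenerate (``a0 = a1 = 0``) and excluded from the
    downstream regression.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tp = data.timepoints
    if tp.size < 2:
        raise ValueError("need at least two timepoints")
    t_index = np.searchsorted(tp, data.time)
    n = data.n_genes
    counts = data.gene_counts()
    a0 = np.zeros(n)
    a1 = np.zeros(n)
    b = np.full(n, 0.5)
    weights = np.zeros((tp.size, n))
    degenerate = np.zeros(n, dtype=bool)
    loglik = np.full(n, -np.inf)

    for i in range(n):
        x = counts[:, i].astype(float)
        if x.max() == 0:
            degenerate[i] = True
            continue
        best = None
        m, v = x.mean(), x.var()
        b_mom = np.clip(m / v if v > m else 0.5, _B_EPS, 1 - _B_EPS)
        pos = x[x > 0]
        split = np.median(pos)
        low, high = x[x <= split], x[x > split]
        if high.size == 0:
            high = pos
        a0_mom = max(low.mean(), 1e-2) * b_mom / (1 - b_mom)
        a1_mom = max(high.mean(), 1e-2) * b_mom / (1 - b_mom)
        if a1_mom <= a0_mom:
            a1_mom = a0_mom * 2 + 0.1
        for restart in range(n_restarts):
            if restart == 0:
                init = (a0_mom, a1_mom, b_mom)
            else:
                jit = rng.lognormal(0.0, 0.5, size=3)
                init = (
                    a0_mom * jit[0],
                    a1_mom * jit[1],
                    np.clip(b_mom * jit[2], _B_EPS, 1 - _B_EPS),
                )
            fit = _em_single_gene(x, t_index, tp.size, init, tol, max_iter)
            if best is None or fit[-1] > best[-1]:
                best = fit
        # model selection: a single NB may explain a unimodal gene better
        # once the mixture's extra parameters (one shape + T weights) are
        # charged for; collapse spurious mode splits by BIC
        a_s, b_s, ll_s = _single_nb_mle(x)
        n_obs = x.shape[0]
        bic_mix = -2 * best[4] + (tp.size + 3) * np.log(n_obs)
        bic_single = -2 * ll_s + 2 * np.log(n_obs)
        if bic_single <= bic_mix:
            a0[i] = a1[i] = a_s
            b[i] = b_s
            weights[:, i] = 0.5
            loglik[i] = ll_s
        else:
            a0[i], a1[i], b[i] = best[0], best[1], best[2]
            weights[:, i] = best[3]
            loglik[i] = best[4]

    return GeneMixtureFit(
        a0=a0,
        a1=a1,
        b=b,
        weights=weights,
        timepoints=tp,
        gene_names=list(data.gene_names),
        degenerate=degenerate,
        loglik=loglik,
    )


def _single_nb_mle(x):
    """Maximum-likelihood single negative binomial (moment start)."""
    m, v = x.mean(), x.var()
    b0 = np.clip(m / v if v > m else 0.5, _B_EPS, 1 - _B_EPS)
    a0 = max(m * b0 / (1 - b0), _A_FLOOR)
    ones = np.ones_like(x)
    _, a, b = _weighted_nb_mle(x, ones, a0, a0, b0)
    ll = float(np.sum(_nb_logpmf(x, a, b)))
    return a, b, ll


def _em_single_gene(x, t_index, n_tp, init, tol, max_iter):
    a0, a1, b = init
    w = np.full(n_tp, 0.5)
    prev_ll = -np.inf
    r = np.full(x.shape[0], 0.5)
    for _ in range(max_iter):
        wc = np.clip(w[t_index], 1e-9, 1 - 1e-9)
        l0 = _nb_logpmf(x, a0, b) + np.log1p(-wc)
        l1 = _nb_logpmf(x, a1, b) + np.log(wc)
        ll = float(np.sum(logsumexp(np.stack([l0, l1]), axis=0)))
        r = expit(l1 - l0)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
        w = np.array([r[t_index == t].mean() if np.any(t_index == t) else 0.5 for t in range(n_tp)])
        a0, a1, b = _weighted_nb_mle(x, r, a0, a1, b)
    if a0 > a1:  # keep the high-frequency mode second
        a0, a1 = a1, a0
        w = 1.0 - w
    return a0, a1, b, w, prev_ll


def binarize(data: SnapshotDataset, fit: GeneMixtureFit, hard: bool = False) -> np.ndarray:
    """Mode-indicator matrix in [0, 1] of shape ``cells x (n_genes + 1)``.

    Entry ``(c, i)`` is the posterior probability that cell ``c``'s
    count for gene ``i`` came from the high-frequency mode; the stimulus
    column (column 0) passes through unchanged.  With ``hard=True`` the
    posterior is thresholded at 0.5, ties going to the high mode.
    """
    if fit.n_genes != data.n_genes:
        raise ValueError("fit does not cover the dataset's genes")
    t_index = np.searchsorted(fit.timepoints, data.time)
    out = np.zeros((data.n_cells, data.n_genes + 1))
    out[:, 0] = data.counts[:, 0]
    counts = data.gene_counts()
    for i in range(data.n_genes):
        out[:, i + 1] = fit.posterior_high(counts[:, i], i, t_index)
    if hard:
        out[:, 1:] = (out[:, 1:] >= 0.5).astype(float)
    return out


def _penalised_logistic(X, z, theta_prev, lam, rho, beta_init=0.0):
    """L1 + proximal-ridge logistic regression with soft targets.

    Minimises mean cross-entropy of ``sigmoid(beta + X @ theta)``
    against targets ``z`` in [0, 1], plus ``lam * ||theta||_1`` and
    ``rho * ||theta - theta_prev||^2``.  Solved by L-BFGS-B on the
    positive/negative split ``theta = u - v`` (which makes the L1 term
    smooth and the bounds simple).
    """
    m, p = X.shape

    def obj(wv):
        beta = wv[0]
        u = wv[1 : 1 + p]
        v = wv[1 + p :]
        th = u - v
        eta = beta + X @ th
        loss = float(np.mean(np.logaddexp(0.0, eta) - z * eta))
        diff = th - theta_prev
        val = loss + lam * float(np.sum(u + v)) + rho * float(diff @ diff)
        g_eta = (expit(eta) - z) / m
        g_th = X.T @ g_eta + 2.0 * rho * diff
        grad = np.concatenate(([g_eta.sum()], g_th + lam, -g_th + lam))
        return val, grad

    x0 = np.concatenate(
        ([beta_init], np.maximum(theta_prev, 0.0), np.maximum(-theta_prev, 0.0))
    )
    # box bounds keep separable fits finite (the sigmoid is flat out there)
    bounds = [(-12.0, 12.0)] + [(0.0, 25.0)] * (2 * p)
    res = minimize(obj, x0, jac=True, method="L-BFGS-B", bounds=bounds, options={"maxiter": 200})
    beta = float(res.x[0])
    theta = res.x[1 : 1 + p] - res.x[1 + p :]
    theta[np.abs(theta) < 1e-10] = 0.0
    return beta, theta


def infer_network(
    data: SnapshotDataset,
    d0,
    penalty: float = 0.01,
    seed=0,
    d1=0.1,
    proximal_weight: float | None = None,
    within_cell_weight: float = 0.0,
    fit: GeneMixtureFit | None = None,
) -> tuple[GRNParameters, EdgeScoreMatrix]:
    """Calibrate the GRN model on a time-stamped dataset.

    Parameters
    ----------
    data:
        Time-stamped counts (at least two timepoints).
    d0:
        Strictly positive per-gene mRNA degradation rates (per hour); a
        scalar is broadcast.  These are external inputs, typically from
        literature tables.
    penalty:
        L1 weight of the sparsity penalty on ``theta``.
    d1:
        Protein degradation rates used when assembling the simulable
        parameter set (scalar broadcast).
    proximal_weight:
        Weight of the ridge term tying each transition's coefficients
        to the previous transition; defaults to ``penalty``.
    within_cell_weight:
        Fraction (in [0, 1]) of the cell's own mode indicator blended
        into the lagged population surrogate for gene regulators; 0
        (default) uses purely forward-in-time population information.
    fit:
        Optional precomputed mixture fit (to reuse across calls).

    Returns
    -------
    (GRNParameters, EdgeScoreMatrix)
        A fully simulable parameter set and the edge scores with their
        per-transition decomposition.
    """
    tp = data.timepoints
    if tp.size < 2:
        raise ValueError("need at least two timepoints to infer a network")
    n = data.n_genes
    d0 = np.broadcast_to(np.asarray(d0, dtype=float), (n,)).copy()
    if np.any(d0 <= 0):
        raise ValueError("d0 must be strictly positive")
    d1 = np.broadcast_to(np.asarray(d1, dtype=float), (n,)).copy()
    if proximal_weight is None:
        proximal_weight = penalty
    if fit is None:
        fit = fit_gene_mixtures(data, seed=seed)
    Z = binarize(data, fit)
    degenerate = (
        fit.degenerate if fit.degenerate is not None else np.zeros(n, dtype=bool)
    )

    # protein surrogates: stimulus = the cell's own (known) 0/1 level;
    # genes = one-step-lagged population mode occupancy, optionally
    # blended with the cell's own indicator
    t_index = np.searchsorted(tp, data.time)
    occupancy = np.vstack([Z[data.time == t].mean(axis=0) for t in tp])
    lagged = np.vstack([occupancy[0]] + [occupancy[m - 1] for m in range(1, tp.size)])
    X_all = np.empty_like(Z)
    X_all[:, 0] = Z[:, 0]
    X_all[:, 1:] = (
        within_cell_weight * Z[:, 1:]
        + (1.0 - within_cell_weight) * lagged[t_index][:, 1:]
    )

    n_trans = tp.size - 1
    stack = np.zeros((n_trans, n + 1, n + 1))
    betas = np.zeros((n_trans, n))
    theta_prev = np.zeros((n, n))  # per-gene coefficients, self column excluded
    beta_prev = np.zeros(n)
    for k in range(n_trans):
        sel = (data.time == tp[k]) | (data.time == tp[k + 1])
        Xfull = X_all[sel]
        Zsel = Z[sel]
        for i in range(n):
            row = i + 1  # row index of gene i in theta
            if degenerate[i]:
                continue
            z = Zsel[:, row]
            if z.std() < 1e-3:
                # no information at this transition: keep previous coefficients
                stack[k, row] = _row_with_self(theta_prev[i], row)
                betas[k, i] = beta_prev[i]
                continue
            cols = [j for j in range(n + 1) if j != row]
            X = Xfull[:, cols]
            beta_i, th = _penalised_logistic(
                X,
                z,
                theta_prev[i],
                lam=penalty,
                rho=proximal_weight,
                beta_init=beta_prev[i],
            )
            theta_prev[i] = th
            beta_prev[i] = beta_i
            stack[k, row] = _row_with_self(th, row)
            betas[k, i] = beta_i
        if k == 0:
            beta0 = beta_prev.copy()

    if np.all(stack == 0):
        warnings.warn("no informative transitions: all edge scores are zero")

    # consolidated score: strongest signed value across transitions (ties -> earliest)
    absstack = np.abs(stack)
    k_star = np.argmax(absstack, axis=0)
    theta_hat = np.take_along_axis(stack, k_star[None], axis=0)[0]
    theta_hat[0, :] = 0.0
    np.fill_diagonal(theta_hat, 0.0)

    # Debiased refit for the generative parameterisation: the L1 path picks
    # the support, but its shrunken magnitudes would under-drive the sigmoid
    # in simulation.  Refit (beta_i, theta_i restricted to the support) on
    # all cells with a tiny ridge, anchoring basal activities to the
    # pre-stimulus cells and restoring separation-scale magnitudes.
    theta_sim = np.zeros((n + 1, n + 1))
    beta_sim = np.zeros(n)
    for i in range(n):
        if degenerate[i]:
            beta_sim[i] = -10.0
            continue
        row = i + 1
        support = np.flatnonzero(theta_hat[row])
        z = Z[:, row]
        if support.size == 0:
            m = float(np.clip(z.mean(), 1e-4, 1 - 1e-4))
            beta_sim[i] = float(np.log(m / (1 - m)))
            continue
        X = X_all[:, support]
        beta_i, th = _penalised_logistic(
            X, z, np.zeros(support.size), lam=0.0, rho=1e-6, beta_init=0.0
        )
        beta_sim[i] = beta_i
        theta_sim[row, support] = th
    theta_sim[0, :] = 0.0
    np.fill_diagonal(theta_sim, 0.0)

    beta_hat = beta0
    scores = EdgeScoreMatrix(
        theta_hat=theta_hat,
        beta_hat=beta_hat,
        per_timepoint=stack,
        transitions=tp[1:],
        gene_names=list(data.gene_names),
    )

    # assemble a simulable parameter set from the mixture estimates
    k0_hat, k1_hat = fit.burst_rates(d0)
    k0_hat = np.maximum(k0_hat, 0.0)
    k1_hat = np.maximum(k1_hat, np.maximum(k0_hat * 1.001, 1e-2))
    bs = np.where(degenerate, 1.0, fit.burst_size_mean)
    params = GRNParameters(
        theta=theta_sim,
        beta=beta_sim,
        k0=np.where(degenerate, 0.0, k0_hat),
        k1=np.where(degenerate, 1e-2, k1_hat),
        burst_size_mean=bs,
        s1=normalised_s1(np.where(degenerate, 1e-2, k1_hat), d0, d1, bs),
        d0=d0,
        d1=d1,
        gene_names=list(data.gene_names),
    )
    return params, scores


def _row_with_self(theta_row_no_self: np.ndarray, row: int) -> np.ndarray:
    """Re-insert the (zero) diagonal entry into a coefficient row."""
    out = np.zeros(theta_row_no_self.shape[0] + 1)
    out[:row] = theta_row_no_self[:row]
    out[row + 1 :] = theta_row_no_self[row:]
    return out


def temporal_decomposition(scores: EdgeScoreMatrix) -> list[tuple[tuple[int, int], float, float]]:
    """Assign each retained edge to the transition where it is strongest.

    Returns ``[((target, regulator), transition time, signed strength), ...]``
    for every off-diagonal edge with a nonzero score at some transition;
    ties between transitions go to the earliest one.
    """
    if scores.per_timepoint is None:
        raise ValueError("per-timepoint stack is missing")
    stack = scores.per_timepoint
    out = []
    n1 = stack.shape[1]
    for i in range(1, n1):
        for j in range(n1):
            if i == j:
                continue
            vals = stack[:, i, j]
            if np.all(vals == 0):
                continue
            k = int(np.argmax(np.abs(vals)))  # argmax takes the earliest on ties
            out.append(((i, j), float(scores.transitions[k]), float(vals[k])))
    return out


def top_edges(scores, fraction: float) -> np.ndarray:
    """Keep, per target gene, only the strongest activations and inhibitions.

    For each row of the consolidated matrix, the top
    ``ceil(fraction * (n+1))`` positive and top ``ceil(fraction * (n+1))``
    negative off-diagonal entries by absolute value are retained; all
    other entries are zeroed.  ``fraction = 1`` is the identity on
    off-diagonal entries.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    theta = scores.theta_hat if isinstance(scores, EdgeScoreMatrix) else np.asarray(scores)
    out = np.zeros_like(theta, dtype=float)
    n1 = theta.shape[0]
    keep = int(np.ceil(fraction * n1))
    for i in range(n1):
        row = theta[i].copy()
        row[i] = 0.0
        for sign in (1, -1):
            vals = row * (np.sign(row) == sign)
            idx = np.argsort(-np.abs(vals))[:keep]
            idx = idx[np.abs(vals[idx]) > 0]
            out[i, idx] = row[idx]
    return out
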