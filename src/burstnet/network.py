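"""Parameterisation of the bursty gene-regulatory-network (GRN) model.

Each gene ``i`` is transcribed in random bursts: burst times follow an
inhomogeneous point process whose instantaneous rate (the *burst
frequency*) is a sigmoid function of the current protein levels of all
genes, and burst sizes are exponentially distributed.  Gene-on-gene
influence is encoded by a directed signed matrix ``theta`` acting through
the burst frequency

    kon_i(P) = k0_i + (k1_i - k0_i) * sigmoid(beta_i + sum_j theta_ij P_j)

where ``k0_i`` / ``k1_i`` are the minimal / maximal burst frequencies of
gene ``i`` (per hour) and ``beta_i`` its basal activity.  Node 0 is a
virtual *stimulus*: it has no mRNA and no bursts, only a protein level
that switches from 0 to 1 at the start of the experiment, modelling an
external perturbation (e.g. addition of a differentiation-inducing
medium).

The transcription rate ``s0`` and promoter closing rate ``koff`` of the
underlying two-state promoter model only enter the bursty regime through
their ratio, the mean burst size ``s0/koff`` (mRNA copies), and through
the count-law scale probability ``b = koff/(koff + s0)``; they are never
stored separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

STIMULUS_NAME = "Stimulus"

#: Benchmark kinetic defaults (rates per hour, burst size in mRNA copies).
DEFAULT_K0 = 0.0
DEFAULT_K1 = 2.0
DEFAULT_BURST_SIZE = 50.0
DEFAULT_D0 = 0.5
DEFAULT_D1 = 0.1

_RATE_COLUMNS = ["k0", "k1", "burst_size_mean", "s1", "d0", "d1", "beta"]


def _as_vector(x, n: int, name: str) -> np.ndarray:
    v = np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite")
    return v


@dataclass
class GRNParameters:
    """Full generative parameterisation of a bursty GRN.

    Attributes
    ----------
    theta:
        Signed interaction matrix of shape ``(n+1, n+1)``; ``theta[i, j]``
        is the strength of the influence of node ``j`` on gene ``i``.
        Index 0 is the stimulus node; row 0 is all zeros (nothing
        regulates the stimulus).
    beta:
        Basal activities, length ``n``.
    k0, k1:
        Minimal and maximal burst frequencies (per hour), length ``n``.
    burst_size_mean:
        Mean mRNA burst size ``s0/koff`` (copies), length ``n``.
    s1:
        Protein synthesis rates (protein per mRNA per hour), length ``n``.
    d0, d1:
        mRNA and protein degradation rates (per hour), length ``n``.
    gene_names:
        Node labels of length ``n+1``; element 0 is the stimulus label.
    """

    theta: np.ndarray
    beta: np.ndarray
    k0: np.ndarray
    k1: np.ndarray
    burst_size_mean: np.ndarray
    s1: np.ndarray
    d0: np.ndarray
    d1: np.ndarray
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        n = self.theta.shape[0] - 1
        for name in ("beta", "k0", "k1", "burst_size_mean", "s1", "d0", "d1"):
            setattr(self, name, _as_vector(getattr(self, name), n, name))
        if not self.gene_names:
            self.gene_names = [STIMULUS_NAME] + [f"Gene{i}" for i in range(1, n + 1)]

    @property
    def n_genes(self) -> int:
        """Number of modelled genes, excluding the stimulus node."""
        return self.theta.shape[0] - 1

    @property
    def scale_prob(self) -> np.ndarray:
        """Scale probability ``b = koff/(koff+s0) = 1/(1 + burst size)`` of the count law."""
        return 1.0 / (1.0 + self.burst_size_mean)

    def copy(self) -> "GRNParameters":
        return replace(
            self,
            theta=self.theta.copy(),
            beta=self.beta.copy(),
            k0=self.k0.copy(),
            k1=self.k1.copy(),
            burst_size_mean=self.burst_size_mean.copy(),
            s1=self.s1.copy(),
            d0=self.d0.copy(),
            d1=self.d1.copy(),
            gene_names=list(self.gene_names),
        )

    def null_network(self) -> "GRNParameters":
        """Copy with all interactions removed (``theta = 0``), genes kept independent."""
        out = self.copy()
        out.theta[:] = 0.0
        return out


def normalised_s1(k1, d0, d1, burst_size_mean) -> np.ndarray:
    """Protein synthesis rate placing the fully-active stationary protein level at 1.

    A gene bursting at its maximal frequency ``k1`` has stationary mean
    mRNA ``(k1/d0) * burst_size_mean``; choosing
    ``s1 = d1 / mean_mRNA`` makes the stationary protein level of a
    fully active gene equal 1, so that ``theta`` and ``beta`` live on a
    common, dimensionless protein scale.
    """
    k1 = np.asarray(k1, dtype=float)
    mean_high = k1 / np.asarray(d0, dtype=float) * np.asarray(burst_size_mean, dtype=float)
    return np.asarray(d1, dtype=float) / np.maximum(mean_high, 1e-12)


def make_parameters(
    n_genes: int,
    theta: np.ndarray | None = None,
    beta=0.0,
    k0=DEFAULT_K0,
    k1=DEFAULT_K1,
    burst_size_mean=DEFAULT_BURST_SIZE,
    s1=None,
    d0=DEFAULT_D0,
    d1=DEFAULT_D1,
    gene_names: list[str] | None = None,
) -> GRNParameters:
    """Build a :class:`GRNParameters` with benchmark kinetic defaults.

    ``s1`` defaults to the normalised value of :func:`normalised_s1` so
    that protein levels are O(1) and interaction strengths are portable
    across genes.
    """
    if theta is None:
        theta = np.zeros((n_genes + 1, n_genes + 1))
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (n_genes + 1, n_genes + 1):
        raise ValueError(
            f"theta must have shape ({n_genes + 1}, {n_genes + 1}), got {theta.shape}"
        )
    k0v = _as_vector(k0, n_genes, "k0")
    k1v = _as_vector(k1, n_genes, "k1")
    bsv = _as_vector(burst_size_mean, n_genes, "burst_size_mean")
    d0v = _as_vector(d0, n_genes, "d0")
    d1v = _as_vector(d1, n_genes, "d1")
    if s1 is None:
        s1v = normalised_s1(k1v, d0v, d1v, bsv)
    else:
        s1v = _as_vector(s1, n_genes, "s1")
    return GRNParameters(
        theta=theta,
        beta=_as_vector(beta, n_genes, "beta"),
        k0=k0v,
        k1=k1v,
        burst_size_mean=bsv,
        s1=s1v,
        d0=d0v,
        d1=d1v,
        gene_names=list(gene_names) if gene_names else [],
    )


def burst_frequency(params: GRNParameters, P: np.ndarray, i: int) -> float:
    """Burst frequency of gene ``i`` (per hour) at protein levels ``P``.

    ``P`` has length ``n_genes + 1`` with ``P[0]`` the stimulus protein
    level; ``i`` is a 1-based gene index (0 is the stimulus, which does
    not burst).
    """
    P = np.asarray(P, dtype=float)
    if not (1 <= i <= params.n_genes):
        raise IndexError(f"gene index {i} out of range 1..{params.n_genes}")
    if P.shape != (params.n_genes + 1,):
        raise ValueError("P must have length n_genes + 1")
    if not np.all(np.isfinite(P)):
        raise ValueError("P must be finite")
    x = params.beta[i - 1] + params.theta[i] @ P
    return float(params.k0[i - 1] + (params.k1[i - 1] - params.k0[i - 1]) * expit(x))


def burst_frequency_all(params: GRNParameters, P: np.ndarray) -> np.ndarray:
    """Vector of burst frequencies of all genes at protein levels ``P``."""
    x = params.beta + params.theta[1:] @ np.asarray(P, dtype=float)
    return params.k0 + (params.k1 - params.k0) * expit(x)


def validate(params: GRNParameters) -> list[str]:
    """Check the model invariants; return a list of human-readable violations.

    An empty list means the parameterisation is valid.  This reports
    rather than raises so callers can surface all problems at once.
    """
    issues: list[str] = []
    n = params.n_genes
    if params.theta.shape != (n + 1, n + 1):
        issues.append(f"theta: expected shape ({n + 1}, {n + 1}), got {params.theta.shape}")
        return issues
    if not np.all(np.isfinite(params.theta)):
        issues.append("theta: contains non-finite entries")
    if np.any(params.theta[0] != 0.0):
        issues.append("theta: stimulus row (row 0) must be all zeros, nothing regulates the stimulus")
    if np.any(params.k0 < 0):
        issues.append("k0: minimal burst frequencies must be nonnegative")
    if np.any(params.k1 <= 0):
        issues.append("k1: maximal burst frequencies must be strictly positive")
    if np.any(params.k0 > params.k1):
        issues.append("k0/k1: k0_i must not exceed k1_i")
    for name in ("burst_size_mean", "s1", "d0", "d1"):
        if np.any(getattr(params, name) <= 0):
            issues.append(f"{name}: entries must be strictly positive")
    if len(params.gene_names) != n + 1:
        issues.append(f"gene_names: expected {n + 1} labels, got {len(params.gene_names)}")
    return issues


def write_network(params: GRNParameters, path) -> None:
    """Write a network as a tab-delimited file pair.

    ``<path>_theta.tsv`` holds the ``(n+1) x (n+1)`` interaction matrix
    with gene names as header row/column; ``<path>_rates.tsv`` holds the
    per-gene kinetic table (columns gene, k0, k1, burst_size_mean, s1,
    d0, d1, beta).
    """
    prefix = Path(path)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    names = params.gene_names
    theta_df = pd.DataFrame(params.theta, index=names, columns=names)
    theta_df.to_csv(_theta_path(prefix), sep="\t")
    rates = pd.DataFrame(
        {
            "gene": names[1:],
            "k0": params.k0,
            "k1": params.k1,
            "burst_size_mean": params.burst_size_mean,
            "s1": params.s1,
            "d0": params.d0,
            "d1": params.d1,
            "beta": params.beta,
        }
    )
    rates.to_csv(_rates_path(prefix), sep="\t", index=False)


def read_network(path) -> GRNParameters:
    """Read a network written by :func:`write_network`; validates on load."""
    prefix = Path(path)
    theta_df = pd.read_csv(_theta_path(prefix), sep="\t", index_col=0)
    rates = pd.read_csv(_rates_path(prefix), sep="\t")
    names = [str(c) for c in theta_df.columns]
    theta = theta_df.to_numpy(dtype=float)
    if theta.shape[0] != theta.shape[1]:
        raise ValueError(f"theta matrix is not square: shape {theta.shape}")
    n = theta.shape[0] - 1
    missing = [c for c in _RATE_COLUMNS if c not in rates.columns]
    if missing:
        raise ValueError(f"rate table is missing columns: {missing}")
    if len(rates) != n:
        raise ValueError(
            f"rate table has {len(rates)} genes but theta implies {n} (stimulus included in theta)"
        )
    order = [str(g) for g in rates["gene"]]
    if order != names[1:]:
        rates = rates.set_index("gene").loc[names[1:]].reset_index()
    params = GRNParameters(
        theta=theta,
        beta=rates["beta"].to_numpy(),
        k0=rates["k0"].to_numpy(),
        k1=rates["k1"].to_numpy(),
        burst_size_mean=rates["burst_size_mean"].to_numpy(),
        s1=rates["s1"].to_numpy(),
        d0=rates["d0"].to_numpy(),
        d1=rates["d1"].to_numpy(),
        gene_names=names,
    )
    issues = validate(params)
    if issues:
        raise ValueError("invalid network file: " + "; ".join(issues))
    return params


def _theta_path(prefix: Path) -> Path:
    return prefix.with_name(prefix.name + "_theta.tsv")


def _rates_path(prefix: Path) -> Path:
    return prefix.with_name(prefix.name + "_rates.tsv")
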