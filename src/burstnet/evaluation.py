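"""Dataset-fidelity metrics: does a simulated dataset look like a reference?

Two time-resolved metrics compare the per-gene count marginals of a
simulated snapshot dataset against a reference one at each timepoint:

* two-sample Kolmogorov-Smirnov tests (a gene/timepoint cell is
  "green" when p >= 0.05, i.e. the simulation is not significantly
  different from the reference); the test is conservative on discrete
  counts and is used without continuity correction;
* the 1-D earth mover's (Wasserstein-1) distance between the empirical
  count distributions, averaged over genes per timepoint.

A block of whole-dataset summary statistics (library sizes, zero
fractions, gene-gene and cell-cell correlation distributions) covers
the descriptive characteristics commonly used to assess synthetic
scRNA-seq data.  Genes that are all-zero in both datasets carry no
signal and are excluded from averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, wasserstein_distance

from .simulate import SnapshotDataset

__all__ = ["FidelityReport", "ks_heatmap", "emd_curve", "summary_stats", "compare"]

GREEN_LEVEL = 0.05


@dataclass
class SummaryBlock:
    """Descriptive statistics of one dataset (stimulus column excluded)."""

    library_sizes: np.ndarray
    cell_zero_fraction: np.ndarray
    gene_zero_fraction: np.ndarray
    gene_gene_correlations: np.ndarray
    cell_cell_correlations: np.ndarray


@dataclass
class FidelityReport:
    """Gene x timepoint KS p-values, per-timepoint mean EMD and mean
    p-value, plus summary blocks for both datasets."""

    ks_pvalues: pd.DataFrame
    emd_by_time: pd.Series
    mean_pvalue_by_time: pd.Series
    reference_summary: SummaryBlock
    simulated_summary: SummaryBlock

    def green_fraction(self) -> float:
        """Fraction of gene/timepoint cells not significantly different."""
        vals = self.ks_pvalues.to_numpy()
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals >= GREEN_LEVEL))


def _check_compatible(reference: SnapshotDataset, simulated: SnapshotDataset) -> np.ndarray:
    if reference.gene_names != simulated.gene_names:
        raise ValueError("datasets have different gene sets")
    tp_ref = reference.timepoints
    tp_sim = simulated.timepoints
    if not np.array_equal(tp_ref, tp_sim):
        raise ValueError("datasets have different timepoint sets")
    return tp_ref


def _informative_genes(reference: SnapshotDataset, simulated: SnapshotDataset) -> np.ndarray:
    both = np.vstack([reference.gene_counts(), simulated.gene_counts()])
    return both.max(axis=0) > 0


def ks_heatmap(reference: SnapshotDataset, simulated: SnapshotDataset) -> pd.DataFrame:
    """Two-sample KS p-values per gene (rows) and timepoint (columns).

    Symmetric in its two arguments.  All-zero genes get NaN.
    """
    tp = _check_compatible(reference, simulated)
    keep = _informative_genes(reference, simulated)
    names = reference.gene_names[1:]
    out = np.full((len(names), tp.size), np.nan)
    for j, t in enumerate(tp):
        ref_t = reference.counts_at(t)[:, 1:]
        sim_t = simulated.counts_at(t)[:, 1:]
        for i in range(len(names)):
            if not keep[i]:
                continue
            out[i, j] = ks_2samp(ref_t[:, i], sim_t[:, i]).pvalue
    return pd.DataFrame(out, index=names, columns=tp)


def emd_curve(reference: SnapshotDataset, simulated: SnapshotDataset) -> pd.Series:
    """Mean 1-D earth mover's distance per timepoint, averaged over genes.

    The per-gene distance is the integral of |ECDF_ref - ECDF_sim| over
    the count axis (unnormalised counts); it is zero iff the empirical
    distributions coincide, and symmetric in the two datasets.
    """
    tp = _check_compatible(reference, simulated)
    keep = _informative_genes(reference, simulated)
    vals = np.zeros(tp.size)
    for j, t in enumerate(tp):
        ref_t = reference.counts_at(t)[:, 1:]
        sim_t = simulated.counts_at(t)[:, 1:]
        ds = [
            wasserstein_distance(ref_t[:, i], sim_t[:, i])
            for i in range(ref_t.shape[1])
            if keep[i]
        ]
        vals[j] = float(np.mean(ds)) if ds else np.nan
    return pd.Series(vals, index=tp, name="mean_emd")


def summary_stats(data: SnapshotDataset, seed=0, n_pairs: int = 10_000) -> SummaryBlock:
    """Descriptive statistics of a snapshot dataset.

    Library size is the total count per cell (stimulus column
    excluded).  Gene-gene correlations pool all cells over all gene
    pairs; cell-cell correlations use ``n_pairs`` random cell pairings
    drawn with the given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = data.gene_counts().astype(float)
    lib = counts.sum(axis=1)
    cell_zero = np.mean(counts == 0, axis=1)
    gene_zero = np.mean(counts == 0, axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        gcorr = np.corrcoef(counts, rowvar=False)
    iu = np.triu_indices(counts.shape[1], k=1)
    gene_gene = gcorr[iu]
    gene_gene = gene_gene[np.isfinite(gene_gene)]

    C = counts.shape[0]
    a = rng.integers(0, C, size=n_pairs)
    b = rng.integers(0, C, size=n_pairs)
    ok = a != b
    a, b = a[ok], b[ok]
    xa = counts[a] - counts[a].mean(axis=1, keepdims=True)
    xb = counts[b] - counts[b].mean(axis=1, keepdims=True)
    num = (xa * xb).sum(axis=1)
    den = np.sqrt((xa**2).sum(axis=1) * (xb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = num / den
    cell_cell = cc[np.isfinite(cc)]

    return SummaryBlock(
        library_sizes=lib,
        cell_zero_fraction=cell_zero,
        gene_zero_fraction=gene_zero,
        gene_gene_correlations=gene_gene,
        cell_cell_correlations=cell_cell,
    )


def compare(reference: SnapshotDataset, simulated: SnapshotDataset, seed=0) -> FidelityReport:
    """Full fidelity report between a reference and a simulated dataset."""
    ks = ks_heatmap(reference, simulated)
    emd = emd_curve(reference, simulated)
    mean_p = ks.mean(axis=0, skipna=True)
    mean_p.name = "mean_ks_pvalue"
    return FidelityReport(
        ks_pvalues=ks,
        emd_by_time=emd,
        mean_pvalue_by_time=mean_p,
        reference_summary=summary_stats(reference, seed=seed),
        simulated_summary=summary_stats(simulated, seed=seed),
    )
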