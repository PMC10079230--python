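# Methods

## The mechanistic model

`burstnet` models a cell as a piecewise-deterministic Markov process over
mRNA levels `M_i` (continuous, in copies) and protein levels `P_i`
(dimensionless, see below) for `n` genes plus a stimulus node (index 0).
Transcription happens in bursts: gene `i` bursts at instantaneous rate

    kon_i(P) = k0_i + (k1_i − k0_i) σ(β_i + Σ_j θ_ij P_j),

and each burst adds an Exponential(mean `burst_size_mean_i`) amount of mRNA.
Between bursts, `M_i` decays at rate `d0_i` and `P_i` relaxes toward
`s1_i M_i / d1_i` at rate `d1_i`; both have closed forms (the protein
update handles the removable singularity `d0 = d1` by its limit
`s1·M·Δ·e^{−d0Δ}`). The assumptions inherited from the bursty regime of the
two-state promoter model are: burst frequency (not burst size) is the
regulated quantity; `koff` does not depend on proteins; and the sigmoid
response limits every gene's marginal to at most two modes (low/high burst
frequency). Discreteness of measured data enters only through a final
Poisson layer (counts ~ Poisson(M)), which maps the stationary
Gamma(`kon/d0`, `burst_size`) marginal of an unregulated gene onto
NB(`kon/d0`, `b`) with `b = 1/(1 + burst_size)`.

The stimulus is a protein-only node: `P_0 = 0` before time 0 and `P_0 = 1`
afterwards. `s0` and `koff` are never stored separately — only
`burst_size_mean = s0/koff` and the scale probability `b` derived from it
are identifiable and used.

### Units and default parameters

Time is in hours; all rates per hour. Defaults (per gene, overridable):

| parameter | default | meaning |
|---|---|---|
| `k0` | 0 /h | minimal burst frequency |
| `k1` | 2 /h | maximal burst frequency |
| `burst_size_mean` | 50 | mean mRNA copies per burst |
| `d0` | 0.5 /h | mRNA degradation (half-life ≈ 1.4 h) |
| `d1` | 0.1 /h | protein degradation (half-life ≈ 7 h) |
| `s1` | `d1·d0/(k1·burst_size)` | protein synthesis per mRNA |

The default `s1` places the stationary protein level of a fully active gene
at 1, so `θ` and `β` live on a common dimensionless protein scale; a
typical strong edge is `|θ| = 10` with basal activity `β = −5` (off until
the regulator is ~half active). `d0 = 0.5`, `d1 = 0.1` give the mRNA/protein
half-lives (~1.4 h / ~7 h) typical of mammalian literature compilations;
they matter because they set the delay with which regulation propagates,
which is what the inference exploits.

## Exact simulation

Burst times are sampled by thinning: candidates for all genes jointly at
the constant majorising rate `K = Σ k1_i` (gene picked proportionally to
`k1_i`), accepted with probability `kon_i(P(t))/k1_i` evaluated at the
candidate time via the closed-form state. No numerical integration occurs
anywhere, so the scheme is exact; the test suite checks the thinned
burst-count law against a direct exponential-gap oracle and the stationary
Gamma/NB/CV² closed forms.

Snapshot datasets mimic destructive single-cell measurement: every sampled
cell is an independent realisation started from its own draw of the
stimulus-off steady state (burn-in default `4/min(d1)` hours, i.e. several
protein half-lives), evolved to its sampling time after stimulus onset,
then measured once through the Poisson layer. Cells at t = 0 are measured
just before onset. An optional `rate_scale_after = (t*, f)` multiplies
burst frequencies and synthesis/degradation rates (never the burst size) by
`f` from `t*` on — a time rescaling that preserves the stationary law,
used to model late acceleration of a differentiation process.

For speed, all cells of a dataset advance in vectorised lockstep from one
seeded generator (a 1000-cell × 96 h dataset simulates in ~0.1 s); single
trajectories (`simulate_cell`) use a scalar reference implementation that
records every burst and can be queried at any time.

## Calibration (inference)

**Step 1 — mixtures.** For each gene, an EM algorithm fits a two-component
negative-binomial mixture with one shared scale probability `b_i`, two
shapes `a0_i ≤ a1_i` (burst frequencies in units of `d0_i`) and one
high-mode weight per timepoint. Initialisation is method-of-moments with
the cells split at the median positive count; 10 restarts with seeded
log-normal jitter; convergence when the log-likelihood gain drops below
1e−6. A per-gene BIC comparison against a single negative binomial
collapses unimodal genes (`a0 = a1`), preventing spurious mode splits from
corrupting the shape and scale estimates. All-zero genes are flagged
degenerate and excluded downstream. Degradation rates are *inputs* (from
literature tables); they convert dimensionless shapes into `k̂0 = a0·d0`
and `k̂1 = a1·d0`.

**Step 2 — network regression.** Counts are softly binarized into posterior
high-mode probabilities. Because measured cells are statistically
independent across timepoints and protein integrates mRNA over roughly one
timepoint gap, the regression goes forward in time: the protein surrogate
of regulator `j` for a cell sampled at `t_m` is the *population mean mode
occupancy of `j` at the previous timepoint* (for the stimulus, whose
protein level is known exactly, the cell's own 0/1 indicator). For each
transition `t_{k−1} → t_k` and each target gene, a logistic regression of
the gene's own indicator on these surrogates is solved over the pooled
cells of both endpoint timepoints, with an L1 penalty (default 0.01 on the
mean cross-entropy scale) and a proximal ridge (default equal to the L1
weight) tying the coefficients to the previous transition. The
self-column is excluded (with indicator features it would be the target
itself); the diagonal and the stimulus row of the result are identically
zero. The consolidated score of an edge is its strongest signed value
across transitions (ties to the earliest), which also yields the
per-transition attribution used for temporal network decompositions and
the per-target top-fraction pruning convention.

**Simulable parameters.** L1 shrinkage is good for ranking but bad for
dynamics: shrunken `θ` under-drive the sigmoid and the compensating `β`
inflates the off-state. The returned `GRNParameters` therefore come from a
debiased refit — an unpenalised (ridge 1e−6, box-bounded) logistic
regression restricted to the L1-selected support over all timepoints —
together with `k̂0`, `k̂1`, the estimated burst size `(1−b̂)/b̂`, the
supplied `d0`/`d1`, and the normalised `s1`.

Known limitations, by design of the method: regulation is detected going
forward in time, so a repression whose effect precedes its observable
consequence can be misread as a reversed edge; with purely lagged
population surrogates (`within_cell_weight = 0`, the default), within-cell
covariation is not used, so mutual-inhibition switches are hard to detect
— setting `within_cell_weight > 0` blends the cell's own indicators back
in at the cost of confounding by co-regulated genes.

## Benchmarking

The zoo (`FN4`, `CN5`, `FN8`, `BN8`) reconstructs canonical topologies from
their structural descriptions — a 4-gene branching structure with an
inhibition feedback loop, a 5-gene cycle, an 8-gene double branch with two
feedback loops, and an 8-gene branching network dominated by a
mutual-inhibition toggle — with `|θ| = 10`, inhibitions negative, in a
single edge table (`benchmark.ZOO_EDGES`) that users can swap for other
parameterisations. `random_tree(n)` draws uniformly over labelled trees on
`n+1` nodes (Prüfer construction), roots at the stimulus and directs edges
away from it, all activations.

Scoring uses the area under the precision-recall curve over candidate
edges ranked by |score|: the diagonal (self-regulation) and edges pointing
into the stimulus are excluded; undirected mode symmetrises scores and
truth by the max over the two directions and scores unordered pairs; tied
scores collapse into a single threshold step (step-wise interpolation).
Precision-recall is preferred over ROC because true edges are sparse.
Baselines: absolute pooled Pearson correlation (symmetric) and a random
0/1 scorer whose mean AUPR equals the edge prevalence up to an
O(1/#candidates) positive bias of the step-wise estimator — the package
checks this baseline on networks with ≥100 candidate edges.

`run_benchmark` simulates fresh datasets per network × replicate from a
spawned seed tree and tabulates directed and undirected AUPR;
`design_sweep` rebuilds the snapshot schedule along one axis (cells per
timepoint; period length at fixed gap; gap at fixed final time — the last
two at constant total cell budget, spillover to the earliest timepoints)
with one fresh random tree per replicate reused across values so
comparisons are paired.

## Dataset-fidelity evaluation

Two time-resolved metrics compare per-gene count marginals between a
reference and a simulated dataset: two-sample Kolmogorov–Smirnov p-values
per gene × timepoint ("green" when p ≥ 0.05; the test is conservative on
discrete counts and is used without correction), and the 1-D earth-mover
(Wasserstein-1) distance averaged over genes per timepoint. Genes all-zero
in both datasets are excluded from averages. Summary statistics (library
sizes, per-cell/per-gene zero fractions, gene-gene correlations over all
pairs, cell-cell correlations over 10 000 seeded random pairings) cover
the descriptive characteristics usually inspected on synthetic scRNA-seq
data; the emergence of cell types under an interacting network shows up as
a negative mode of the cell-cell correlation distribution.

The package's central consistency check (`loop`) calibrates the model on a
dataset, re-simulates with the inferred network and with the null network
(θ = 0, everything else identical), and evaluates both against the input.
At t = 0 both arms simulate the same pre-stimulus steady state, so their
distances to the reference differ only by sampling noise; from the first
post-stimulus timepoint on, the inferred-network arm should dominate while
the null arm diverges. Tests assert exactly that.

## Synthetic data as study material

All tests and the acceptance script run on data generated by the package's
own simulator — that is the point of the design (the simulator *is* the
generative model assumed by the inference). Consequences worth stating:
passing tests demonstrate internal consistency and correct mathematics,
not robustness to technical noise, batch effects, sequencing depth
variation, doublets, or model misspecification, none of which the
generator emulates. Default study conditions follow the reference
protocol: 10 timepoints (0, 6, 12, 24, 36, 48, 60, 72, 84, 96 h) × 100
cells, benchmark kinetics as in the table above.

## Problem sizes and numerical choices

Deliberate scale choices for the standard test/acceptance runs (full-size
runs are available through the API): the ranking comparison uses 5 seeded
Tree(10) datasets (1 replicate each), the design sweep 3 replicates over
cells ∈ {10, 50, 100}, the self-consistency loop one 4-gene cascade; the
stationary/CV² checks use 2000–4000 cells per condition and the thinning
check 10 000 short runs. Numerical details: EM tolerance 1e−6 on the
log-likelihood; shape floor 1e−4 and scale clipping 1e−6; L-BFGS-B
throughout, with the L1 term made smooth by the positive/negative split
`θ = u − v`; logistic coefficients box-bounded (|β| ≤ 12, |θ| ≤ 25) so
separable fits stay finite; hard-binarization ties (posterior exactly 0.5)
go to the high mode; zero-variance regression targets leave the previous
transition's coefficients untouched; all randomness flows from one root
seed through named `SeedSequence` substreams.
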