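# Methods

## Network model

Each condition (WT, KO) is represented as a directed weighted bipartite
graph: gene source nodes, biological-process (BP) target nodes, one edge
per (gene, annotated BP) pair. The edge weight is the gene's
*representation* in that condition: `log2(1 + mean expression across the
condition's replicates)` by default, or the raw arithmetic mean with
`transform="linear"`. Genes whose mean expression is at or below
`min_weight` (default 0) are absent from that condition's network; BPs
appear only through incident edges.

**Why the log representation is the default.** Normalized expression is
heavy-tailed (orders of magnitude between genes). With raw means as edge
weights the dominant eigenvector of the adjacency frequently *localizes*
on the single strongest gene star: that gene and its processes absorb
essentially all centrality mass, every other node's max-normalized score
collapses toward zero, and the between-condition rate of change becomes an
artifact of whichever star happens to dominate each network. In
simulation this made planted centrality-gainers unrecoverable in a
substantial fraction of random datasets regardless of how strongly they
were planted. The log2(1+x) transform — the standard variance-stabilizing
scale for expression — keeps edge weights within one order of magnitude,
the spectral structure is then carried by process hubs rather than a
single gene, and the centrality comparison is stable. The raw-mean option
is retained for networks whose weights are already on a homogeneous
scale.

## Eigenvector centrality

Centrality is computed on the symmetrized adjacency: in a strictly
gene→BP directed graph every gene has zero in-degree and directed
eigenvector centrality is identically zero on genes, so the undirected
view is the meaningful one ("traffic" through a node). Direction is kept
in the data model and GraphML export.

The dominant eigenvector is found by power iteration on
`A/w_max + σI`, where `w_max` is the largest edge weight and `σ` the
largest row sum of the rescaled adjacency. Connected bipartite graphs
have symmetric spectra (±λ), so plain power iteration oscillates; the
diagonal shift leaves the eigenvectors unchanged while making the
eigenvalue with the largest *positive* part strictly dominant at any
weight scale. Iteration starts from the uniform vector (deterministic),
L2-normalizes each step, and stops when a geometric-series bound on the
remaining error (`resid · r/(1−r)` with `r` the step-to-step contraction)
falls below `tol` (default 1e-10, budget 20 000 iterations). The vector
is made non-negative and rescaled so the top node scores exactly 1;
*relative importance* is this score × 100, so thresholds like "below 1 %"
are relative to the most central node of that network.

Rate of change for gene g: `R = 100·(c_KO − c_WT)/c_WT`. Genes present
only in KO are flagged `novel_in_ko` (R = +∞ sentinel; they count as
complements when up-regulated), genes absent from KO are `absent_in_ko`
(R = −100). Functional complements require `R > increase_threshold`
(default 1000 %) and, by default, positive log2 fold change; reduced
importance requires KO relative importance strictly below
`reduced_threshold` (default 1 %). A gene qualifying as both is labelled
a complement (the gain is the stronger signal). Louvain clustering runs
on the same symmetrized weighted graph with a seeded node order;
modularity is Newman's weighted modularity.

## Differential expression and auxiliary statistics

Replicate abundances are tested per gene with a two-sided two-sample
Student's t test (pooled variance by default, Welch by flag; qPCR
comparisons conventionally use the Welch form). When both groups have
zero variance the statistic is undefined: equal means report (t=0, p=1)
with a `degenerate` flag rather than an error, since two-replicate
designs hit this case routinely. log2 fold change is computed on
condition means as `log2((m_KO + f)/(m_WT + f))` with the pseudo-value
`f` (default 1.0 expression unit) applied only when either mean is zero.
Selection keeps genes with raw `p < 0.05` and `|log2FC| > 2`, both
strict; no multiple-testing correction is applied by default (a
Benjamini–Hochberg column is available but does not drive selection).
ΔΔCt fold change is `2^−(ΔCt_test − ΔCt_control)` with
`ΔCt = mean Ct_target − mean Ct_reference`. TAS normalization rescales
every sample so its total protein area equals the mean of the original
per-sample totals, preserving within-sample ratios; proteins quantified
from fewer than 3 peptides are dropped before testing. Peptide arrays are
normalized against the mean of the empty control spots — subtraction
(floored at 0) by default, ratio by flag — and compared per peptide;
one-way ANOVA uses the classical F = MSB/MSW with df = (k−1, N−k).

## ITC single-site model

For injection i the displacement-corrected cell concentrations are
`M_i = M_0 (1−d)/(1+d)` and `X_i = X_syr (dV/V_0)/(1+d)` with
`d = dV/(2V_0)` and `dV = i·v_inj` — the standard perfusion-cell
bookkeeping, agreeing with the exact exponential mixing model to ~0.5 %
over a 19 × 2 µL protocol. The bound fraction Θ_i is the [0,1] root of
`Θ² − Θ(1 + X/(nM) + 1/(nK_a M)) + X/(nM) = 0`, cumulative heat
`Q_i = n Θ_i M_i V_0 ΔH` (µcal for molar concentrations, µL volumes,
kcal/mol enthalpy), and the per-injection heat is
`q_i = Q_i − Q_{i−1} + (v_inj/V_0)(Q_i + Q_{i−1})/2`. Thermogram
integration subtracts a median-outside-windows baseline and integrates
each injection window by the trapezoid rule. Fitting minimizes the SSE
between observed and modelled heats in (log10 Ka, ΔH, n) space with
`scipy.optimize.least_squares`, multi-started from a Ka × n grid
(1e3–1e8 /M × {0.5, 1, 2}) with ΔH initialized from the early-injection
heat scale; an optional flag drops the anomalous first injection.
All-flat heats are unidentifiable and returned with `converged=False`.

The default protocol mirrors the emulated assay (19 × 2 µL, 200 µM
titrant into 200 µM macromolecule; the 200 µL cell volume is a typical
value for the instrument class and configurable). That design stops near
molar ratio 0.2, so parameter-recovery *studies* use a saturating design
of the same geometry — 400 µM titrant into 20 µM macromolecule, reaching
molar ratio ≈ 3.8 — with the Wiseman parameter c = n·Ka·M_0 drawn
log-uniformly in [1, 1000] and Gaussian noise at 2 % of the largest heat.

## Synthetic data

The generator emulates a 2-condition × 3-replicate knockdown experiment.
Gene baselines are log-normal (meanlog 5, sdlog 1 — a realistic
several-orders-of-magnitude spread of normalized abundances); replicate
noise is multiplicative log-normal parameterized by a 10 % coefficient of
variation and mean-corrected. 10 % of genes are differentially expressed
at |log2FC| = 3 (half up, half down). Planted functional complements
follow the profile such candidates show in real data — the most
up-regulated genes of the experiment: near-silent in WT (0.2 normalized
units, at the detection floor) with an 84-fold KO induction
(log2FC ≈ +6.4) and a broad 5-process annotation. Annotations give every
other gene 1–4 random process memberships out of 20; the
interacting-protein table covers all processes except 4 designated ones,
giving the coverage-gap analysis a known answer. Array and ITC
generators add seeded Gaussian noise to their deterministic signals. All
generators are deterministic under (config, seed), with independent
substreams per generator so partial outputs stay consistent.

What the generator does *not* emulate: count-based sampling noise
(negative-binomial dispersion), correlated genes, annotation bias toward
highly expressed genes, batch effects, or missing values. Passing
recovery tests therefore demonstrates that the pipeline's logic and
thresholds behave as designed under the stated signal model, not that
real experiments of this size have comparable power.

## Numerical choices and limitations

- Strict inequalities at every threshold (|log2FC| > 2, p < 0.05,
  R > 1000 %, relative importance < 1 %); boundary values are excluded.
- Ties and determinism: power iteration starts from the uniform vector;
  Louvain order is driven by the passed seed; report rows are sorted by
  gene id. Reruns with the same inputs are byte-identical.
- Annotation gene ids match expression gene ids case-sensitively;
  unmatched annotation rows are dropped with a logged count. BPs compare
  by term id, with a case-folded name fallback behind a flag.
- Ontology levels count the root as level 1 (level 3 = two `is_a` steps
  below the root), configurable by filtering on the returned map.
- Disconnected networks: the power iteration converges to the dominant
  component's eigenvector; nodes of other components score ≈ 0. Exact
  eigenvalue ties between components are not resolved symmetrically —
  networks built from real annotation tables are connected in practice.
- With two technical replicates, zero-variance t tests are flagged, not
  raised; their p-value of 1 makes them conservatively non-significant.
- The >1000 % complement threshold is calibrated to max-normalized
  centralities; other normalizations rescale every R by a per-network
  constant and would need a rescaled threshold.
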