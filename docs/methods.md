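# Methods

This note records the models implemented in `gsnet`, the defaults and why
they were chosen, the numerical conventions, and what the simulation-based
tests do and do not demonstrate.

## Interaction models and statistics

All analysis runs on the largest connected component (LCC) of an undirected
simple graph; distance and diffusion quantities are not meaningful across
components, so the LCC restriction is enforced rather than silently patched
(disconnected input to the matrix builders raises). Ties between equally
large components are broken toward the component containing the
lexicographically smallest node id, and the node ordering of all matrices is
frozen as the sorted node ids, so persisted matrices and bootstrap draws are
reproducible byte-for-byte.

Three pairwise interaction structures are used:

* **Direct** — the adjacency matrix itself. Degree statistics (`T_TD`,
  `T_ID`) and the induced-module size `T_M` need nothing else.
* **Shortest path** — all-pairs unweighted BFS distances, stored as `int16`.
* **Random walk with restart** — `H = β (I − (1−β) Ā)⁻¹` with
  `Ā = A D⁻¹` normalized by *column*; each column of `H` then sums to one,
  i.e. the unit of heat injected at a node is conserved, which is the
  property the test suite checks to 1e-9. The default restart probability is
  `β = 0.85`, the conventional choice for propagation on biological
  networks; diagonal entries of `H` grow monotonically with `β` and
  `H → I` as `β → 1`.

Two conventions deserve note. The shortest-path statistic `T_SP` excludes
the self-distance: the minimum runs over the *other* members of the geneset
(the literal formula including `j = i` would be identically zero). The heat
statistics sum over ordered pairs, so `h_ij` and `h_ji` both contribute; in
the association statistic `U_H` a gene present in both sets additionally
contributes its withheld heat `h_ii`, which makes identical genesets
maximally associated and matches the cross-minimum convention in `U_SP`
(a shared gene has cross-distance zero).

Matrices are dense float64/int16; at 20k nodes a heat matrix costs ~3.2 GB,
which is the practical ceiling for this implementation (sparse or iterative
RWR solvers are deliberately out of scope). Both matrices persist to one
HDF5 container together with the node order and `β`; loading verifies the
node order against the network it will be used with.

## Hypothesis testing

Null distributions are bootstrap estimates conditioned on geneset size:
`n_samples` random node sets of the observed size are drawn and the
statistic recomputed. The default is 500 samples (stable in practice);
benchmark runs use 200 to keep grids affordable. The empirical p-value uses
a unit pseudo-count, `p = (#{Q_i ≥ q̄} + 1)/(|Q| + 1)`, so `p` is bounded
below by `1/(n_samples+1)` and never zero. Tail direction is fixed per
statistic: lower for `T_SP`/`U_SP` (small distance = cohesive/close), upper
for everything else. For two-set tests the null either resamples both sets
(`both_random`) or keeps the first fixed (`fix_first`); the latter is more
conservative and is recommended when the first set is a curated pathway.

Two samplers generate null node sets. `uniform` draws without replacement.
`degree_matched` draws, for each tested gene, a node from the same
logarithmic degree class (`⌊log2 deg⌋`); a class short of candidates is
widened once to its two neighbours before failing. Logarithmic bins were
chosen because biological degree distributions are heavy-tailed: linear bins
would leave hub bins empty, and exact degree matching is usually infeasible
without replacement.

Reproducibility contract: the random substream of bootstrap sample `i` is
derived from `(seed, i)` alone, so results are bit-identical whatever the
worker count; with one core no process pool is created. Result CSVs contain
no timestamps.

## Benchmark generators

The generators *are* the study conditions; their defaults encode the
benchmark protocol and are not tuned per run.

**SBM topology benchmark.** `n = 1000` nodes, `k = 7` blocks of 100 genes
over a background block, baseline edge probability `p0 = 0.01`; the first
`⌊k/2⌋ = 3` blocks get within-block probability `α·p0` (positives), the
remaining 4 stay at baseline (negatives). `α` ranges over {2, 3, 5, 10} in
the full grid; the headline runs use {5, 10}. Block membership is the
geneset.

**SBM association benchmark.** Eight 50-gene blocks, all with within-block
probability `α·p0` (`α = 5`), linked in disjoint pairs: (0,1) and (2,3) get
between-block probability `p0(1 + β(α−1))` with `β = 10` (positives), (4,5)
and (6,7) stay at baseline, `β = 0` (negatives). Disjoint pairs keep the
positive and negative pairs independent. For each pair `(i, j)` the tested
genesets are block `i` and a mixture of `π·m` genes from `i` plus the rest
from `j` (`π ∈ {0.04, 0.12}`: 2 or 6 shared genes out of 50). Fractional
counts round half away from zero with a logged warning.

**HDN robustness benchmark.** Networks plant `n_hd = 30` hubs whose edge
probability `p_hd` to any node exceeds the baseline `p0`; the grid crosses
`p0 ∈ {0.006, 0.02}` with `p_hd ∈ {0.01, 0.05, 0.08, 0.1, 0.2, 0.5}`
(combinations with `p_hd ≤ p0` are invalid and skipped). Extended genesets
mix `π_hd·n_hd` hubs with `ρ·π_hd·n_hd` random non-hub nodes
(`π_hd ∈ {0.1, 0.2, 0.5}`, `ρ ∈ {2, 3, 4}`, three genesets per
combination). These sets have no planted module, so every rejection is a
false positive — except that strong hubs can make a random mixture a *real*
connected module; genesets whose induced-subgraph LCC holds more than 75%
of their genes are therefore discarded before testing (the boundary itself
is kept).

*Null protocol on hub networks.* The degree statistics `T_TD` and `T_ID`
are tested against the degree-matched null in this benchmark, the distance
and diffusion statistics against the uniform null. On hub networks the
degree statistics are driven by node degree alone — a uniform null measures
"contains hubs", which is true by construction, not a false positive in any
informative sense, and would saturate `T_TD` rejections. The degree-matched
null conditions that confounder away and is exactly the remedy the sampler
exists for; the hub-induced inflation of the shortest-path and heat tests is
the phenomenon this benchmark is meant to expose, so those keep the uniform
null. The choice is exposed as a parameter (`degree_stat_sampler`). The SBM
benchmarks use the uniform null throughout.

**Evaluation.** TPR is the fraction of positive-labeled tests with
`p < 0.05`, FPR the same among negatives; the threshold is explicit and
configurable. Replication defaults are desk-scale: 3 networks per setting
(the original protocol used 10) and 200 bootstrap samples; rates are
reported pooled over networks. `scripts/acceptance.py` reports worst-case
summaries — the minimum TPR among the three well-powered topology tests,
maxima of FPR over statistics or grid conditions — with configurations
required to retain at least 5 filtered genesets before their FPR counts
toward a maximum (smaller denominators make a maximum meaningless).

## What the simulations do and do not show

SBM and HDN networks are exchangeable within blocks, have Poisson-like
degrees within a role, and carry no edge weights, directions, annotation
bias or missing-link structure. Passing benchmarks therefore demonstrates
the *statistical machinery* — power against planted structure, calibration
under the null, robustness or sensitivity to degree confounding — not
performance on any particular curated interactome, where literature bias
and incomplete coverage dominate. Calibration checks use homogeneous
networks (`α = 1` reduces the SBM to a single edge probability) with a
fresh network per replicate, since rejection events on a shared network are
correlated and would defeat the binomial error bands.

## Known limitations

* Undirected, unweighted networks only; no sparse solvers, so ~20k nodes is
  the practical ceiling for the RWR matrix.
* The bootstrap conditions on geneset size, not composition; heavily
  annotated (high-degree) genesets should be interpreted against the
  degree-matched null.
* `U_H` is sensitive to overlap by construction: pairs sharing more than
  ~10% of their genes are flagged regardless of inter-connectivity, which
  is visible in the association benchmark at 12% overlap.
* Empirical p-values are bounded below by `1/(n_samples+1)`; multiple-test
  correction over many genesets needs `n_samples` well above the number of
  tests for BH to resolve small adjusted values.
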