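# gsnet — statistical geneset network analysis

High-throughput experiments produce lists of genes; most biological function
lives in the *interactions* between them. `gsnet` tests whether a geneset is
more tightly wired on an interaction network than chance predicts — a
**geneset network topology (GNT)** test — and whether two genesets interact
with each other more than chance predicts — a **geneset network association
(GNA)** test. It is aimed at people doing downstream analysis of
differential-expression or screening results against a protein–protein
interaction network, and at method developers who need a controlled
simulation bench for network statistics.

## Statistics

Let `G = (V, E)` be the largest connected component of an undirected
interaction network with adjacency `A` and degrees `deg(i)`, and let
`S` be a geneset mapped onto `V` with `n = |S|`. Three interaction models
feed five topology statistics and two association statistics:

* direct interactions: `T_TD = (1/n) Σ_{i∈S} deg(i)`,
  `T_ID = (1/n) Σ_{i∈S} deg(i,S)/deg(i)` (where `deg(i,S)` counts edges from
  `i` into `S`), and the module statistic `T_M`, the size of the largest
  connected component of the subgraph induced by `S`;
* shortest paths: `T_SP = (1/n) Σ_{i∈S} min_{j∈S, j≠i} s_ij` with `s_ij` the
  unweighted shortest-path length;
* random walk with restart (RWR): heat `H = β (I − (1−β) A D⁻¹)⁻¹` with
  restart probability `β = 0.85`, and `T_H = Σ_{i,j∈S, i≠j} h_ij`.

For two genesets `S1, S2` (sizes `n, m`):

* `U_SP = (1/(n+m)) [Σ_{i∈S1} min_{j∈S2} s_ij + Σ_{j∈S2} min_{i∈S1} s_ij]
  − (T_SP(S1) + T_SP(S2))/2` (negative = the sets are close);
* `U_H = Σ_{i∈S1, j∈S2} (h_ij + h_ji)`, counting withheld heat `h_ii` for
  genes in the overlap.

Significance comes from a bootstrap null conditioned on geneset size:
statistics are recomputed on random node sets and the empirical p-value is
`(#{Q_i ≥ q̄} + 1)/(|Q| + 1)` (lower-tail analogue for distance statistics).
Node sets are drawn uniformly or matched to the tested set's `log2` degree
bins. A stochastic-block-model (SBM) and a high-degree-node (HDN) simulator
generate benchmark networks with planted modules, linked block pairs, or
hubs, to measure each test's true and false positive rates.

## Worked example

Generate one benchmark network (1000 nodes, seven 100-gene blocks over a
baseline edge probability of 0.01, three blocks densified fivefold), then run
the heat topology test on a planted block and on a baseline block:

```python
from gsnet import (gnt_benchmark, largest_connected_component, build_matrices,
                   map_geneset, gnt_test)

ds = gnt_benchmark(n_nodes=1000, k=7, block_size=100, p0=0.01, alpha=5.0,
                   n_networks=1, seed=42)[0]
net = largest_connected_component(ds.network)
matrices = build_matrices(net)              # shortest paths + RWR heat, beta = 0.85

for name in ("net0_block0", "net0_block5"):  # a planted block and a baseline block
    S = map_geneset(ds.genesets[name], net, name)
    res = gnt_test(S, "heat", net=net, matrices=matrices,
                   n_samples=500, seed=1)
    print(f"{name}: T_H = {res.observed:.3f}  null = {res.null.mean:.3f} "
          f"+/- {res.null.sd:.3f}  p = {res.pvalue:.4g}")
```

```
net0_block0: T_H = 5.189  null = 1.471 +/- 0.155  p = 0.001996
net0_block5: T_H = 1.414  null = 1.471 +/- 0.155  p = 0.6248
```

The planted block exchanges 3.5× the heat of a random 100-gene set; its
p-value of 1/501 ≈ 0.002 is the floor of a 500-sample bootstrap, meaning no
null draw reached the observed value. The baseline block sits in the middle
of its null and is correctly not called.

The same pipeline is available from the shell:

```bash
gsnet build-matrices --network net.tsv --out net.h5
gsnet test-topology-heat --network net.tsv --geneset sets.gmt \
      --matrices net.h5 --n-samples 500 --seed 1 --out results.csv
```

Networks are two-column TSV edge lists, genesets are GMT or plain-text
files, interaction matrices persist to a single HDF5 container, and all
results are CSV. `gsnet --help` lists the simulation (`generate-*`) and
benchmark (`benchmark-*`) commands.

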