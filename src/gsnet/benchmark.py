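"""Benchmark harness: run tests over simulated datasets, tabulate TPR/FPR.

The harness connects the simulators to the test machinery: it extracts the
LCC of each generated network, precomputes interaction matrices when a
requested statistic needs them, runs the bootstrap tests with per-test seeds
derived deterministically from one base seed, and reduces labeled p-values to
true/false positive rates at a significance threshold.
"""

from __future__ import annotations

from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .gnt import DIRECT_STATISTICS, GNT_STATISTICS
from .inference import gna_test, gnt_test
from .netcore import build_matrices, largest_connected_component, map_geneset
from .simulate import (
    GnaBenchmarkDataset,
    GntBenchmarkDataset,
    HdnSpec,
    _child_seed,
    extended_geneset,
    generate_hdn_network,
    gna_benchmark,
    gnt_benchmark,
    lcc_filter,
)

DEFAULT_THRESHOLD = 0.05


def _needs_matrices(statistics: Sequence[str]) -> bool:
    return any(s not in DIRECT_STATISTICS for s in statistics)


def run_gnt_dataset(
    ds: GntBenchmarkDataset,
    statistics: Sequence[str] = GNT_STATISTICS,
    n_samples: int = 200,
    sampler: str = "uniform",
    seed: int = 0,
    cores: int = 1,
) -> pd.DataFrame:
    """Run topology tests over every geneset of one benchmark dataset."""
    net = largest_connected_component(ds.network)
    matrices = build_matrices(net) if _needs_matrices(statistics) else None
    rows = []
    for g_idx, (name, genes) in enumerate(sorted(ds.genesets.items())):
        S = map_geneset(genes, net, name)
        for s_idx, stat in enumerate(statistics):
            res = gnt_test(
                S, stat, net=net, matrices=matrices, n_samples=n_samples,
                sampler=sampler, seed=_child_seed(seed, g_idx, s_idx), cores=cores,
            )
            row = res.to_row()
            row["label"] = ds.labels[name]
            row.update(ds.params)
            rows.append(row)
    return pd.DataFrame(rows)


def run_gna_dataset(
    ds: GnaBenchmarkDataset,
    statistics: Sequence[str] = ("association_heat", "association_shortest_path"),
    n_samples: int = 200,
    mode: str = "both_random",
    seed: int = 0,
    cores: int = 1,
) -> pd.DataFrame:
    """Run association tests over every labeled pair of one dataset."""
    net = largest_connected_component(ds.network)
    matrices = build_matrices(net)
    rows = []
    for p_idx, pair in enumerate(ds.pairs):
        S1 = map_geneset(pair.genes_a, net, pair.name_a)
        S2 = map_geneset(pair.genes_b, net, pair.name_b)
        for s_idx, stat in enumerate(statistics):
            res = gna_test(
                S1, S2, stat, matrices, n_samples=n_samples, mode=mode,
                seed=_child_seed(seed, p_idx, s_idx), cores=cores,
            )
            row = res.to_row()
            row["label"] = pair.label
            row.update(ds.params)
            rows.append(row)
    return pd.DataFrame(rows)


def evaluate_benchmark(
    results: pd.DataFrame,
    group_cols: Sequence[str] = ("statistic",),
    threshold: float = DEFAULT_THRESHOLD,
    strict: bool = True,
) -> pd.DataFrame:
    """Reduce labeled test results to TPR/FPR per group.

    TPR is the fraction of positive-labeled tests with p < threshold, FPR the
    same fraction among negative-labeled tests. With ``strict`` (default) a
    group missing one class raises; one-sided benchmarks (e.g. the HDN false
    positive probe, which has no positives) pass ``strict=False`` and get NaN
    for the missing rate.
    """
    required = {"label", "pvalue"} | set(group_cols)
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table is missing columns: {sorted(missing)}")
    out = []
    for key, grp in results.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        pos = grp[grp["label"] == "positive"]
        neg = grp[grp["label"] == "negative"]
        if strict and (len(pos) == 0 or len(neg) == 0):
            absent = "positive" if len(pos) == 0 else "negative"
            raise ValueError(
                f"group {dict(zip(group_cols, key))}: no {absent}-labeled results"
            )
        rec = dict(zip(group_cols, key))
        rec["tpr"] = float((pos["pvalue"] < threshold).mean()) if len(pos) else np.nan
        rec["fpr"] = float((neg["pvalue"] < threshold).mean()) if len(neg) else np.nan
        rec["n_positive"] = len(pos)
        rec["n_negative"] = len(neg)
        rec["threshold"] = threshold
        out.append(rec)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# full benchmark grids


def gnt_sbm_benchmark(
    alphas: Sequence[float] = (5.0, 10.0),
    n_nodes: int = 1000,
    k: int = 7,
    block_size: int = 100,
    p0: float = 0.01,
    n_networks: int = 3,
    statistics: Sequence[str] = GNT_STATISTICS,
    n_samples: int = 200,
    seed: int = 0,
    cores: int = 1,
) -> pd.DataFrame:
    """Topology benchmark over the SBM grid; returns one row per test."""
    frames = []
    for a_idx, alpha in enumerate(alphas):
        datasets = gnt_benchmark(
            n_nodes=n_nodes, k=k, block_size=block_size, p0=p0, alpha=alpha,
            n_networks=n_networks, seed=_child_seed(seed, a_idx),
        )
        for d_idx, ds in enumerate(datasets):
            frames.append(
                run_gnt_dataset(
                    ds, statistics=statistics, n_samples=n_samples,
                    seed=_child_seed(seed, a_idx, d_idx, 7), cores=cores,
                )
            )
    return pd.concat(frames, ignore_index=True)


def gna_sbm_benchmark(
    pis: Sequence[float] = (0.04, 0.12),
    n_nodes: int = 1000,
    block_size: int = 50,
    p0: float = 0.01,
    alpha: float = 5.0,
    beta_mix: float = 10.0,
    n_networks: int = 3,
    statistics: Sequence[str] = ("association_heat", "association_shortest_path"),
    n_samples: int = 200,
    mode: str = "both_random",
    seed: int = 0,
    cores: int = 1,
) -> pd.DataFrame:
    """Association benchmark over the SBM grid; returns one row per test."""
    frames = []
    for p_idx, pi in enumerate(pis):
        datasets = gna_benchmark(
            n_nodes=n_nodes, block_size=block_size, p0=p0, alpha=alpha,
            beta_mix=beta_mix, pi=pi, n_networks=n_networks,
            seed=_child_seed(seed, p_idx),
        )
        for d_idx, ds in enumerate(datasets):
            frame = run_gna_dataset(
                ds, statistics=statistics, n_samples=n_samples, mode=mode,
                seed=_child_seed(seed, p_idx, d_idx, 7), cores=cores,
            )
            frame["pi"] = pi
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def hdn_benchmark(
    p0s: Sequence[float] = (0.006, 0.02),
    p_hds: Sequence[float] = (0.01, 0.05, 0.08, 0.1, 0.2, 0.5),
    n_nodes: int = 1000,
    n_hd: int = 30,
    pi_hds: Sequence[float] = (0.1, 0.2, 0.5),
    rhos: Sequence[float] = (2.0, 3.0, 4.0),
    n_genesets: int = 3,
    n_networks: int = 3,
    statistics: Sequence[str] = ("internal_degree", "shortest_path", "heat"),
    n_samples: int = 200,
    seed: int = 0,
    cores: int = 1,
    max_lcc_fraction: float = 0.75,
    degree_stat_sampler: str = "degree_matched",
) -> pd.DataFrame:
    """False-positive benchmark on hub networks with extended genesets.

    Every geneset is a hub/non-hub mixture with no planted module, labeled
    negative; genesets whose induced LCC exceeds ``max_lcc_fraction`` of
    their genes are discarded before testing. Grid points with
    ``p_hd <= p0`` are skipped (the hub model requires p_hd > p0).

    Purely degree-driven statistics (``total_degree``, ``internal_degree``)
    are tested against the ``degree_stat_sampler`` null (degree-matched by
    default): on hub networks their observed values are driven by node
    degree alone, which is exactly the confounder the degree-matched sampler
    conditions away. Distance and diffusion statistics keep the uniform
    null, so their hub-induced false positive rates remain visible.
    """
    frames = []
    combos = [(p0, p_hd) for p0, p_hd in product(p0s, p_hds) if p_hd > p0]
    for c_idx, (p0, p_hd) in enumerate(combos):
        for net_id in range(n_networks):
            net_seed = _child_seed(seed, c_idx, net_id)
            spec = HdnSpec(n_nodes, n_hd, p0, p_hd, seed=net_seed)
            network, hubs = generate_hdn_network(spec)
            net = largest_connected_component(network)
            matrices = build_matrices(net) if _needs_matrices(statistics) else None
            genesets = []
            for g_idx, (pi_hd, rho, rep) in enumerate(
                product(pi_hds, rhos, range(n_genesets))
            ):
                rng = np.random.default_rng(_child_seed(seed, c_idx, net_id, g_idx, 3))
                gspec = HdnSpec(n_nodes, n_hd, p0, p_hd, pi_hd=pi_hd, rho=rho)
                genes = extended_geneset(gspec, network, hubs, rng)
                genesets.append((f"ext_{g_idx}", genes, pi_hd, rho))
            kept = lcc_filter(
                [(name, genes) for name, genes, _, _ in genesets],
                network, max_fraction=max_lcc_fraction,
            )
            kept_names = {name for name, _ in kept}
            rows = []
            for g_idx, (name, genes, pi_hd, rho) in enumerate(genesets):
                if name not in kept_names:
                    continue
                S = map_geneset(genes, net, name)
                n_hubs = len(set(genes) & set(hubs))
                for s_idx, stat in enumerate(statistics):
                    sampler = (
                        degree_stat_sampler
                        if stat in ("total_degree", "internal_degree")
                        else "uniform"
                    )
                    res = gnt_test(
                        S, stat, net=net, matrices=matrices, n_samples=n_samples,
                        sampler=sampler,
                        seed=_child_seed(seed, c_idx, net_id, g_idx, s_idx, 11),
                        cores=cores,
                    )
                    row = res.to_row()
                    row.update(
                        label="negative", p0=p0, p_hd=p_hd, n_hd=n_hd,
                        pi_hd=pi_hd, rho=rho, n_hubs=n_hubs, network=net_id,
                    )
                    rows.append(row)
            if rows:
                frames.append(pd.DataFrame(rows))
    if not frames:
        raise ValueError("no genesets survived the LCC filter anywhere on the grid")
    return pd.concat(frames, ignore_index=True)
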