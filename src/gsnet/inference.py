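"""Bootstrap hypothesis testing for GNT and GNA statistics.

Closed-form null distributions are unavailable for these statistics on
arbitrary networks, so significance is assessed against an empirical null:
the statistic is recomputed on randomly sampled node sets of the same size(s)
as the tested geneset(s), and the p-value is the pseudo-count-corrected tail
fraction

    P = (#{Q_i >= q_obs} + 1) / (|Q| + 1)        (upper tail)

(with ``<=`` for the lower tail). Around 500 bootstrap samples give a stable
null; the default is configurable per call.

Two node samplers are provided: ``uniform`` (nodes drawn uniformly without
replacement) and ``degree_matched`` (each sampled node drawn from the same
logarithmic degree bin, floor(log2(deg)), as the corresponding geneset gene —
useful for degree-driven statistics).

Reproducibility contract: the random substream of bootstrap sample *i* is
derived from the base seed and *i* alone (counter-based), so results are
bit-identical regardless of how samples are distributed over worker
processes. With ``cores=1`` no process pool is created.
"""

from __future__ import annotations

import multiprocessing
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from . import gna, gnt
from .netcore import Geneset, InteractionMatrices, Network

DEFAULT_N_SAMPLES = 500

#: direction of the alternative per statistic: cohesive/associated genesets
#: have *small* shortest-path statistics and *large* everything else.
TAILS = {
    "total_degree": "upper",
    "internal_degree": "upper",
    "module": "upper",
    "heat": "upper",
    "shortest_path": "lower",
    "association_heat": "upper",
    "association_shortest_path": "lower",
}

SAMPLERS = ("uniform", "degree_matched")


@dataclass
class NullDistribution:
    """Bootstrap null of one statistic, conditioned on geneset size(s)."""

    values: np.ndarray
    sampler: str
    conditioned_on: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.size > 1 else 0.0


@dataclass
class TestResult:
    """Outcome of one GNT or GNA bootstrap test."""

    geneset: str
    geneset_b: str | None
    statistic: str
    observed: float
    n_mapped: int
    m_mapped: int | None
    null: NullDistribution = field(repr=False)
    pvalue: float = 0.0
    tail: str = "upper"
    n_samples: int = 0
    sampler: str = "uniform"
    mode: str | None = None
    seed: int = 0

    def to_row(self) -> dict:
        """Flatten into a CSV-ready record."""
        return {
            "geneset": self.geneset,
            "geneset_b": "" if self.geneset_b is None else self.geneset_b,
            "statistic": self.statistic,
            "observed": self.observed,
            "n_mapped": self.n_mapped,
            "m_mapped": "" if self.m_mapped is None else self.m_mapped,
            "null_mean": self.null.mean,
            "null_sd": self.null.sd,
            "pvalue": self.pvalue,
            "tail": self.tail,
            "n_samples": self.n_samples,
            "sampler": self.sampler,
            "mode": "" if self.mode is None else self.mode,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# empirical p-values


def empirical_pvalue(observed: float, Q: np.ndarray, tail: str = "upper") -> float:
    """Pseudo-count-corrected empirical p-value of ``observed`` against ``Q``."""
    Q = np.asarray(Q, dtype=np.float64)
    if Q.size == 0:
        raise ValueError("null distribution is empty")
    if tail == "upper":
        hits = int(np.count_nonzero(Q >= observed))
    elif tail == "lower":
        hits = int(np.count_nonzero(Q <= observed))
    else:
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    return (hits + 1) / (Q.size + 1)


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg FDR adjustment."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# samplers


def _rng_for(seed: int, index: int) -> np.random.Generator:
    # substream keyed by the sample index, not the worker: parallel-invariant
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),)))


def sample_uniform(net_nodes, size: int, rng: np.random.Generator) -> set[str]:
    """Sample ``size`` distinct nodes uniformly at random."""
    nodes = list(net_nodes)
    if size > len(nodes):
        raise ValueError(f"cannot sample {size} nodes from {len(nodes)}")
    idx = rng.choice(len(nodes), size=size, replace=False)
    return {nodes[i] for i in idx}


def degree_bins(degrees: np.ndarray) -> np.ndarray:
    """Logarithmic degree classes: floor(log2(deg)) per node."""
    return np.floor(np.log2(np.maximum(degrees, 1))).astype(np.int64)


def _sample_degree_matched_idx(
    rng: np.random.Generator, node_bins: np.ndarray, ref_bins: np.ndarray
) -> np.ndarray:
    """Sample node indices matching ``ref_bins`` bin-for-bin, without replacement.

    A bin short on candidates is widened once to its two neighboring bins; if
    still short, sampling fails.
    """
    taken = np.zeros(node_bins.shape[0], dtype=bool)
    chosen: list[np.ndarray] = []
    bins, counts = np.unique(ref_bins, return_counts=True)
    for b, count in zip(bins, counts):
        cands = np.nonzero((node_bins == b) & ~taken)[0]
        if cands.size < count:
            cands = np.nonzero((np.abs(node_bins - b) <= 1) & ~taken)[0]
        if cands.size < count:
            raise ValueError(
                f"degree bin {b} (widened) has {cands.size} free candidate "
                f"nodes but {count} are required"
            )
        sel = rng.choice(cands, size=int(count), replace=False)
        taken[sel] = True
        chosen.append(sel)
    return np.sort(np.concatenate(chosen))


def sample_degree_matched(
    net: Network, reference: Geneset, rng: np.random.Generator
) -> set[str]:
    """Sample a node set matching the degree-bin profile of ``reference``."""
    if reference.n_mapped < 1:
        raise ValueError("reference geneset has no mapped genes")
    node_bins = degree_bins(net.degrees)
    ref_idx = np.array([net.node_index[g] for g in reference.mapped])
    idx = _sample_degree_matched_idx(rng, node_bins, node_bins[ref_idx])
    return {net.nodes[i] for i in idx}


# ---------------------------------------------------------------------------
# bootstrap jobs (picklable: evaluated in worker processes when cores > 1)


_KERNEL_ARRAYS = {
    "total_degree": ("degrees",),
    "internal_degree": ("adjacency", "degrees"),
    "module": ("adjacency",),
    "shortest_path": ("sp",),
    "heat": ("heat",),
    "association_shortest_path": ("sp",),
    "association_heat": ("heat",),
}


def _eval_gnt(statistic: str, idx: np.ndarray, arrays: dict) -> float:
    if statistic == "total_degree":
        return gnt._total_degree(idx, arrays["degrees"])
    if statistic == "internal_degree":
        return gnt._internal_degree(idx, arrays["adjacency"], arrays["degrees"])
    if statistic == "module":
        return gnt._module(idx, arrays["adjacency"])
    if statistic == "shortest_path":
        return gnt._shortest_path(idx, arrays["sp"])
    if statistic == "heat":
        return gnt._heat(idx, arrays["heat"])
    raise ValueError(f"unknown GNT statistic {statistic!r}")


def _eval_gna(statistic: str, idx1: np.ndarray, idx2: np.ndarray, arrays: dict) -> float:
    if statistic == "association_shortest_path":
        return gna._association_sp(idx1, idx2, arrays["sp"])
    if statistic == "association_heat":
        return gna._association_heat(idx1, idx2, arrays["heat"])
    raise ValueError(f"unknown GNA statistic {statistic!r}")


class _GntNullJob:
    def __init__(self, statistic, size, seed, arrays, n_nodes, node_bins, ref_bins):
        self.statistic = statistic
        self.size = size
        self.seed = seed
        self.arrays = arrays
        self.n_nodes = n_nodes
        self.node_bins = node_bins  # None for the uniform sampler
        self.ref_bins = ref_bins

    def _sample(self, rng: np.random.Generator) -> np.ndarray:
        if self.node_bins is None:
            return rng.choice(self.n_nodes, size=self.size, replace=False)
        return _sample_degree_matched_idx(rng, self.node_bins, self.ref_bins)

    def __call__(self, i: int) -> float:
        rng = _rng_for(self.seed, i)
        return _eval_gnt(self.statistic, self._sample(rng), self.arrays)


class _GnaNullJob:
    def __init__(self, statistic, n, m, seed, arrays, n_nodes, fixed_idx1):
        self.statistic = statistic
        self.n = n
        self.m = m
        self.seed = seed
        self.arrays = arrays
        self.n_nodes = n_nodes
        self.fixed_idx1 = fixed_idx1  # None in both_random mode

    def __call__(self, i: int) -> float:
        rng = _rng_for(self.seed, i)
        if self.fixed_idx1 is None:
            idx1 = rng.choice(self.n_nodes, size=self.n, replace=False)
        else:
            idx1 = self.fixed_idx1
        idx2 = rng.choice(self.n_nodes, size=self.m, replace=False)
        return _eval_gna(self.statistic, idx1, idx2, self.arrays)


def _run_bootstrap(job, n_samples: int, cores: int) -> np.ndarray:
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if cores <= 1:
        values = [job(i) for i in range(n_samples)]
    else:
        chunk = max(1, -(-n_samples // (cores * 4)))
        with multiprocessing.Pool(cores) as pool:
            values = pool.map(job, range(n_samples), chunksize=chunk)
    return np.asarray(values, dtype=np.float64)


# ---------------------------------------------------------------------------
# test orchestration


def _context_arrays(
    statistic: str, net: Network | None, matrices: InteractionMatrices | None
) -> tuple[dict, tuple[str, ...]]:
    """Collect the arrays a statistic needs and the node order they follow."""
    needed = _KERNEL_ARRAYS[statistic]
    arrays: dict[str, np.ndarray] = {}
    if "adjacency" in needed or "degrees" in needed:
        if net is None:
            raise ValueError(f"{statistic} requires the network")
        arrays["adjacency"] = net.adjacency
        arrays["degrees"] = net.degrees
        order = net.nodes
    if "sp" in needed or "heat" in needed:
        if matrices is None:
            raise ValueError(f"{statistic} requires precomputed interaction matrices")
        key = "sp" if "sp" in needed else "heat"
        if getattr(matrices, key) is None:
            raise ValueError(f"interaction matrices have no {key!r} matrix")
        arrays[key] = getattr(matrices, key)
        order = matrices.node_order
        if net is not None and tuple(net.nodes) != tuple(order):
            raise ValueError("network and interaction matrices disagree on node order")
    return arrays, tuple(order)


def gnt_test(
    S: Geneset,
    statistic: str,
    net: Network | None = None,
    matrices: InteractionMatrices | None = None,
    n_samples: int = DEFAULT_N_SAMPLES,
    sampler: str = "uniform",
    seed: int = 0,
    cores: int = 1,
) -> TestResult:
    """Bootstrap test of one topology statistic for one geneset.

    The null is built from ``n_samples`` random node sets of size
    ``S.n_mapped`` drawn by ``sampler``; the tail is lower for
    ``shortest_path`` and upper otherwise.
    """
    if statistic not in gnt.GNT_STATISTICS:
        raise ValueError(f"unknown GNT statistic {statistic!r}")
    if sampler not in SAMPLERS:
        raise ValueError(f"unknown sampler {sampler!r}")
    arrays, order = _context_arrays(statistic, net, matrices)
    index = {v: i for i, v in enumerate(order)}
    idx = gnt._indices(S, index)
    observed = _eval_gnt(statistic, idx, arrays)

    node_bins = ref_bins = None
    if sampler == "degree_matched":
        if net is None:
            raise ValueError("the degree_matched sampler requires the network")
        node_bins = degree_bins(net.degrees)
        ref_bins = node_bins[idx]
    job = _GntNullJob(statistic, len(idx), seed, arrays, len(order), node_bins, ref_bins)
    Q = _run_bootstrap(job, n_samples, cores)
    tail = TAILS[statistic]
    null = NullDistribution(Q, sampler, (len(idx),))
    return TestResult(
        geneset=S.name, geneset_b=None, statistic=statistic,
        observed=observed, n_mapped=len(idx), m_mapped=None,
        null=null, pvalue=empirical_pvalue(observed, Q, tail), tail=tail,
        n_samples=n_samples, sampler=sampler, mode=None, seed=seed,
    )


def gna_test(
    S1: Geneset,
    S2: Geneset,
    statistic: str,
    matrices: InteractionMatrices,
    n_samples: int = DEFAULT_N_SAMPLES,
    mode: str = "both_random",
    seed: int = 0,
    cores: int = 1,
) -> TestResult:
    """Bootstrap test of one association statistic for a geneset pair.

    ``both_random`` resamples both sets at their observed sizes each draw;
    ``fix_first`` keeps S1 fixed and resamples only S2 (more conservative,
    recommended when S1 is a curated pathway).
    """
    if statistic == "association_sp":
        statistic = "association_shortest_path"
    if statistic not in gna.GNA_STATISTICS:
        raise ValueError(f"unknown GNA statistic {statistic!r}")
    if mode not in ("both_random", "fix_first"):
        raise ValueError(f"mode must be 'both_random' or 'fix_first', got {mode!r}")
    arrays, order = _context_arrays(statistic, None, matrices)
    index = {v: i for i, v in enumerate(order)}
    minimum = 2 if statistic == "association_shortest_path" else 1
    gnt._require(S1, minimum)
    gnt._require(S2, minimum)
    idx1 = gnt._indices(S1, index)
    idx2 = gnt._indices(S2, index)
    observed = _eval_gna(statistic, idx1, idx2, arrays)

    fixed = idx1 if mode == "fix_first" else None
    job = _GnaNullJob(statistic, len(idx1), len(idx2), seed, arrays, len(order), fixed)
    Q = _run_bootstrap(job, n_samples, cores)
    tail = TAILS[statistic]
    null = NullDistribution(Q, "uniform", (len(idx1), len(idx2)))
    return TestResult(
        geneset=S1.name, geneset_b=S2.name, statistic=statistic,
        observed=observed, n_mapped=len(idx1), m_mapped=len(idx2),
        null=null, pvalue=empirical_pvalue(observed, Q, tail), tail=tail,
        n_samples=n_samples, sampler="uniform", mode=mode, seed=seed,
    )
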