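"""Synthetic benchmark generators: SBM and high-degree-node (HDN) networks.

Stochastic block models (SBM) generate networks with planted structure under
full experimental control: edge probability between two nodes depends only on
their block memberships, so planting a dense block creates a geneset with a
true network effect (for topology tests), and linking two blocks creates a
pair of truly associated genesets (for association tests).

The HDN model instead plants hubs — nodes whose connection probability
``p_hd`` to every other node exceeds the baseline ``p0`` — and builds
"extended" genesets mixing a few hubs with random nodes. These genesets have
no planted module, so any rejection is a false positive: the model probes
robustness of the tests to degree confounding.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .netcore import Network

logger = logging.getLogger(__name__)


def _round_half_away(x: float) -> int:
    """Round half away from zero (used for fractional node counts)."""
    r = int(math.floor(abs(x) + 0.5))
    if abs(x - round(x)) > 1e-12:
        logger.warning("fractional node count %.4g rounded to %d", x, r)
    return r if x >= 0 else -r


def _node_names(n: int) -> list[str]:
    width = len(str(max(n - 1, 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# specs


@dataclass
class SbmSpec:
    """A stochastic block model: explicit block sizes and probability matrix.

    ``block_sizes`` must sum to at most ``n_nodes``; leftover nodes form a
    trailing background block whose row/column in ``M`` must be included
    (i.e. ``M`` is (k+1)x(k+1) when a background block exists, kxk otherwise).
    """

    n_nodes: int
    block_sizes: Sequence[int]
    M: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.float64)
        sizes = list(self.block_sizes)
        rest = self.n_nodes - sum(sizes)
        if rest < 0:
            raise ValueError("block sizes exceed the number of nodes")
        self.all_sizes = sizes + ([rest] if rest > 0 else [])
        k = len(self.all_sizes)
        if self.M.shape != (k, k):
            raise ValueError(
                f"M must be {k}x{k} (labeled blocks plus background), "
                f"got {self.M.shape}"
            )
        if not np.allclose(self.M, self.M.T):
            raise ValueError("M must be symmetric")
        if (self.M < 0).any() or (self.M > 1).any():
            raise ValueError("all entries of M must lie in [0, 1]")


@dataclass
class HdnSpec:
    """Parameters of the high-degree-node benchmark model."""

    n_nodes: int
    n_hd: int
    p0: float
    p_hd: float
    pi_hd: float = 0.1
    rho: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0 or not 0.0 <= self.p_hd <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.p_hd <= self.p0:
            raise ValueError("p_hd must exceed the baseline probability p0")
        if not 0.0 < self.pi_hd <= 1.0:
            raise ValueError("pi_hd must lie in (0, 1]")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if self.n_hd > self.n_nodes:
            raise ValueError("more hubs than nodes")


@dataclass
class GntBenchmarkDataset:
    """One SBM network with block genesets labeled positive/negative."""

    network: Network
    genesets: dict[str, tuple[str, ...]]
    labels: dict[str, str]
    params: dict = field(default_factory=dict)

    @property
    def positive_genesets(self) -> dict[str, tuple[str, ...]]:
        return {k: v for k, v in self.genesets.items() if self.labels[k] == "positive"}

    @property
    def negative_genesets(self) -> dict[str, tuple[str, ...]]:
        return {k: v for k, v in self.genesets.items() if self.labels[k] == "negative"}


@dataclass
class GenesetPair:
    """One association test instance: a block geneset vs a mixture geneset."""

    name_a: str
    genes_a: tuple[str, ...]
    name_b: str
    genes_b: tuple[str, ...]
    label: str  # positive (linked blocks) or negative (baseline blocks)


@dataclass
class GnaBenchmarkDataset:
    """One SBM network with labeled geneset pairs for association testing."""

    network: Network
    pairs: list[GenesetPair]
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# generators


def generate_sbm_network(spec: SbmSpec) -> tuple[Network, np.ndarray]:
    """Sample an undirected simple graph from a stochastic block model.

    Returns the network and per-node block labels (background block, when
    present, is the last label).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    sizes = spec.all_sizes
    labels = np.repeat(np.arange(len(sizes)), sizes)
    # per-pair edge probability, sampled on the upper triangle only
    prob = spec.M[np.ix_(labels, labels)]
    draws = rng.random((n, n))
    adj = np.triu(draws < prob, k=1)
    adj = (adj | adj.T).astype(np.uint8)
    return Network.from_adjacency(_node_names(n), adj), labels


def generate_hdn_network(spec: HdnSpec) -> tuple[Network, tuple[str, ...]]:
    """Sample a network with ``n_hd`` planted hubs (the first node ids).

    Any pair with at least one hub endpoint connects with probability
    ``p_hd``; all other pairs with ``p0``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    hub = np.zeros(n, dtype=bool)
    hub[: spec.n_hd] = True
    prob = np.where(hub[:, None] | hub[None, :], spec.p_hd, spec.p0)
    draws = rng.random((n, n))
    adj = np.triu(draws < prob, k=1)
    adj = (adj | adj.T).astype(np.uint8)
    names = _node_names(n)
    return Network.from_adjacency(names, adj), tuple(names[: spec.n_hd])


# ---------------------------------------------------------------------------
# benchmark dataset builders


def gnt_benchmark(
    n_nodes: int = 1000,
    k: int = 7,
    block_size: int = 100,
    p0: float = 0.01,
    alpha: float = 5.0,
    n_networks: int = 3,
    seed: int = 0,
) -> list[GntBenchmarkDataset]:
    """SBM datasets for topology-test benchmarking.

    Each network carries ``k`` blocks of ``block_size`` nodes over a
    background at baseline ``p0``; the first floor(k/2) blocks are densified
    to within-block probability ``alpha * p0`` (positive genesets), the rest
    stay at baseline (negative genesets).
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    if alpha * p0 > 1:
        raise ValueError(f"alpha * p0 = {alpha * p0:.3g} exceeds 1")
    n_pos = k // 2
    datasets = []
    for net_id in range(n_networks):
        net_seed = _child_seed(seed, net_id)
        M = np.full((k + 1, k + 1), p0)
        for b in range(n_pos):
            M[b, b] = alpha * p0
        spec = SbmSpec(n_nodes, [block_size] * k, M, seed=net_seed)
        network, labels = generate_sbm_network(spec)
        genesets, geneset_labels = {}, {}
        for b in range(k):
            name = f"net{net_id}_block{b}"
            genesets[name] = tuple(network.nodes[i] for i in np.nonzero(labels == b)[0])
            geneset_labels[name] = "positive" if b < n_pos else "negative"
        datasets.append(
            GntBenchmarkDataset(
                network, genesets, geneset_labels,
                params={"n_nodes": n_nodes, "k": k, "block_size": block_size,
                        "p0": p0, "alpha": alpha, "network": net_id, "seed": net_seed},
            )
        )
    return datasets


def gna_benchmark(
    n_nodes: int = 1000,
    block_size: int = 50,
    p0: float = 0.01,
    alpha: float = 5.0,
    beta_mix: float = 10.0,
    pi: float = 0.04,
    n_networks: int = 3,
    seed: int = 0,
) -> list[GnaBenchmarkDataset]:
    """SBM datasets for association-test benchmarking.

    Eight blocks of ``block_size`` nodes, all with within-block probability
    ``alpha * p0``, are linked in disjoint pairs: pairs (0,1) and (2,3) get
    between-block probability ``p0 + beta_mix * p0 * (alpha - 1)`` (positive
    pairs), pairs (4,5) and (6,7) stay at baseline (negative pairs). For each
    pair (i, j) the tested genesets are block i and a mixture geneset of
    ``round(pi * m)`` nodes from block i plus the rest from block j, so the
    tested pair overlaps in ``round(pi * m)`` genes.
    """
    if alpha < 1 or beta_mix < 0:
        raise ValueError("alpha must be >= 1 and beta_mix >= 0")
    p_within = alpha * p0
    p_between = p0 + beta_mix * p0 * (alpha - 1.0)
    if p_within > 1 or p_between > 1:
        raise ValueError("derived block probabilities exceed 1")
    k = 8
    pair_blocks = [(0, 1), (2, 3), (4, 5), (6, 7)]
    pair_labels = ["positive", "positive", "negative", "negative"]
    n_overlap = _round_half_away(pi * block_size)
    datasets = []
    for net_id in range(n_networks):
        net_seed = _child_seed(seed, net_id)
        rng = np.random.default_rng(_child_seed(seed, net_id, 1))
        M = np.full((k + 1, k + 1), p0)
        for b in range(k):
            M[b, b] = p_within
        for (i, j), lab in zip(pair_blocks, pair_labels):
            if lab == "positive":
                M[i, j] = M[j, i] = p_between
        spec = SbmSpec(n_nodes, [block_size] * k, M, seed=net_seed)
        network, labels = generate_sbm_network(spec)
        blocks = {
            b: tuple(network.nodes[i] for i in np.nonzero(labels == b)[0])
            for b in range(k)
        }
        pairs = []
        for (i, j), lab in zip(pair_blocks, pair_labels):
            from_i = tuple(rng.choice(blocks[i], size=n_overlap, replace=False))
            from_j = tuple(
                rng.choice(blocks[j], size=block_size - n_overlap, replace=False)
            )
            pairs.append(
                GenesetPair(
                    name_a=f"net{net_id}_block{i}",
                    genes_a=blocks[i],
                    name_b=f"net{net_id}_mix{i}_{j}",
                    genes_b=tuple(sorted(from_i + from_j)),
                    label=lab,
                )
            )
        datasets.append(
            GnaBenchmarkDataset(
                network, pairs,
                params={"n_nodes": n_nodes, "block_size": block_size, "p0": p0,
                        "alpha": alpha, "beta_mix": beta_mix, "pi": pi,
                        "network": net_id, "seed": net_seed},
            )
        )
    return datasets


def extended_geneset(
    spec: HdnSpec,
    network: Network,
    hubs: Sequence[str],
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Sample a mixture geneset of hubs and random non-hub nodes.

    Takes ``round(pi_hd * n_hd)`` hubs and ``round(rho * pi_hd * n_hd)``
    non-hub nodes, for a total of about ``(1 + rho) * pi_hd * n_hd`` genes.
    """
    n_hub = _round_half_away(spec.pi_hd * spec.n_hd)
    n_other = _round_half_away(spec.rho * spec.pi_hd * spec.n_hd)
    hubs = list(hubs)
    others = [v for v in network.nodes if v not in set(hubs)]
    if n_hub > len(hubs) or n_other > len(others):
        raise ValueError("not enough hub or non-hub candidates for the geneset")
    pick_h = rng.choice(len(hubs), size=n_hub, replace=False)
    pick_o = rng.choice(len(others), size=n_other, replace=False)
    return tuple(sorted([hubs[i] for i in pick_h] + [others[i] for i in pick_o]))


# ---------------------------------------------------------------------------
# filters


def lcc_fraction(genes: Sequence[str], network: Network) -> float:
    """Fraction of the geneset inside the largest component it induces."""
    present = [g for g in genes if g in network.node_index]
    if not present:
        return 0.0
    from .gnt import _module

    idx = np.array([network.node_index[g] for g in present], dtype=np.int64)
    return _module(idx, network.adjacency) / len(genes)


def lcc_filter(
    genesets: Sequence[tuple[str, Sequence[str]]],
    network: Network,
    max_fraction: float = 0.75,
) -> list[tuple[str, Sequence[str]]]:
    """Drop genesets whose induced-subgraph LCC holds more than 75% of them.

    Extended genesets that happen to form one big connected cluster are real
    modules, not false-positive probes, and are discarded from FPR counts.
    The boundary is strict: exactly ``max_fraction`` is kept.
    """
    kept = [
        (name, genes)
        for name, genes in genesets
        if lcc_fraction(genes, network) <= max_fraction
    ]
    if len(kept) < len(genesets):
        logger.info(
            "LCC filter discarded %d of %d genesets", len(genesets) - len(kept),
            len(genesets),
        )
    return kept


def _child_seed(seed: int, *key: int) -> int:
    """Deterministic 31-bit child seed for a simulation substream."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))
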