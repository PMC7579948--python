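"""Network ingestion, LCC extraction, and precomputed interaction matrices.

An interaction network is an undirected simple graph over gene (or protein)
identifiers. Distance- and diffusion-based statistics are only meaningful on a
connected graph, so all downstream analysis is restricted to the largest
connected component (LCC). Two node-pair interaction structures are
precomputed once per network and persisted to HDF5:

* the all-pairs unweighted shortest-path length matrix ``sp``, and
* the random-walk-with-restart (RWR) heat matrix
  ``H = beta * (I - (1 - beta) * Abar)^-1`` with ``Abar = A D^-1``
  (column-normalized adjacency), where ``beta`` is the restart probability.

With column normalization each column of ``H`` sums to one: the unit of heat
injected at a node is conserved across the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

logger = logging.getLogger(__name__)

DEFAULT_RESTART_PROB = 0.85


class Network:
    """An undirected simple graph with a frozen, sorted node ordering.

    Parameters
    ----------
    nodes:
        Node identifiers. Stored sorted; all matrices follow this order.
    adjacency:
        Symmetric 0/1 matrix aligned with the *sorted* node order. Built
        internally by the constructors; not validated here beyond shape.
    """

    def __init__(self, nodes: Sequence[str], adjacency: np.ndarray):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if adjacency.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node count")
        self.adjacency = adjacency
        self.node_index: dict[str, int] = {v: i for i, v in enumerate(self.nodes)}
        self._degrees: np.ndarray | None = None

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "Network":
        """Build a network from an edge iterable.

        Self-loops are dropped (a node incident only to a self-loop is kept as
        an isolated node) and duplicate edges are collapsed; counts of both are
        logged.
        """
        nodes: set[str] = set(extra_nodes)
        seen: set[frozenset[str]] = set()
        n_self, n_dup = 0, 0
        pairs: list[tuple[str, str]] = []
        for a, b in edges:
            nodes.add(a)
            nodes.add(b)
            if a == b:
                n_self += 1
                continue
            key = frozenset((a, b))
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            pairs.append((a, b))
        if n_self or n_dup:
            logger.info("dropped %d self-loops and %d duplicate edges", n_self, n_dup)
        order = sorted(nodes)
        index = {v: i for i, v in enumerate(order)}
        n = len(order)
        adj = np.zeros((n, n), dtype=np.uint8)
        if pairs:
            ii = np.fromiter((index[a] for a, b in pairs), dtype=np.int64)
            jj = np.fromiter((index[b] for a, b in pairs), dtype=np.int64)
            adj[ii, jj] = 1
            adj[jj, ii] = 1
        return cls(order, adj)

    @classmethod
    def from_adjacency(cls, nodes: Sequence[str], adjacency: np.ndarray) -> "Network":
        """Wrap a symmetric 0/1 matrix given in sorted node order."""
        order = list(nodes)
        if order != sorted(order):
            raise ValueError("nodes must be given in sorted order")
        return cls(order, np.asarray(adjacency, dtype=np.uint8))

    # -- basic properties --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        """Per-node edge counts, aligned with ``self.nodes``."""
        if self._degrees is None:
            self._degrees = self.adjacency.sum(axis=1).astype(np.int64)
        return self._degrees

    @property
    def edges(self) -> set[frozenset[str]]:
        ii, jj = np.nonzero(np.triu(self.adjacency))
        return {frozenset((self.nodes[i], self.nodes[j])) for i, j in zip(ii, jj)}

    def degree_of(self, node: str) -> int:
        return int(self.degrees[self.node_index[node]])

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        ii, jj = np.nonzero(np.triu(self.adjacency))
        g.add_edges_from((self.nodes[i], self.nodes[j]) for i, j in zip(ii, jj))
        return g

    def subnetwork(self, keep: Iterable[str]) -> "Network":
        """Induced subgraph on ``keep`` (sorted order preserved)."""
        idx = np.array(sorted(self.node_index[v] for v in keep), dtype=np.int64)
        return Network([self.nodes[i] for i in idx], self.adjacency[np.ix_(idx, idx)])

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return False
        ncomp, _ = connected_components(csr_matrix(self.adjacency), directed=False)
        return ncomp == 1

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class InteractionMatrices:
    """Precomputed node-pair interaction structure for one network LCC.

    ``node_order`` is the frozen (sorted) node ordering shared by both
    matrices. ``sp[i, j]`` is the unweighted shortest-path length and
    ``heat[i, j]`` the RWR steady-state heat from node j to node i (columns of
    ``heat`` sum to one).
    """

    node_order: tuple[str, ...]
    sp: np.ndarray | None = None
    heat: np.ndarray | None = None
    restart_prob: float | None = None
    node_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.node_order = tuple(self.node_order)
        self.node_index = {v: i for i, v in enumerate(self.node_order)}


@dataclass
class Geneset:
    """A named gene collection partitioned against a network's node set.

    Statistics are computed on ``mapped`` only; ``unmapped`` genes are carried
    for reporting. ``mapped`` is kept sorted so index arrays are deterministic.
    """

    name: str
    genes: frozenset[str]
    mapped: tuple[str, ...]
    unmapped: frozenset[str]

    @property
    def n_mapped(self) -> int:
        return len(self.mapped)


# ---------------------------------------------------------------------------
# operations


def load_network(path: str | Path, skip_header: bool = False) -> Network:
    """Read a two-column tab-separated edge list into a :class:`Network`.

    Lines starting with ``#`` and blank lines are ignored. Extra columns
    beyond the first two are allowed and ignored. Duplicate edges are
    collapsed and self-loops dropped (logged).
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        first_data_line = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if skip_header and first_data_line:
                first_data_line = False
                continue
            first_data_line = False
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: line {lineno}: expected at least two tab-separated "
                    f"fields, got {line!r}"
                )
            edges.append((fields[0].strip(), fields[1].strip()))
    if not edges:
        raise ValueError(f"{path}: no interactions found")
    return Network.from_edges(edges)


def largest_connected_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken by the component containing the
    lexicographically smallest node id, so the result is deterministic.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    ncomp, labels = connected_components(csr_matrix(net.adjacency), directed=False)
    if ncomp == 1:
        return net
    sizes = np.bincount(labels, minlength=ncomp)
    best = sizes.max()
    # nodes are sorted, so the first node whose component has maximal size
    # belongs to the lexicographically-smallest tied component
    winner = labels[np.argmax(sizes[labels] == best)]
    keep = [net.nodes[i] for i in np.nonzero(labels == winner)[0]]
    return net.subnetwork(keep)


def compute_shortest_path_matrix(net: Network) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (BFS from every node).

    Requires a connected network; run :func:`largest_connected_component`
    first otherwise.
    """
    if not net.is_connected():
        raise ValueError(
            "network is disconnected: extract the largest connected component "
            "before computing shortest paths"
        )
    d = shortest_path(csr_matrix(net.adjacency), method="D", unweighted=True)
    return d.astype(np.int16)


def compute_rwr_matrix(
    net: Network, restart_prob: float = DEFAULT_RESTART_PROB
) -> np.ndarray:
    """Random-walk-with-restart heat matrix H = beta (I - (1-beta) Abar)^-1.

    ``Abar`` is the adjacency with each column divided by the column node's
    degree, so ``Abar`` (and hence ``H``) is column-stochastic.
    """
    if not 0.0 < restart_prob < 1.0:
        raise ValueError("restart_prob must lie in (0, 1)")
    deg = net.degrees
    if (deg == 0).any():
        raise ValueError("all nodes must have degree >= 1 (use the LCC)")
    abar = net.adjacency.astype(np.float64) / deg[np.newaxis, :]
    n = net.n_nodes
    system = np.eye(n) - (1.0 - restart_prob) * abar
    try:
        heat = restart_prob * np.linalg.solve(system, np.eye(n))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded, unreachable
        raise np.linalg.LinAlgError(f"RWR system is singular: {exc}") from exc
    return heat


def build_matrices(
    net: Network, restart_prob: float = DEFAULT_RESTART_PROB
) -> InteractionMatrices:
    """Compute both interaction matrices for a connected network."""
    return InteractionMatrices(
        node_order=net.nodes,
        sp=compute_shortest_path_matrix(net),
        heat=compute_rwr_matrix(net, restart_prob),
        restart_prob=restart_prob,
    )


def save_matrices(m: InteractionMatrices, path: str | Path) -> None:
    """Persist interaction matrices to one HDF5 container.

    Layout: ``/node_order`` (UTF-8 strings), ``/sp`` (int16), ``/heat``
    (float64), with ``restart_prob`` stored as a root attribute.
    """
    with h5py.File(path, "w") as fh:
        fh.create_dataset(
            "node_order",
            data=np.array(m.node_order, dtype=h5py.string_dtype("utf-8")),
        )
        if m.sp is not None:
            fh.create_dataset("sp", data=m.sp.astype(np.int16))
        if m.heat is not None:
            fh.create_dataset("heat", data=m.heat.astype(np.float64))
        if m.restart_prob is not None:
            fh.attrs["restart_prob"] = float(m.restart_prob)


def load_matrices(
    path: str | Path, net: Network | None = None, mmap: bool = False
) -> InteractionMatrices:
    """Load a persisted matrix container.

    If ``net`` is given, its node set must match the stored ``node_order``
    exactly; a mismatch raises rather than silently misaligning indices.
    With ``mmap=True`` the file is opened without the HDF5 chunk cache warmup
    and datasets are read lazily per access pattern of h5py; the arrays are
    still materialized on return (dense matrices are the supported layout).
    """
    kwargs = {"rdcc_nbytes": 0} if mmap else {}
    with h5py.File(path, "r", **kwargs) as fh:
        node_order = tuple(s.decode() if isinstance(s, bytes) else str(s)
                           for s in fh["node_order"][()])
        sp = fh["sp"][()] if "sp" in fh else None
        heat = fh["heat"][()] if "heat" in fh else None
        restart_prob = float(fh.attrs["restart_prob"]) if "restart_prob" in fh.attrs else None
    if net is not None and tuple(net.nodes) != node_order:
        raise ValueError(
            "node order in the matrix container does not match the supplied "
            "network; recompute the matrices for this network"
        )
    return InteractionMatrices(node_order, sp=sp, heat=heat, restart_prob=restart_prob)


def map_geneset(genes: Iterable[str], net: Network, name: str = "geneset") -> Geneset:
    """Partition ``genes`` into mapped/unmapped against the network node set."""
    genes = frozenset(genes)
    mapped = tuple(sorted(g for g in genes if g in net.node_index))
    unmapped = frozenset(genes - set(mapped))
    if not mapped:
        raise ValueError(
            f"geneset {name!r}: none of {len(genes)} genes map to the network"
        )
    if unmapped:
        logger.info(
            "geneset %s: %d/%d genes not in the network",
            name, len(unmapped), len(genes),
        )
    return Geneset(name=name, genes=genes, mapped=mapped, unmapped=unmapped)
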