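"""Geneset network topology (GNT) statistics.

Five statistics quantify how strongly the genes of one set interact with each
other on the network, each under a different interaction model:

============================  =======================================================
statistic                     definition (S = mapped geneset, n = |S|)
============================  =======================================================
``total_degree``              (1/n) sum_{i in S} deg(i)
``internal_degree``           (1/n) sum_{i in S} deg(i, S) / deg(i)
``module``                    size of the largest connected component of G[S]
``shortest_path``             (1/n) sum_{i in S} min_{j in S, j != i} sp[i, j]
``heat``                      sum_{i, j in S, i != j} H[i, j]
============================  =======================================================

``deg(i, S)`` counts edges from i into S. The shortest-path statistic
excludes the trivial self-distance (the minimum is over the *rest* of the
geneset), and the heat statistic sums over ordered pairs, so both H[i, j] and
H[j, i] contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .netcore import Geneset, InteractionMatrices, Network

GNT_STATISTICS = ("total_degree", "internal_degree", "module", "shortest_path", "heat")

#: statistics computable from the adjacency alone
DIRECT_STATISTICS = ("total_degree", "internal_degree", "module")


@dataclass
class GntObservation:
    """Observed value of one topology statistic for one geneset."""

    geneset_name: str
    statistic_name: str
    observed: float
    n_mapped: int


# ---------------------------------------------------------------------------
# index-level kernels (shared with the bootstrap machinery in `inference`)


def _total_degree(idx: np.ndarray, degrees: np.ndarray) -> float:
    return float(degrees[idx].mean())


def _internal_degree(idx: np.ndarray, adjacency: np.ndarray, degrees: np.ndarray) -> float:
    sub = adjacency[np.ix_(idx, idx)]
    return float((sub.sum(axis=1) / degrees[idx]).mean())


def _module(idx: np.ndarray, adjacency: np.ndarray) -> float:
    sub = adjacency[np.ix_(idx, idx)]
    _, labels = connected_components(csr_matrix(sub), directed=False)
    return float(np.bincount(labels).max())


def _shortest_path(idx: np.ndarray, sp: np.ndarray) -> float:
    sub = sp[np.ix_(idx, idx)].astype(np.float64)
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _heat(idx: np.ndarray, heat: np.ndarray) -> float:
    sub = heat[np.ix_(idx, idx)]
    return float(sub.sum() - np.trace(sub))


# ---------------------------------------------------------------------------
# public operations


def _indices(S: Geneset, index: dict[str, int]) -> np.ndarray:
    try:
        return np.array([index[g] for g in S.mapped], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(
            f"geneset {S.name!r}: gene {exc.args[0]!r} is not in the node order; "
            "map the geneset against the same network the matrices were built on"
        ) from exc


def _require(S: Geneset, minimum: int) -> None:
    if S.n_mapped < minimum:
        raise ValueError(
            f"geneset {S.name!r}: needs at least {minimum} mapped gene(s), "
            f"has {S.n_mapped}"
        )


def total_degree_stat(S: Geneset, net: Network) -> float:
    """Mean network degree of the mapped genes."""
    _require(S, 1)
    return _total_degree(_indices(S, net.node_index), net.degrees)


def internal_degree_stat(S: Geneset, net: Network) -> float:
    """Mean fraction of each mapped gene's edges that stay inside the geneset.

    Lies in [0, 1]; 1 means every neighbor of every geneset gene is itself in
    the geneset.
    """
    _require(S, 1)
    return _internal_degree(_indices(S, net.node_index), net.adjacency, net.degrees)


def module_stat(S: Geneset, net: Network) -> float:
    """Size of the largest connected component induced by the mapped genes."""
    _require(S, 1)
    return _module(_indices(S, net.node_index), net.adjacency)


def shortest_path_stat(S: Geneset, m: InteractionMatrices) -> float:
    """Mean distance from each mapped gene to its nearest other geneset gene."""
    _require(S, 2)
    if m.sp is None:
        raise ValueError("interaction matrices have no shortest-path matrix")
    return _shortest_path(_indices(S, m.node_index), m.sp)


def heat_stat(S: Geneset, m: InteractionMatrices) -> float:
    """Total RWR heat exchanged within the geneset (ordered pairs, i != j)."""
    _require(S, 2)
    if m.heat is None:
        raise ValueError("interaction matrices have no heat matrix")
    return _heat(_indices(S, m.node_index), m.heat)


def gnt_statistic(
    S: Geneset,
    statistic: str,
    net: Network | None = None,
    matrices: InteractionMatrices | None = None,
) -> GntObservation:
    """Compute any of the five topology statistics by name."""
    if statistic in DIRECT_STATISTICS:
        if net is None:
            raise ValueError(f"{statistic} requires the network")
        fn = {
            "total_degree": total_degree_stat,
            "internal_degree": internal_degree_stat,
            "module": module_stat,
        }[statistic]
        value = fn(S, net)
    elif statistic == "shortest_path":
        if matrices is None:
            raise ValueError("shortest_path requires precomputed matrices")
        value = shortest_path_stat(S, matrices)
    elif statistic == "heat":
        if matrices is None:
            raise ValueError("heat requires precomputed matrices")
        value = heat_stat(S, matrices)
    else:
        raise ValueError(f"unknown GNT statistic {statistic!r}")
    return GntObservation(S.name, statistic, value, S.n_mapped)
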