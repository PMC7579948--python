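"""Geneset network association (GNA) statistics.

Two statistics quantify how strongly the genes of two sets S1 (n genes) and
S2 (m genes) interact with *each other*:

* ``association_shortest_path``::

      U_SP = (1/(n+m)) * [ sum_{i in S1} min_{j in S2} sp[i,j]
                         + sum_{j in S2} min_{i in S1} sp[i,j] ]
             - (T_SP(S1) + T_SP(S2)) / 2

  The cross term measures how close each gene is to the other set; the
  within-set baseline is subtracted, so negative values mean the two sets are
  closer to each other than each is internally cohesive. A gene shared by
  both sets contributes a cross-minimum of zero (its distance to itself).

* ``association_heat``::

      U_H = sum_{i in S1, j in S2} (H[i,j] + H[j,i])

  Genes in the overlap contribute their withheld heat H[i,i], so identical
  sets are maximally associated.

Both statistics are symmetric in (S1, S2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gnt import _indices, _require, _shortest_path
from .netcore import Geneset, InteractionMatrices

GNA_STATISTICS = ("association_shortest_path", "association_heat")


@dataclass
class GnaObservation:
    """Observed value of one association statistic for a geneset pair."""

    geneset_a: str
    geneset_b: str
    statistic_name: str
    observed: float
    n: int
    m: int
    overlap: int


# ---------------------------------------------------------------------------
# index-level kernels


def _association_sp(idx1: np.ndarray, idx2: np.ndarray, sp: np.ndarray) -> float:
    cross = sp[np.ix_(idx1, idx2)].astype(np.float64)
    n, m = len(idx1), len(idx2)
    cross_term = (cross.min(axis=1).sum() + cross.min(axis=0).sum()) / (n + m)
    baseline = 0.5 * (_shortest_path(idx1, sp) + _shortest_path(idx2, sp))
    return float(cross_term - baseline)


def _association_heat(idx1: np.ndarray, idx2: np.ndarray, heat: np.ndarray) -> float:
    return float(heat[np.ix_(idx1, idx2)].sum() + heat[np.ix_(idx2, idx1)].sum())


# ---------------------------------------------------------------------------
# public operations


def association_sp(S1: Geneset, S2: Geneset, m: InteractionMatrices) -> float:
    """Shortest-path association between two genesets (negative = close)."""
    _require(S1, 2)
    _require(S2, 2)
    if m.sp is None:
        raise ValueError("interaction matrices have no shortest-path matrix")
    return _association_sp(_indices(S1, m.node_index), _indices(S2, m.node_index), m.sp)


def association_heat(S1: Geneset, S2: Geneset, m: InteractionMatrices) -> float:
    """Total RWR heat exchanged between two genesets (large = associated)."""
    _require(S1, 1)
    _require(S2, 1)
    if m.heat is None:
        raise ValueError("interaction matrices have no heat matrix")
    return _association_heat(
        _indices(S1, m.node_index), _indices(S2, m.node_index), m.heat
    )


def gna_statistic(
    S1: Geneset, S2: Geneset, statistic: str, matrices: InteractionMatrices
) -> GnaObservation:
    """Compute an association statistic by name."""
    if statistic in ("association_shortest_path", "association_sp"):
        value = association_sp(S1, S2, matrices)
        name = "association_shortest_path"
    elif statistic == "association_heat":
        value = association_heat(S1, S2, matrices)
        name = "association_heat"
    else:
        raise ValueError(f"unknown GNA statistic {statistic!r}")
    overlap = len(set(S1.mapped) & set(S2.mapped))
    return GnaObservation(S1.name, S2.name, name, value, S1.n_mapped, S2.n_mapped, overlap)
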