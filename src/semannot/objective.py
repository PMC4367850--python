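"""Groupwise similarity and the global annotation objective.

A candidate annotation A is scored against the neighbor annotations A_K by
the Best Match Average (BMA):

    sim_bma(A, B) = 1/(2|A|) * sum_{c in A} max_{c' in B} lin(c, c')
                  + 1/(2|B|) * sum_{c in B} max_{c' in A} lin(c, c')

and the objective trades semantic fidelity against concision:

    f(A) = 1/|A_K| * sum_{A_d in A_K} sim_bma(A, A_d)  -  mu * |A|

with mu in [0, 1].  Everything here is computed by direct summation over a
precomputed pairwise-similarity matrix; this module is the ground truth the
incremental search bookkeeping must reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .corpus import NeighborSet
from .ontology import PairwiseSimMatrix

__all__ = [
    "ObjectiveConfig",
    "sim_concept_set",
    "sim_bma",
    "objective_f",
    "removal_degradation",
]

#: absolute tolerance for comparisons between objective values
F_TOL = 1e-12


@dataclass(frozen=True)
class ObjectiveConfig:
    """mu is the concision penalty weight; 0 means pure similarity."""

    mu: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")


def sim_concept_set(c: str, a: Iterable[str], m: PairwiseSimMatrix) -> float:
    """max_{c' in a} lin(c, c') — the best match of ``c`` inside ``a``."""
    idx = m.rows(a)
    if idx.size == 0:
        raise ValueError("similarity to an empty concept set is undefined")
    return float(m.values[m.index[c], idx].max())


def sim_bma(a: Iterable[str], b: Iterable[str], m: PairwiseSimMatrix) -> float:
    """Best Match Average between two concept sets, in [0, 1], symmetric."""
    ia, ib = m.rows(a), m.rows(b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("BMA of an empty concept set is undefined")
    block = m.values[np.ix_(ia, ib)]
    return 0.5 * float(block.max(axis=1).mean()) + 0.5 * float(block.max(axis=0).mean())


def objective_f(
    candidate: Iterable[str],
    neighbors: NeighborSet | Sequence[Iterable[str]],
    cfg: ObjectiveConfig,
    m: PairwiseSimMatrix,
) -> float:
    """f(A): mean BMA to the neighbor annotations minus mu * |A|."""
    annotations = _annotations(neighbors)
    cand = list(candidate)
    if not cand:
        raise ValueError("objective of an empty candidate is undefined")
    total = 0.0
    for ann in annotations:
        total += sim_bma(cand, ann, m)
    return total / len(annotations) - cfg.mu * len(cand)


def removal_degradation(
    candidate: Iterable[str],
    c: str,
    neighbors: NeighborSet | Sequence[Iterable[str]],
    m: PairwiseSimMatrix,
) -> float:
    """Similarity cost of dropping ``c`` from the candidate.

    The absolute mean, over neighbor annotations, of the BMA drop when ``c``
    is removed — the quantity mu trades off against.  Diagnostic only: the
    search is driven by the objective itself.
    """
    cand = set(candidate)
    if c not in cand:
        raise ValueError(f"concept {c!r} not in candidate")
    if len(cand) < 2:
        raise ValueError("cannot remove from a singleton candidate")
    annotations = _annotations(neighbors)
    reduced = cand - {c}
    delta = 0.0
    for ann in annotations:
        delta += sim_bma(cand, ann, m) - sim_bma(reduced, ann, m)
    return abs(delta / len(annotations))


def _annotations(
    neighbors: NeighborSet | Sequence[Iterable[str]],
) -> list[frozenset[str]]:
    if isinstance(neighbors, NeighborSet):
        return neighbors.annotations
    anns = [frozenset(a) for a in neighbors]
    if not anns or any(not a for a in anns):
        raise ValueError("every neighbor annotation must be non-empty")
    return anns
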