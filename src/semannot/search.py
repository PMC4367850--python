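"""Annotation search: maximize f over subsets of the candidate pool.

Three routes to the same contract:

* :func:`exhaustive_best` — enumerate every non-empty subset (guarded to
  small pools); the ground-truth optimum for oracle tests.
* :func:`hill_climb_naive` — steepest-ascent removal, every objective value
  recomputed from scratch by direct summation.
* :func:`hill_climb_optimized` — identical output, but per-neighbor column-max
  sums and row maxima are maintained incrementally: removing a concept c_r
  only subtracts the precomputed max of its similarity column per neighbor,
  and only rows whose current best match *is* c_r get their maximum
  recomputed, with the delta propagated to the neighbors containing that row
  concept.  Values touched by the winning tentative removal are kept and
  applied on acceptance, so no accepted step recomputes anything.

Both climbers start from the full pool, at each round test the removal of
every concept (in canonical sorted order), remove the one with the largest
strict increase in f, and stop when no removal strictly improves f or a
single concept remains.  Ties on the increase go to the lexicographically
smallest concept; a concept is never added back.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .corpus import (
    NeighborSet,
    RankedNeighborList,
    build_candidate_pool,
    filter_candidate_pool,
    select_topk,
)
from .objective import F_TOL, ObjectiveConfig, objective_f, removal_degradation
from .ontology import Ontology, OntologyError, PairwiseSimMatrix, build_sim_matrix

__all__ = [
    "SearchResult",
    "AnnotationResult",
    "exhaustive_best",
    "hill_climb_naive",
    "hill_climb_optimized",
    "annotate",
]


@dataclass
class SearchResult:
    """Final annotation, its objective value, and the removal trace."""

    annotation: frozenset[str]
    objective: float
    trace: list[str]
    #: largest |stored - recomputed| seen by debug-mode consistency checks
    debug_max_dev: float = 0.0

    def __iter__(self) -> Iterator:
        return iter((self.annotation, self.objective, self.trace))


def _neighbor_annotations(
    neighbors: NeighborSet | Sequence[Sequence[str]],
) -> list[frozenset[str]]:
    if isinstance(neighbors, NeighborSet):
        return neighbors.annotations
    return [frozenset(a) for a in neighbors]


def exhaustive_best(
    pool: Sequence[str] | frozenset[str],
    neighbors: NeighborSet | Sequence[Sequence[str]],
    cfg: ObjectiveConfig,
    m: PairwiseSimMatrix,
    max_pool: int = 20,
) -> tuple[frozenset[str], float]:
    """Best non-empty subset of ``pool`` by full enumeration.

    Intractable in general (2^|A0| candidates) — deliberately implemented as
    the small-instance oracle, refused beyond ``max_pool`` concepts.  Ties in
    f (within 1e-12) go to the smaller subset, then to lexicographic concept
    order.
    """
    concepts = sorted(pool)
    n = len(concepts)
    if n == 0:
        raise ValueError("empty candidate pool")
    if n > max_pool:
        raise ValueError(f"pool of {n} concepts exceeds enumeration guard {max_pool}")
    annotations = _neighbor_annotations(neighbors)
    cols = m.rows(concepts)
    rows_d = [m.rows(a) for a in annotations]
    # columns are fixed per subset; row maxima must be recomputed per subset
    colmax_d = [m.values[np.ix_(r, cols)].max(axis=0) for r in rows_d]

    n_subsets = (1 << n) - 1
    masks_bits = np.arange(1, n_subsets + 1, dtype=np.uint32)
    member = ((masks_bits[:, None] >> np.arange(n)) & 1).astype(bool)
    sizes = member.sum(axis=1)

    f_vals = np.zeros(n_subsets, dtype=np.float64)
    for r, cmax, ann in zip(rows_d, colmax_d, annotations):
        block = m.values[np.ix_(r, cols)]
        col_part = (member @ cmax) / (2.0 * sizes)
        chunk = 65536
        row_part = np.empty(n_subsets)
        for lo in range(0, n_subsets, chunk):
            hi = min(lo + chunk, n_subsets)
            masked = np.where(member[lo:hi, None, :], block[None, :, :], -np.inf)
            row_part[lo:hi] = masked.max(axis=2).sum(axis=1)
        f_vals += col_part + row_part / (2.0 * len(ann))
    f_vals = f_vals / len(annotations) - cfg.mu * sizes

    fmax = f_vals.max()
    tied = np.nonzero(f_vals >= fmax - F_TOL)[0]
    best = min(
        tied,
        key=lambda i: (sizes[i], tuple(c for j, c in enumerate(concepts) if member[i, j])),
    )
    subset = frozenset(c for j, c in enumerate(concepts) if member[best, j])
    return subset, float(f_vals[best])


def hill_climb_naive(
    pool: Sequence[str] | frozenset[str],
    neighbors: NeighborSet | Sequence[Sequence[str]],
    cfg: ObjectiveConfig,
    m: PairwiseSimMatrix,
    strategy: str = "steepest",
) -> SearchResult:
    """Greedy removal with every f value recomputed from scratch.

    ``strategy="steepest"`` (default) removes the best-improving concept each
    round.  ``strategy="first"`` is the order-dependent baseline that removes
    the first improving concept encountered; it is kept only for comparison,
    as it is easily stuck at worse local maxima.
    """
    current = sorted(set(pool))
    if not current:
        raise ValueError("empty candidate pool")
    if strategy not in ("steepest", "first"):
        raise ValueError(f"unknown strategy {strategy!r}")
    annotations = _neighbor_annotations(neighbors)
    f_cur = objective_f(current, annotations, cfg, m)
    trace: list[str] = []
    while len(current) > 1:
        best_gain = 0.0
        best_c: str | None = None
        best_f = f_cur
        for c in current:
            reduced = [x for x in current if x != c]
            f_new = objective_f(reduced, annotations, cfg, m)
            if f_new - f_cur > best_gain + F_TOL:
                best_gain, best_c, best_f = f_new - f_cur, c, f_new
                if strategy == "first":
                    break
        if best_c is None:
            break
        current.remove(best_c)
        trace.append(best_c)
        f_cur = best_f
    return SearchResult(frozenset(current), f_cur, trace)


class _SearchState:
    """Incremental per-neighbor sums for the optimized climber.

    For every neighbor annotation A_d (whose concepts index *rows* of the
    similarity matrix, the candidate concepts indexing *columns*):

    * ``colmax[d]`` — max of each full column over the rows of A_d; fixed,
      since rows never change.  The column-max sum for the current candidate
      is ``sumcols[d]``; removing a candidate concept just subtracts its
      precomputed column max.
    * ``rowmax[r]`` / ``provider[r]`` — current best match of row concept r
      among the candidate columns, and the column attaining it (smallest
      index on ties).  Only rows provided by the removed concept are
      recomputed; ``membership[r]`` lists the neighbors containing r, to
      which each row delta is propagated into ``sumrows[d]``.
    """

    def __init__(
        self,
        pool_cols: np.ndarray,
        rows_d: list[np.ndarray],
        ann_sizes: np.ndarray,
        values: np.ndarray,
        mu: float,
    ) -> None:
        self.values = values
        self.mu = mu
        self.rows_d = rows_d
        self.ann_sizes = ann_sizes
        self.n_d = len(rows_d)
        self.current = list(pool_cols)  # ascending matrix-column indices
        cols = np.array(self.current, dtype=np.intp)

        # full-width column maxima per neighbor: rows never change, so these
        # are computed once and only ever indexed
        self.colmax = np.stack([values[r, :].max(axis=0) for r in rows_d])
        self.sumcols = self.colmax[:, cols].sum(axis=1)

        all_rows = sorted({int(r) for rr in rows_d for r in rr})
        self.row_ids = all_rows
        self.rowmax: dict[int, float] = {}
        self.provider: dict[int, int] = {}
        self.membership: dict[int, list[int]] = {r: [] for r in all_rows}
        for d, rr in enumerate(rows_d):
            for r in rr:
                self.membership[int(r)].append(d)
        for r in all_rows:
            sims = values[r, cols]
            j = int(np.argmax(sims))  # first occurrence = smallest column index
            self.rowmax[r] = float(sims[j])
            self.provider[r] = self.current[j]
        self.sumrows = np.array(
            [sum(self.rowmax[int(r)] for r in rr) for rr in rows_d]
        )

    @property
    def z(self) -> int:
        return len(self.current)

    def f(self) -> float:
        z = self.z
        per_d = self.sumcols / (2.0 * z) + self.sumrows / (2.0 * self.ann_sizes)
        return float(per_d.mean()) - self.mu * z

    def tentative_removal(self, c: int) -> tuple[float, dict]:
        """f after removing column ``c``, without mutating the state.

        Returns the objective and a cache of every value the removal would
        touch, so accepting it is a pure application with no recomputation.
        """
        z1 = self.z - 1
        remaining = np.array([x for x in self.current if x != c], dtype=np.intp)
        sumcols_new = self.sumcols - self.colmax[:, c]
        sumrows_delta = np.zeros(self.n_d)
        touched: dict[int, tuple[float, int]] = {}
        for r in self.row_ids:
            if self.provider[r] != c:
                continue
            sims = self.values[r, remaining]
            j = int(np.argmax(sims))
            new_max = float(sims[j])
            delta = new_max - self.rowmax[r]
            touched[r] = (new_max, int(remaining[j]))
            for d in self.membership[r]:
                sumrows_delta[d] += delta
        sumrows_new = self.sumrows + sumrows_delta
        per_d = sumcols_new / (2.0 * z1) + sumrows_new / (2.0 * self.ann_sizes)
        f_new = float(per_d.mean()) - self.mu * z1
        cache = {"c": c, "sumcols": sumcols_new, "sumrows": sumrows_new, "rows": touched}
        return f_new, cache

    def accept(self, cache: dict) -> None:
        """Apply a cached tentative removal permanently."""
        self.current.remove(cache["c"])
        self.sumcols = cache["sumcols"]
        self.sumrows = cache["sumrows"]
        for r, (new_max, new_provider) in cache["rows"].items():
            self.rowmax[r] = new_max
            self.provider[r] = new_provider

    def consistency_deviation(self) -> tuple[float, int]:
        """Max |stored - from-scratch| over all sums, and the worst neighbor."""
        cols = np.array(self.current, dtype=np.intp)
        worst, worst_d = 0.0, -1
        for d, rr in enumerate(self.rows_d):
            block = self.values[np.ix_(rr, cols)]
            dev = abs(float(block.max(axis=0).sum()) - float(self.sumcols[d]))
            dev = max(dev, abs(float(block.max(axis=1).sum()) - float(self.sumrows[d])))
            if dev > worst:
                worst, worst_d = dev, d
        for r in self.row_ids:
            dev = abs(float(self.values[r, cols].max()) - self.rowmax[r])
            if dev > worst:
                worst, worst_d = dev, -1
        return worst, worst_d


def hill_climb_optimized(
    pool: Sequence[str] | frozenset[str],
    neighbors: NeighborSet | Sequence[Sequence[str]],
    cfg: ObjectiveConfig,
    m: PairwiseSimMatrix,
    debug: bool = False,
) -> SearchResult:
    """Steepest-ascent removal with incremental max maintenance.

    Output (final set, objective, trace) is identical to
    ``hill_climb_naive(strategy="steepest")`` under the same tie-breaking.
    With ``debug=True`` every accepted removal is followed by a from-scratch
    recomputation of all stored sums; a deviation above 1e-9 raises an
    AssertionError naming the offending neighbor.
    """
    concepts = sorted(set(pool))
    if not concepts:
        raise ValueError("empty candidate pool")
    annotations = _neighbor_annotations(neighbors)
    cols = m.rows(concepts)
    rows_d = [m.rows(a) for a in annotations]
    ann_sizes = np.array([len(a) for a in annotations], dtype=np.float64)
    state = _SearchState(cols, rows_d, ann_sizes, m.values, cfg.mu)
    col_to_concept = {int(m.index[c]): c for c in concepts}

    f_cur = state.f()
    trace: list[str] = []
    max_dev = 0.0
    while state.z > 1:
        best_gain = 0.0
        best_cache: dict | None = None
        best_f = f_cur
        for c in state.current:  # ascending column index == canonical order
            f_new, cache = state.tentative_removal(c)
            if f_new - f_cur > best_gain + F_TOL:
                best_gain, best_cache, best_f = f_new - f_cur, cache, f_new
        if best_cache is None:
            break
        state.accept(best_cache)
        trace.append(col_to_concept[best_cache["c"]])
        f_cur = best_f
        if debug:
            dev, worst_d = state.consistency_deviation()
            max_dev = max(max_dev, dev)
            if dev > 1e-9:
                raise AssertionError(
                    f"incremental state drifted by {dev:.3e} "
                    f"(neighbor index {worst_d})"
                )
    final = frozenset(col_to_concept[c] for c in state.current)
    return SearchResult(final, f_cur, trace, debug_max_dev=max_dev)


@dataclass
class AnnotationResult:
    """Suggested annotation for one document, with diagnostics."""

    doc_id: str
    suggested: frozenset[str]
    objective: float
    trace: list[str]
    k_used: int
    filtered: bool
    mu: float
    pool: frozenset[str]
    degradations: dict[str, float] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        # timings are diagnostics for logs; keeping them out of the payload
        # makes reruns of the same config byte-identical
        return {
            "doc_id": self.doc_id,
            "suggested_concepts": sorted(self.suggested),
            "objective": self.objective,
            "trace": self.trace,
            "k_used": self.k_used,
            "filtered": self.filtered,
            "mu": self.mu,
            "pool_size": len(self.pool),
            "degradations": {c: self.degradations[c] for c in sorted(self.degradations)},
        }


def annotate(
    ranked: RankedNeighborList,
    ontology: Ontology,
    k: int = 20,
    use_filter: bool = False,
    min_docs: int = 2,
    mu: float = 0.0,
    map_click: tuple[float, float] | None = None,
    simulate_expert_click: bool = False,
) -> AnnotationResult:
    """Suggest an annotation for one document from its ranked neighbors.

    Selects the k-NN set (by rank, or by proximity to a click on the 2D
    semantic map), builds the candidate pool (optionally filtered to
    concepts in >= ``min_docs`` neighbor annotations), precomputes the
    pairwise-similarity matrix, and runs the optimized hill climber.  The
    suggestion has variable size: concepts are removed until no removal
    improves the objective.
    """
    cfg = ObjectiveConfig(mu=mu)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if map_click is not None or simulate_expert_click:
        from . import semantic_map

        candidates = ranked.annotated()
        if simulate_expert_click:
            if not ranked.gold:
                raise ValueError(
                    f"{ranked.target_id}: expert-click simulation needs a gold annotation"
                )
            click, embedding = semantic_map.gold_click(candidates, ranked.gold, ontology)
        else:
            embedding = semantic_map.embed_documents(candidates, ontology)
            click = map_click
        neighbors = semantic_map.click_select(embedding, click, k)
    else:
        neighbors = select_topk(ranked, k)
    timings["select"] = time.perf_counter() - t0

    pool = (
        filter_candidate_pool(neighbors, min_docs=min_docs)
        if use_filter
        else build_candidate_pool(neighbors)
    )
    union = build_candidate_pool(neighbors)
    missing = sorted(c for c in union if c not in ontology)
    if missing:
        raise OntologyError(
            "unresolvable concept identifiers in neighbor annotations: "
            + ", ".join(missing)
        )

    t0 = time.perf_counter()
    matrix = build_sim_matrix(ontology, sorted(union))
    timings["matrix"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result = hill_climb_optimized(pool, neighbors, cfg, matrix)
    timings["search"] = time.perf_counter() - t0

    degradations = {}
    if len(result.annotation) >= 2:
        degradations = {
            c: removal_degradation(result.annotation, c, neighbors, matrix)
            for c in result.annotation
        }
    return AnnotationResult(
        doc_id=ranked.target_id,
        suggested=result.annotation,
        objective=result.objective,
        trace=result.trace,
        k_used=len(neighbors),
        filtered=use_filter,
        mu=mu,
        pool=frozenset(pool),
        degradations=degradations,
        timings=timings,
    )
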