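"""Subsumption ontologies and intrinsic semantic similarity.

The annotation vocabulary is a rooted IS_A directed acyclic graph (e.g. a
MeSH or Gene Ontology subset).  Concept specificity is measured by Seco's
intrinsic information content,

    IC(c) = 1 - log(hypo(c) + 1) / log(|V|),

where ``hypo(c)`` counts the strict descendants of ``c`` and ``|V|`` the
concepts of the ontology: the root scores 0, every leaf scores 1, and IC is
monotone non-decreasing along IS_A specialisation.  Pairwise concept
similarity is Lin's measure,

    lin(x, y) = 2 * IC(MICA(x, y)) / (IC(x) + IC(y)),

with MICA the most informative common ancestor (ancestor sets are
self-inclusive, so lin(c, c) = 1 whenever IC(c) > 0).  Because the measure is
intrinsic, no corpus statistics are needed and the machinery applies to any
IS_A vocabulary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np

__all__ = [
    "Ontology",
    "OntologyError",
    "PairwiseSimMatrix",
    "load_ontology",
    "load_edge_table",
    "load_obo",
    "compute_seco_ic",
    "mica",
    "lin_similarity",
    "build_sim_matrix",
    "write_ic_table",
]

#: identifier given to the synthetic root added when the input has several
#: apparent roots; it carries IC 0 like any root.
VIRTUAL_ROOT = "VIRTUAL_ROOT"


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or unknown concepts."""


@dataclass
class Ontology:
    """A rooted IS_A DAG over string concept identifiers.

    ``parents`` maps each concept to its set of direct IS_A parents; the
    root is the unique concept with no parent.  Ancestor sets (computed
    lazily, memoised) are self-inclusive.
    """

    parents: dict[str, frozenset[str]]
    root: str
    _ancestors: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _ic: dict[str, float] | None = field(default=None, repr=False, compare=False)

    @property
    def concepts(self) -> frozenset[str]:
        return frozenset(self.parents)

    def __len__(self) -> int:
        return len(self.parents)

    def __contains__(self, concept: str) -> bool:
        return concept in self.parents

    def _require(self, concept: str) -> None:
        if concept not in self.parents:
            raise OntologyError(f"unknown concept: {concept!r}")

    def ancestors(self, concept: str) -> frozenset[str]:
        """Self-inclusive ancestor set of ``concept`` (so MICA(c, c) = c)."""
        self._require(concept)
        cached = self._ancestors.get(concept)
        if cached is not None:
            return cached
        # iterative DFS with memoisation; the DAG is validated acyclic
        order: list[str] = []
        stack = [concept]
        seen = set()
        while stack:
            node = stack.pop()
            if node in seen or node in self._ancestors:
                continue
            seen.add(node)
            order.append(node)
            stack.extend(self.parents[node])
        for node in reversed(order):
            acc = {node}
            for p in self.parents[node]:
                acc.update(self._ancestors.get(p) or self.ancestors(p))
            self._ancestors[node] = frozenset(acc)
        return self._ancestors[concept]

    @property
    def ic(self) -> dict[str, float]:
        """Seco information content table, computed on first access."""
        if self._ic is None:
            self._ic = compute_seco_ic(self)
        return self._ic

    def leaves(self) -> frozenset[str]:
        non_leaves = set()
        for c, ps in self.parents.items():
            non_leaves.update(ps)
        return frozenset(self.parents) - non_leaves


def _finalize(parents: dict[str, set[str]]) -> Ontology:
    """Validate edges, resolve multiple roots, check acyclicity."""
    if not parents:
        raise OntologyError("empty ontology")
    known = set(parents)
    for child, ps in parents.items():
        unresolved = ps - known
        if unresolved:
            name = sorted(unresolved)[0]
            raise OntologyError(
                f"unresolvable parent reference {name!r} (child {child!r})"
            )
    roots = sorted(c for c, ps in parents.items() if not ps)
    if not roots:
        # every node has a parent: necessarily cyclic; fall through to the
        # cycle check below which names an offending concept
        pass
    elif len(roots) > 1:
        parents[VIRTUAL_ROOT] = set()
        for r in roots:
            parents[r] = {VIRTUAL_ROOT}
        roots = [VIRTUAL_ROOT]
    # Kahn's algorithm: detect cycles and unreachable-from-root nodes at once
    children: dict[str, set[str]] = {c: set() for c in parents}
    for child, ps in parents.items():
        for p in ps:
            children[p].add(child)
    indeg = {c: len(ps) for c, ps in parents.items()}
    queue = [c for c, d in indeg.items() if d == 0]
    visited = 0
    while queue:
        node = queue.pop()
        visited += 1
        for ch in children[node]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                queue.append(ch)
    if visited != len(parents):
        on_cycle = sorted(c for c, d in indeg.items() if d > 0)[0]
        raise OntologyError(f"cycle detected involving concept {on_cycle!r}")
    return Ontology(
        parents={c: frozenset(ps) for c, ps in parents.items()}, root=roots[0]
    )


def load_edge_table(source: Union[str, Path, TextIO]) -> Ontology:
    """Load a 2-column tab-separated child→parent edge table.

    The first line is a header and is skipped.  A child may appear on several
    lines (multiple parents); a parent-only concept is created implicitly.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    parents: dict[str, set[str]] = {}
    for line in lines[1:]:
        line = line.strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise OntologyError(f"malformed edge-table line: {line!r}")
        child, parent = fields[0].strip(), fields[1].strip()
        if not child or not parent:
            raise OntologyError(f"malformed edge-table line: {line!r}")
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
    return _finalize(parents)


def load_obo(source: Union[str, Path]) -> Ontology:
    """Load an OBO file, keeping only ``is_a`` edges.

    Obsolete terms are skipped; ``part_of`` and other relationship types are
    ignored, as IC and MICA are defined on the subsumption hierarchy only.
    """
    import obonet

    graph = obonet.read_obo(source, ignore_obsolete=True)
    parents: dict[str, set[str]] = {node: set() for node in graph.nodes}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    if not parents:
        raise OntologyError("empty ontology")
    return _finalize(parents)


def load_ontology(source: Union[str, Path, TextIO]) -> Ontology:
    """Load an ontology from an OBO file or a child→parent edge table.

    Dispatches on the ``.obo`` suffix; anything else is read as a
    tab-separated edge table with a one-line header.
    """
    if not hasattr(source, "read") and str(source).endswith(".obo"):
        return load_obo(source)
    return load_edge_table(source)


def compute_seco_ic(ontology: Ontology) -> dict[str, float]:
    """Intrinsic (Seco) information content for every concept.

    hypo(c) counts strict descendants; since ancestor sets are self-inclusive,
    it is the number of concepts whose ancestor set contains ``c``, minus one.
    """
    n = len(ontology)
    if n < 2:
        raise OntologyError(
            "Seco IC undefined for a single-concept ontology (log|V| = 0)"
        )
    counts = {c: 0 for c in ontology.parents}
    for c in ontology.parents:
        for a in ontology.ancestors(c):
            counts[a] += 1
    log_n = math.log(n)
    return {c: 1.0 - math.log(counts[c]) / log_n for c in counts}


def mica(ontology: Ontology, cx: str, cy: str, ic: Mapping[str, float] | None = None) -> str:
    """Most informative common ancestor of ``cx`` and ``cy``.

    Ancestor sets are self-inclusive, so mica(c, c) = c.  Ties on IC are
    broken toward the lexicographically smallest identifier for determinism.
    """
    if ic is None:
        ic = ontology.ic
    common = ontology.ancestors(cx) & ontology.ancestors(cy)
    return min(common, key=lambda c: (-ic[c], c))


def lin_similarity(
    ontology: Ontology,
    cx: str,
    cy: str,
    ic: Mapping[str, float] | None = None,
) -> float:
    """Lin similarity 2*IC(MICA)/(IC(x)+IC(y)) in [0, 1].

    Degenerate zero denominator (both concepts are the root): 1 if the
    concepts are identical, else 0 — the identity case stays continuous and
    no information is shared otherwise.
    """
    if ic is None:
        ic = ontology.ic
    if cx not in ic or cy not in ic:
        missing = cx if cx not in ic else cy
        raise OntologyError(f"unknown concept: {missing!r}")
    denom = ic[cx] + ic[cy]
    if denom == 0.0:
        return 1.0 if cx == cy else 0.0
    m = mica(ontology, cx, cy, ic)
    return 2.0 * ic[m] / denom


@dataclass
class PairwiseSimMatrix:
    """Lin similarities over an ordered concept pool.

    ``values[i, j]`` is the similarity of ``pool[i]`` and ``pool[j]``; the
    matrix is symmetric with entries in [0, 1].  ``index`` maps concept id to
    matrix position.
    """

    pool: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.index: dict[str, int] = {c: i for i, c in enumerate(self.pool)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        cx, cy = pair
        return float(self.values[self.index[cx], self.index[cy]])

    def rows(self, concepts: Iterable[str]) -> np.ndarray:
        """Positions of ``concepts`` in the pool, in canonical sorted order."""
        try:
            return np.array(sorted(self.index[c] for c in concepts), dtype=np.intp)
        except KeyError as exc:
            raise OntologyError(f"concept not in similarity pool: {exc.args[0]!r}")

    def submatrix(self, a: Iterable[str], b: Iterable[str]) -> np.ndarray:
        """Similarity block with rows from ``a`` and columns from ``b``."""
        return self.values[np.ix_(self.rows(a), self.rows(b))]


def build_sim_matrix(
    ontology: Ontology,
    pool: Sequence[str],
    ic: Mapping[str, float] | None = None,
) -> PairwiseSimMatrix:
    """Precompute all pairwise Lin similarities over ``pool``.

    The pool order is preserved as given; a sorted pool gives the canonical
    concept ordering the search relies on for reproducible traces.
    """
    if len(pool) == 0:
        raise OntologyError("empty concept pool")
    if ic is None:
        ic = ontology.ic
    for c in pool:
        if c not in ontology:
            raise OntologyError(f"unknown concept: {c!r}")
    n = len(pool)
    values = np.empty((n, n), dtype=np.float64)
    for i, ci in enumerate(pool):
        values[i, i] = lin_similarity(ontology, ci, ci, ic)
        for j in range(i + 1, n):
            s = lin_similarity(ontology, ci, pool[j], ic)
            values[i, j] = values[j, i] = s
    return PairwiseSimMatrix(pool=tuple(pool), values=values)


def write_ic_table(ontology: Ontology, path: Union[str, Path]) -> None:
    """Export concept→IC as tab-separated values, 6 decimal places."""
    ic = ontology.ic
    with open(path, "w") as fh:
        fh.write("concept\tic\n")
        for c in sorted(ic):
            fh.write(f"{c}\t{ic[c]:.6f}\n")
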