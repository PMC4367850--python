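"""Seeded synthetic fixtures: ontologies, gold annotations, neighbor lists.

The generators emulate the statistical setting the annotation method
assumes — similar documents are similarly annotated.  A random rooted DAG
stands in for the domain ontology; a gold concept set is drawn for the
target document; each neighbor's annotation is the gold set perturbed
concept-wise (dropped, substituted by a parent/child/sibling, or joined by
an unrelated concept), and neighbors are ranked by their BMA similarity to
the gold — a stand-in for a retrieval engine's proximity scores.  Everything
is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .corpus import DocumentRecord, RankedNeighborList
from .objective import sim_bma
from .ontology import Ontology, build_sim_matrix

__all__ = [
    "PerturbationConfig",
    "generate_ontology",
    "generate_instance",
    "write_edge_table",
    "write_obo",
]


@dataclass(frozen=True)
class PerturbationConfig:
    """Concept-wise noise applied to the gold annotation of each neighbor.

    p_substitute — probability a gold concept is replaced by a uniformly
    drawn parent, child or sibling (sibling = shares >= 1 parent); p_drop —
    probability it is omitted; p_add — probability an unrelated concept is
    added alongside it.  The ontology root is never drawn as a substitution
    or addition target (it carries no information content).
    """

    p_substitute: float = 0.0
    p_drop: float = 0.0
    p_add: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_substitute", "p_drop", "p_add"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def generate_ontology(n_concepts: int, max_parents: int = 2, seed: int = 0) -> Ontology:
    """Random rooted connected DAG, deterministic per seed.

    Concepts are added in order; each non-root concept attaches to
    1..max_parents uniformly chosen earlier concepts, so every concept
    reaches the single root and the graph is acyclic by construction.
    max_parents=1 yields a tree.
    """
    if n_concepts < 2:
        raise ValueError("need at least 2 concepts")
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    rng = np.random.default_rng(seed)
    names = [f"C{i:04d}" for i in range(n_concepts)]
    parents: dict[str, frozenset[str]] = {names[0]: frozenset()}
    for i in range(1, n_concepts):
        n_par = int(rng.integers(1, min(max_parents, i) + 1))
        chosen = rng.choice(i, size=n_par, replace=False)
        parents[names[i]] = frozenset(names[j] for j in chosen)
    return Ontology(parents=parents, root=names[0])


def _relatives(ontology: Ontology, children: dict[str, set[str]], c: str) -> list[str]:
    """Parents, children and siblings of ``c``, root excluded, sorted."""
    rel: set[str] = set(ontology.parents[c]) | children[c]
    for p in ontology.parents[c]:
        rel.update(children[p])
    rel.discard(c)
    rel.discard(ontology.root)
    return sorted(rel)


def generate_instance(
    ontology: Ontology,
    gold_size: int,
    n_neighbors: int,
    cfg: PerturbationConfig,
    target_id: str = "target",
    max_retries: int = 20,
) -> tuple[frozenset[str], RankedNeighborList]:
    """One document: a gold annotation plus perturbed, ranked neighbors.

    The gold set is drawn uniformly without replacement from the non-root
    concepts.  Each neighbor perturbs gold concept-wise per the config; a
    neighbor whose annotation comes out empty is redrawn (bounded retries).
    Neighbors are ranked by BMA similarity to the gold, descending.
    """
    non_root = sorted(set(ontology.parents) - {ontology.root})
    if gold_size < 1 or gold_size > len(non_root):
        raise ValueError(f"gold_size {gold_size} out of range")
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    gold = frozenset(str(c) for c in rng.choice(non_root, size=gold_size, replace=False))

    children: dict[str, set[str]] = {c: set() for c in ontology.parents}
    for child, ps in ontology.parents.items():
        for p in ps:
            children[p].add(child)

    annotations: list[frozenset[str]] = []
    for _ in range(n_neighbors):
        ann: frozenset[str] | None = None
        for _attempt in range(max_retries):
            drawn = _perturb(gold, ontology, children, non_root, cfg, rng)
            if drawn:
                ann = drawn
                break
        if ann is None:
            raise RuntimeError(
                "perturbation kept emptying a neighbor annotation "
                f"(p_drop={cfg.p_drop}); giving up after {max_retries} retries"
            )
        annotations.append(ann)

    union = sorted(set().union(gold, *annotations))
    m = build_sim_matrix(ontology, union)
    scores = [sim_bma(ann, gold, m) for ann in annotations]
    order = sorted(range(n_neighbors), key=lambda i: (-scores[i], i))
    neighbors = [
        (
            DocumentRecord(doc_id=f"{target_id}-n{i:03d}", concepts=annotations[i]),
            rank,
            scores[i],
        )
        for rank, i in enumerate(order, start=1)
    ]
    return gold, RankedNeighborList(target_id=target_id, neighbors=neighbors, gold=gold)


def _perturb(
    gold: frozenset[str],
    ontology: Ontology,
    children: dict[str, set[str]],
    non_root: list[str],
    cfg: PerturbationConfig,
    rng: np.random.Generator,
) -> frozenset[str]:
    ann: set[str] = set()
    for c in sorted(gold):
        u = rng.random()
        if u < cfg.p_drop:
            pass
        elif u < cfg.p_drop + cfg.p_substitute:
            rel = _relatives(ontology, children, c)
            ann.add(str(rng.choice(rel)) if rel else c)
        else:
            ann.add(c)
        if cfg.p_add > 0 and rng.random() < cfg.p_add:
            extras = [x for x in non_root if x not in gold and x not in ann]
            if extras:
                ann.add(str(rng.choice(extras)))
    return frozenset(ann)


def write_edge_table(ontology: Ontology, path: Union[str, Path]) -> None:
    """Write the child→parent tab-separated format the loader reads."""
    with open(path, "w") as fh:
        fh.write("child\tparent\n")
        for child in sorted(ontology.parents):
            for parent in sorted(ontology.parents[child]):
                fh.write(f"{child}\t{parent}\n")


def write_obo(ontology: Ontology, path: Union[str, Path]) -> None:
    """Write a minimal OBO rendering (id, name, is_a) of the ontology."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for concept in sorted(ontology.parents):
            fh.write(f"\n[Term]\nid: {concept}\nname: {concept}\n")
            for parent in sorted(ontology.parents[concept]):
                fh.write(f"is_a: {parent} ! {parent}\n")
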