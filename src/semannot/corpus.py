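"""Documents, ranked neighbor lists and candidate concept pools.

A document to annotate comes with an ordered list of related documents
(produced upstream by any retrieval engine; rankings are consumed, never
computed here).  The k nearest *annotated* neighbors supply the candidate
pool A0 — the union of their concept sets — optionally pre-filtered to the
concepts supported by at least ``min_docs`` neighbor annotations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, Union

logger = logging.getLogger(__name__)

__all__ = [
    "DocumentRecord",
    "RankedNeighborList",
    "NeighborSet",
    "CorpusError",
    "select_topk",
    "build_candidate_pool",
    "filter_candidate_pool",
    "read_neighbor_file",
    "write_neighbor_file",
    "iter_neighbor_files",
]


class CorpusError(ValueError):
    """Raised for malformed neighbor files or unsatisfiable selections."""


@dataclass(frozen=True)
class DocumentRecord:
    doc_id: str
    concepts: frozenset[str] | None = None
    title: str | None = None

    @property
    def is_annotated(self) -> bool:
        return bool(self.concepts)


@dataclass
class RankedNeighborList:
    """Ordered related documents for one target, with rank and score."""

    target_id: str
    neighbors: list[tuple[DocumentRecord, int, float]]
    gold: frozenset[str] | None = None

    def __post_init__(self) -> None:
        ranks = [r for _, r, _ in self.neighbors]
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise CorpusError(
                f"{self.target_id}: neighbor ranks must be strictly increasing"
            )
        seen: set[str] = set()
        for rec, _, _ in self.neighbors:
            if not rec.doc_id:
                raise CorpusError("empty doc_id in neighbor list")
            if rec.doc_id in seen:
                raise CorpusError(f"duplicate doc_id {rec.doc_id!r}")
            seen.add(rec.doc_id)

    def annotated(self) -> list[DocumentRecord]:
        return [rec for rec, _, _ in self.neighbors if rec.is_annotated]


@dataclass
class NeighborSet:
    """The selected k-NN set K; every member carries a non-empty annotation."""

    members: list[DocumentRecord]
    k: int = field(default=0)

    def __post_init__(self) -> None:
        if self.k == 0:
            self.k = len(self.members)
        if len(self.members) != self.k:
            raise CorpusError(f"expected {self.k} members, got {len(self.members)}")
        for rec in self.members:
            if not rec.is_annotated:
                raise CorpusError(f"neighbor {rec.doc_id!r} has no annotation")

    @property
    def annotations(self) -> list[frozenset[str]]:
        return [rec.concepts for rec in self.members]  # type: ignore[misc]

    def __len__(self) -> int:
        return len(self.members)


def select_topk(ranked: RankedNeighborList, k: int) -> NeighborSet:
    """Top-k annotated neighbors in rank order.

    Unannotated neighbors are skipped without consuming a slot: retrieval
    engines may return neighbors whose annotations are missing, and an
    annotation-less neighbor contributes nothing to the pool.
    """
    if k < 1:
        raise CorpusError("k must be positive")
    annotated = ranked.annotated()
    if len(annotated) < k:
        raise CorpusError(
            f"{ranked.target_id}: requested k={k} but only "
            f"{len(annotated)} annotated neighbors are available"
        )
    return NeighborSet(members=annotated[:k], k=k)


def build_candidate_pool(neighbors: NeighborSet) -> frozenset[str]:
    """A0: union of the k-NN annotations — the search space of the heuristic."""
    pool: set[str] = set()
    for ann in neighbors.annotations:
        pool.update(ann)
    return frozenset(pool)


def filter_candidate_pool(
    neighbors: NeighborSet, min_docs: int = 2, fallback: bool = True
) -> frozenset[str]:
    """Concepts annotating at least ``min_docs`` of the k-NNs.

    ``min_docs=1`` reduces to the unfiltered pool.  Concepts supported by a
    single neighbor are often too document-specific to describe the target;
    dropping them shrinks the search space and its noise.  If the filter
    empties the pool and ``fallback`` is true, the unfiltered pool is
    returned with a warning (an empty suggestion is useless).
    """
    if min_docs < 1:
        raise CorpusError("min_docs must be >= 1")
    freq: dict[str, int] = {}
    for ann in neighbors.annotations:
        for c in ann:
            freq[c] = freq.get(c, 0) + 1
    kept = frozenset(c for c, n in freq.items() if n >= min_docs)
    if not kept and fallback:
        logger.warning(
            "min_docs=%d filter emptied the candidate pool; "
            "falling back to the unfiltered pool",
            min_docs,
        )
        return frozenset(freq)
    return kept


def read_neighbor_file(path: Union[str, Path]) -> RankedNeighborList:
    """Read a JSON-Lines neighbor file.

    One object per neighbor: ``{"doc_id", "rank", "score", "title"?,
    "concepts"?: [ids]}``.  An optional header object may carry ``"gold"``
    (and ``"target_id"``); otherwise the target id is the file stem.
    """
    path = Path(path)
    target_id = path.stem
    gold: frozenset[str] | None = None
    neighbors: list[tuple[DocumentRecord, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid JSON ({exc})")
            if "doc_id" not in obj:
                # header object
                if "gold" in obj:
                    gold = frozenset(obj["gold"])
                if "target_id" in obj:
                    target_id = str(obj["target_id"])
                continue
            concepts = obj.get("concepts")
            rec = DocumentRecord(
                doc_id=str(obj["doc_id"]),
                concepts=frozenset(concepts) if concepts else None,
                title=obj.get("title"),
            )
            try:
                rank = int(obj["rank"])
                score = float(obj.get("score", 0.0))
            except (KeyError, TypeError, ValueError):
                raise CorpusError(f"{path}:{lineno}: missing or invalid rank/score")
            neighbors.append((rec, rank, score))
    return RankedNeighborList(target_id=target_id, neighbors=neighbors, gold=gold)


def write_neighbor_file(ranked: RankedNeighborList, path: Union[str, Path]) -> None:
    """Write the JSON-Lines neighbor format read by :func:`read_neighbor_file`."""
    with open(path, "w") as fh:
        header: dict = {"target_id": ranked.target_id}
        if ranked.gold is not None:
            header["gold"] = sorted(ranked.gold)
        fh.write(json.dumps(header) + "\n")
        for rec, rank, score in ranked.neighbors:
            obj: dict = {"doc_id": rec.doc_id, "rank": rank, "score": score}
            if rec.title is not None:
                obj["title"] = rec.title
            if rec.concepts is not None:
                obj["concepts"] = sorted(rec.concepts)
            fh.write(json.dumps(obj) + "\n")


def iter_neighbor_files(directory: Union[str, Path]) -> Iterator[RankedNeighborList]:
    """Yield neighbor lists for every ``*.jsonl`` file in a directory."""
    for path in sorted(Path(directory).glob("*.jsonl")):
        yield read_neighbor_file(path)
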