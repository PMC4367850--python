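"""2D semantic maps of candidate neighbors, and click-based k-NN selection.

Rather than trusting the retrieval ranking, a curator can pick the k-NN set
spatially: the annotated candidate documents are embedded in the plane by
classical (Torgerson) multidimensional scaling of their pairwise BMA
dissimilarities d(i,j) = 1 - sim_bma(A_i, A_j), and the k documents closest
to a clicked point become the neighbor set.  Benchmark mode simulates the
expert click by jointly embedding a pseudo-document carrying the gold
annotation and clicking on its coordinates.

Classical MDS is used deliberately: it is a deterministic eigendecomposition
(no random initialisation, no iteration), adequate at the tens-of-documents
scale maps are drawn at.  Negative eigenvalues of the double-centered matrix
(non-Euclidean dissimilarities) are clamped to zero, as usual.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .corpus import DocumentRecord, NeighborSet
from .objective import sim_bma
from .ontology import Ontology, build_sim_matrix

__all__ = [
    "MapEmbedding",
    "embed_documents",
    "click_select",
    "gold_click",
    "classical_mds",
    "write_map",
]


@dataclass
class MapEmbedding:
    """2D coordinates for an ordered set of documents.

    Coordinates are dimensionless and defined up to rotation/reflection;
    compare inter-point distances, not raw axes.  ``stress`` is Kruskal's
    stress-1 of the embedded distances against the input dissimilarities.
    """

    doc_ids: list[str]
    coordinates: np.ndarray  # (n, 2)
    stress: float
    records: list[DocumentRecord] | None = None

    def __post_init__(self) -> None:
        if self.coordinates.shape != (len(self.doc_ids), 2):
            raise ValueError("one 2D coordinate pair per document required")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")


def classical_mds(dissimilarity: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, float]:
    """Torgerson scaling of a symmetric zero-diagonal dissimilarity matrix.

    Double-centers the squared dissimilarities, eigendecomposes, clamps
    negative eigenvalues to zero and returns the top ``n_components``
    coordinates plus the stress-1 of the result.
    """
    d = np.asarray(dissimilarity, dtype=np.float64)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9) or not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d * d) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:n_components]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    if coords.shape[1] < n_components:
        coords = np.pad(coords, ((0, 0), (0, n_components - coords.shape[1])))
    emb_d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    denom = float((d * d).sum())
    stress = float(np.sqrt(((emb_d - d) ** 2).sum() / denom)) if denom > 0 else 0.0
    return coords, stress


def _bma_dissimilarity(
    annotations: Sequence[frozenset[str]], ontology: Ontology
) -> np.ndarray:
    union = sorted(set().union(*annotations))
    m = build_sim_matrix(ontology, union)
    n = len(annotations)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - sim_bma(annotations[i], annotations[j], m)
    return d


def embed_documents(
    candidates: Sequence[DocumentRecord], ontology: Ontology
) -> MapEmbedding:
    """Embed annotated candidates in 2D so BMA similarities are respected."""
    if len(candidates) < 3:
        raise ValueError("at least 3 annotated candidates are required for a map")
    annotations = []
    for rec in candidates:
        if not rec.is_annotated:
            raise ValueError(f"candidate {rec.doc_id!r} has no annotation")
        annotations.append(rec.concepts)
    d = _bma_dissimilarity(annotations, ontology)
    coords, stress = classical_mds(d)
    return MapEmbedding(
        doc_ids=[r.doc_id for r in candidates],
        coordinates=coords,
        stress=stress,
        records=list(candidates),
    )


def click_select(
    embedding: MapEmbedding, click: tuple[float, float], k: int
) -> NeighborSet:
    """The k documents closest (Euclidean) to the clicked map point.

    Distance ties are broken by original retrieval rank, i.e. by position in
    the embedding's document order.
    """
    n = len(embedding.doc_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} embedded documents")
    if embedding.records is None:
        raise ValueError("embedding carries no document records to select from")
    point = np.asarray(click, dtype=np.float64)
    dist = np.sqrt(((embedding.coordinates - point) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")[:k]
    return NeighborSet(members=[embedding.records[i] for i in sorted(order)], k=k)


def gold_click(
    candidates: Sequence[DocumentRecord],
    gold: frozenset[str],
    ontology: Ontology,
) -> tuple[tuple[float, float], MapEmbedding]:
    """Simulated expert click: where the gold annotation falls on the map.

    A pseudo-document carrying the gold annotation is embedded *jointly* with
    the candidates in a single MDS run; its coordinates are the click point.
    Returns the click and the candidates-only restriction of the joint
    embedding, so the click and the map share one geometry.
    """
    if not gold:
        raise ValueError("gold annotation is empty")
    if len(candidates) < 3:
        raise ValueError("at least 3 annotated candidates are required for a map")
    annotations = [rec.concepts for rec in candidates]
    if any(a is None or not a for a in annotations):
        raise ValueError("every candidate must be annotated")
    joint = list(annotations) + [frozenset(gold)]
    d = _bma_dissimilarity(joint, ontology)
    coords, stress = classical_mds(d)
    click = (float(coords[-1, 0]), float(coords[-1, 1]))
    embedding = MapEmbedding(
        doc_ids=[r.doc_id for r in candidates],
        coordinates=coords[:-1],
        stress=stress,
        records=list(candidates),
    )
    return click, embedding


def write_map(embedding: MapEmbedding, path: Union[str, Path]) -> None:
    """Export the map as tab-separated doc_id, x, y."""
    with open(path, "w") as fh:
        fh.write("doc_id\tx\ty\n")
        for doc_id, (x, y) in zip(embedding.doc_ids, embedding.coordinates):
            fh.write(f"{doc_id}\t{x:.6f}\t{y:.6f}\n")
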