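import pytest

from semannot import DocumentRecord, NeighborSet, Ontology


@pytest.fixture
def chain_ontology():
    """r <- a <- b: the 3-concept chain used for hand-computed values."""
    return Ontology(
        parents={"r": frozenset(), "a": frozenset({"r"}), "b": frozenset({"a"})},
        root="r",
    )


@pytest.fixture
def star_ontology():
    """6 concepts: a root with five leaf children c1..c5.

    All leaves have IC 1 and pairwise Lin 0 (their MICA is the root), which
    makes objective values easy to verify by hand.
    """
    parents = {"root": frozenset()}
    for i in range(1, 6):
        parents[f"c{i}"] = frozenset({"root"})
    return Ontology(parents=parents, root="root")


@pytest.fixture
def figure_neighbors():
    """Three neighbors annotated {c1,c2}, {c2,c3}, {c3,c4,c5}."""
    return NeighborSet(
        members=[
            DocumentRecord("d1", frozenset({"c1", "c2"})),
            DocumentRecord("d2", frozenset({"c2", "c3"})),
            DocumentRecord("d3", frozenset({"c3", "c4", "c5"})),
        ]
    )
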