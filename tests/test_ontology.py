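import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semannot import (
    Ontology,
    OntologyError,
    build_sim_matrix,
    compute_seco_ic,
    lin_similarity,
    load_ontology,
    mica,
)
from semannot.ontology import VIRTUAL_ROOT, load_edge_table, load_obo, write_ic_table
from semannot.synthetic import generate_ontology, write_obo

CHAIN_LIN_AB = 2 * (1 - math.log(2) / math.log(3)) / (1 + (1 - math.log(2) / math.log(3)))


def edge_table(*edges):
    return io.StringIO("child\tparent\n" + "".join(f"{c}\t{p}\n" for c, p in edges))


class TestLoading:
    def test_minimal_tree(self):
        onto = load_edge_table(edge_table(("b", "a"), ("c", "a")))
        assert onto.root == "a"
        assert onto.leaves() == {"b", "c"}

    def test_chain(self):
        onto = load_edge_table(
            edge_table(("a", "r"), ("b", "a"), ("c", "b"), ("d", "c"))
        )
        assert onto.root == "r"
        assert onto.leaves() == {"d"}
        assert len(onto) == 5

    def test_smallest_cycle_rejected(self):
        with pytest.raises(OntologyError, match="cycle"):
            load_edge_table(edge_table(("a", "b"), ("b", "a")))

    def test_empty_rejected(self):
        with pytest.raises(OntologyError, match="empty"):
            load_edge_table(io.StringIO("child\tparent\n"))

    def test_multiple_roots_joined_under_virtual_root(self):
        onto = load_edge_table(edge_table(("x", "r1"), ("y", "r2")))
        assert onto.root == VIRTUAL_ROOT
        assert onto.ic[VIRTUAL_ROOT] == 0.0
        # MICA of concepts from the two components exists
        assert mica(onto, "x", "y") == VIRTUAL_ROOT

    def test_obo_round_trip_and_relation_filtering(self, tmp_path):
        onto = generate_ontology(25, 2, seed=5)
        path = tmp_path / "onto.obo"
        write_obo(onto, path)
        reloaded = load_obo(path)
        assert reloaded.parents == onto.parents

    def test_obo_skips_obsolete_and_non_isa(self, tmp_path):
        text = (
            "format-version: 1.2\n\n"
            "[Term]\nid: A\nname: a\n\n"
            "[Term]\nid: B\nname: b\nis_a: A ! a\nrelationship: part_of A\n\n"
            "[Term]\nid: C\nname: c\nis_a: A ! a\nis_obsolete: true\n"
        )
        path = tmp_path / "t.obo"
        path.write_text(text)
        onto = load_ontology(str(path))
        assert "C" not in onto
        assert onto.parents["B"] == {"A"}


class TestAncestors:
    def test_chain_self_inclusive(self, chain_ontology):
        assert chain_ontology.ancestors("b") == {"b", "a", "r"}

    def test_root(self, chain_ontology):
        assert chain_ontology.ancestors("r") == {"r"}

    def test_diamond(self):
        onto = load_edge_table(
            edge_table(("p", "r"), ("q", "r"), ("c", "p"), ("c", "q"))
        )
        assert onto.ancestors("c") == {"c", "p", "q", "r"}

    def test_unknown_concept(self, chain_ontology):
        with pytest.raises(OntologyError, match="unknown"):
            chain_ontology.ancestors("nope")


class TestSecoIC:
    def test_leaf_and_root(self, chain_ontology):
        ic = compute_seco_ic(chain_ontology)
        assert ic["b"] == 1.0
        assert ic["r"] == 0.0

    def test_chain_intermediate(self, chain_ontology):
        ic = compute_seco_ic(chain_ontology)
        assert ic["a"] == pytest.approx(1 - math.log(2) / math.log(3), abs=1e-12)

    def test_single_concept_rejected(self):
        onto = Ontology(parents={"r": frozenset()}, root="r")
        with pytest.raises(OntologyError):
            compute_seco_ic(onto)


class TestMicaAndLin:
    def test_mica_self(self, chain_ontology):
        assert mica(chain_ontology, "a", "a") == "a"

    def test_mica_chain(self, chain_ontology):
        assert mica(chain_ontology, "a", "b") == "a"

    def test_mica_through_root(self):
        onto = load_edge_table(
            edge_table(("a", "r"), ("b", "r"), ("x", "a"), ("y", "b"))
        )
        assert mica(onto, "x", "y") == "r"

    def test_mica_tie_breaks_lexicographically(self):
        # p and q are both MICAs of c and d with equal IC
        onto = load_edge_table(
            edge_table(("p", "r"), ("q", "r"), ("c", "p"), ("c", "q"),
                       ("d", "p"), ("d", "q"))
        )
        assert onto.ic["p"] == onto.ic["q"]
        assert mica(onto, "c", "d") == "p"

    def test_lin_self_is_one(self, chain_ontology):
        assert lin_similarity(chain_ontology, "b", "b") == 1.0

    def test_lin_through_root_is_zero(self, star_ontology):
        assert lin_similarity(star_ontology, "c1", "c2") == 0.0

    def test_lin_chain_value(self, chain_ontology):
        assert lin_similarity(chain_ontology, "a", "b") == pytest.approx(
            CHAIN_LIN_AB, abs=1e-12
        )

    def test_lin_root_root_degenerate(self, chain_ontology):
        assert lin_similarity(chain_ontology, "r", "r") == 1.0

    def test_lin_unknown_concept(self, chain_ontology):
        with pytest.raises(OntologyError):
            lin_similarity(chain_ontology, "a", "zz")


class TestSimMatrix:
    def test_singleton(self, chain_ontology):
        m = build_sim_matrix(chain_ontology, ["b"])
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == 1.0

    def test_root_mica_off_diagonal(self, star_ontology):
        m = build_sim_matrix(star_ontology, ["c1", "c2"])
        assert m.values[0, 1] == 0.0

    def test_chain_off_diagonal(self, chain_ontology):
        m = build_sim_matrix(chain_ontology, ["a", "b"])
        assert m.values[0, 1] == pytest.approx(CHAIN_LIN_AB, abs=1e-12)

    def test_unknown_concept_named(self, chain_ontology):
        with pytest.raises(OntologyError, match="bogus"):
            build_sim_matrix(chain_ontology, ["a", "bogus"])

    def test_matches_elementwise_lin(self):
        onto = generate_ontology(20, 2, seed=11)
        pool = sorted(onto.parents)[:8]
        m = build_sim_matrix(onto, pool)
        for i, ci in enumerate(pool):
            for j, cj in enumerate(pool):
                assert m.values[i, j] == pytest.approx(
                    lin_similarity(onto, ci, cj), abs=1e-15
                )


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(5, 40), mp=st.integers(1, 3))
def test_ic_monotone_and_lin_symmetric_bounded(seed, n, mp):
    """IC never decreases along specialisation; Lin is symmetric in [0,1]."""
    onto = generate_ontology(n, mp, seed=seed)
    ic = onto.ic
    for c, parents in onto.parents.items():
        for p in parents:
            assert ic[p] <= ic[c] + 1e-12
    rng = np.random.default_rng(seed)
    concepts = sorted(onto.parents)
    for _ in range(10):
        x, y = rng.choice(concepts, size=2)
        sxy = lin_similarity(onto, x, y)
        assert 0.0 <= sxy <= 1.0 + 1e-12
        assert sxy == pytest.approx(lin_similarity(onto, y, x), abs=1e-15)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_mica_matches_brute_force(seed):
    """MICA is a common ancestor of maximal IC (brute-force intersection)."""
    onto = generate_ontology(15, 2, seed=seed)
    ic = onto.ic
    concepts = sorted(onto.parents)
    rng = np.random.default_rng(seed)
    for _ in range(10):
        x, y = rng.choice(concepts, size=2)
        common = onto.ancestors(x) & onto.ancestors(y)
        best_ic = max(ic[c] for c in common)
        m = mica(onto, x, y)
        assert m in common
        assert ic[m] == pytest.approx(best_ic, abs=1e-15)


def test_ic_table_export(tmp_path, chain_ontology):
    path = tmp_path / "ic.tsv"
    write_ic_table(chain_ontology, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "concept\tic"
    assert lines[1] == "a\t0.369070"
    assert lines[3] == "r\t0.000000"
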