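import numpy as np
import pytest

from semannot import (
    DocumentRecord,
    NeighborSet,
    ObjectiveConfig,
    annotate,
    build_sim_matrix,
    exhaustive_best,
    hill_climb_naive,
    hill_climb_optimized,
    objective_f,
)
from semannot.experiments import random_instance
from semannot.ontology import OntologyError
from semannot.synthetic import PerturbationConfig, generate_instance, generate_ontology


class TestExhaustive:
    def test_single_concept(self, star_ontology):
        m = build_sim_matrix(star_ontology, ["c1"])
        best, f = exhaustive_best({"c1"}, [{"c1"}] * 3, ObjectiveConfig(0.0), m)
        assert best == {"c1"}
        assert f == pytest.approx(1.0)

    def test_exact_neighbor_annotation_is_optimal(self, star_ontology):
        m = build_sim_matrix(star_ontology, ["c1", "c2", "c3"])
        pool = {"c1", "c2", "c3"}
        best, f = exhaustive_best(pool, [pool], ObjectiveConfig(0.0), m)
        assert best == pool
        assert f == pytest.approx(1.0)

    def test_matches_python_enumeration(self):
        # cross-check the vectorized enumeration against objective_f
        import itertools

        rng = np.random.default_rng(4)
        inst = random_instance(rng, max_pool=7, max_neighbors=4)
        cfg = ObjectiveConfig(0.02)
        best, f = exhaustive_best(inst.pool, inst.neighbors, cfg, inst.matrix)
        concepts = sorted(inst.pool)
        expected_f = max(
            objective_f(sub, inst.neighbors, cfg, inst.matrix)
            for r in range(1, len(concepts) + 1)
            for sub in itertools.combinations(concepts, r)
        )
        assert f == pytest.approx(expected_f, abs=1e-12)
        assert objective_f(best, inst.neighbors, cfg, inst.matrix) == pytest.approx(
            f, abs=1e-12
        )

    def test_size_guard(self, star_ontology):
        m = build_sim_matrix(star_ontology, ["c1"])
        with pytest.raises(ValueError, match="guard"):
            exhaustive_best([f"x{i}" for i in range(25)], [{"c1"}], ObjectiveConfig(), m)

    def test_empty_pool(self, star_ontology):
        m = build_sim_matrix(star_ontology, ["c1"])
        with pytest.raises(ValueError):
            exhaustive_best(set(), [{"c1"}], ObjectiveConfig(), m)


class TestNaiveClimb:
    def test_identical_neighbors_keep_everything(self, star_ontology):
        # every removal strictly lowers the BMA term, so nothing is removed
        m = build_sim_matrix(star_ontology, ["c1", "c2", "c3"])
        pool = {"c1", "c2", "c3"}
        res = hill_climb_naive(pool, [pool] * 3, ObjectiveConfig(0.0), m)
        assert res.annotation == pool
        assert res.trace == []
        assert res.objective == pytest.approx(1.0)

    def test_unrelated_concept_removed_first_round(self, star_ontology):
        # c5 never appears in a neighbor annotation and has Lin 0 to all of
        # them; with mu > 0 removing it increases f by at least mu
        m = build_sim_matrix(star_ontology, ["c1", "c2", "c5"])
        neighbors = [{"c1", "c2"}, {"c1", "c2"}]
        cfg = ObjectiveConfig(0.05)
        res = hill_climb_naive({"c1", "c2", "c5"}, neighbors, cfg, m)
        assert res.trace[0] == "c5"
        assert "c5" not in res.annotation
        f_before = objective_f({"c1", "c2", "c5"}, neighbors, cfg, m)
        f_after = objective_f({"c1", "c2"}, neighbors, cfg, m)
        assert f_after - f_before >= 0.05

    def test_never_beats_exhaustive(self):
        rng = np.random.default_rng(7)
        for i in range(25):
            inst = random_instance(rng, max_pool=8, max_neighbors=5)
            cfg = ObjectiveConfig((0.0, 0.02, 0.1)[i % 3])
            res = hill_climb_naive(inst.pool, inst.neighbors, cfg, inst.matrix)
            _, f_opt = exhaustive_best(inst.pool, inst.neighbors, cfg, inst.matrix)
            assert res.objective <= f_opt + 1e-9

    def test_first_improvement_strategy_runs(self, star_ontology):
        m = build_sim_matrix(star_ontology, ["c1", "c2", "c5"])
        res = hill_climb_naive(
            {"c1", "c2", "c5"}, [{"c1", "c2"}], ObjectiveConfig(0.05), m,
            strategy="first",
        )
        assert "c5" not in res.annotation
        with pytest.raises(ValueError):
            hill_climb_naive({"c1"}, [{"c1"}], ObjectiveConfig(), m, strategy="bogus")

    def test_empty_pool(self, star_ontology):
        m = build_sim_matrix(star_ontology, ["c1"])
        with pytest.raises(ValueError):
            hill_climb_naive(set(), [{"c1"}], ObjectiveConfig(), m)


class TestOptimizedClimb:
    def test_equivalent_to_naive_on_random_instances(self):
        rng = np.random.default_rng(11)
        mus = (0.0, 0.005, 0.02, 0.1)
        for i in range(40):
            inst = random_instance(rng, max_pool=25, max_neighbors=10)
            cfg = ObjectiveConfig(mus[i % 4])
            naive = hill_climb_naive(inst.pool, inst.neighbors, cfg, inst.matrix)
            opt = hill_climb_optimized(
                inst.pool, inst.neighbors, cfg, inst.matrix, debug=True
            )
            assert opt.trace == naive.trace
            assert opt.annotation == naive.annotation
            assert opt.objective == pytest.approx(naive.objective, abs=1e-9)
            assert opt.debug_max_dev < 1e-9

    def test_monotone_ascent_and_never_below_start(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            inst = random_instance(rng, max_pool=20, max_neighbors=8)
            cfg = ObjectiveConfig(0.02)
            res = hill_climb_optimized(inst.pool, inst.neighbors, cfg, inst.matrix)
            current = set(inst.pool)
            f_prev = objective_f(current, inst.neighbors, cfg, inst.matrix)
            assert res.objective >= f_prev - 1e-12
            for c in res.trace:
                current.remove(c)
                f_now = objective_f(current, inst.neighbors, cfg, inst.matrix)
                assert f_now > f_prev
                f_prev = f_now
            assert f_prev == pytest.approx(res.objective, abs=1e-9)

    def test_final_state_matches_recomputation(self):
        rng = np.random.default_rng(17)
        inst = random_instance(rng, max_pool=20, max_neighbors=8)
        res = hill_climb_optimized(
            inst.pool, inst.neighbors, ObjectiveConfig(0.1), inst.matrix, debug=True
        )
        assert res.debug_max_dev < 1e-9


class TestAnnotate:
    def test_figure_fixture_filter_pool(self, star_ontology):
        from semannot import RankedNeighborList

        ranked = RankedNeighborList(
            "fig",
            [
                (DocumentRecord("d1", frozenset({"c1", "c2"})), 1, 0.9),
                (DocumentRecord("d2", frozenset({"c2", "c3"})), 2, 0.8),
                (DocumentRecord("d3", frozenset({"c3", "c4", "c5"})), 3, 0.7),
            ],
        )
        res = annotate(ranked, star_ontology, k=3, use_filter=True)
        assert res.pool == {"c2", "c3"}
        assert res.filtered is True

    def test_identically_annotated_neighbors_returned_verbatim(self):
        onto = generate_ontology(30, 2, seed=1)
        gold, ranked = generate_instance(onto, 5, 20, PerturbationConfig(seed=2))
        res = annotate(ranked, onto, k=20, mu=0.0)
        assert res.suggested == gold
        assert res.k_used == 20

    def test_zero_noise_recovers_gold(self):
        onto = generate_ontology(45, 3, seed=9)
        gold, ranked = generate_instance(onto, 6, 10, PerturbationConfig(seed=10))
        res = annotate(ranked, onto, k=10, mu=0.0)
        assert res.suggested == gold

    def test_unresolvable_concepts_listed(self, star_ontology):
        from semannot import RankedNeighborList

        ranked = RankedNeighborList(
            "bad",
            [
                (DocumentRecord("d1", frozenset({"c1", "zz1"})), 1, 0.9),
                (DocumentRecord("d2", frozenset({"c1", "zz2"})), 2, 0.8),
            ],
        )
        with pytest.raises(OntologyError, match="zz1, zz2"):
            annotate(ranked, star_ontology, k=2)

    def test_json_payload_and_degradations(self):
        onto = generate_ontology(30, 2, seed=21)
        gold, ranked = generate_instance(
            onto, 4, 8, PerturbationConfig(p_substitute=0.2, seed=22)
        )
        res = annotate(ranked, onto, k=8, mu=0.0)
        payload = res.to_json_dict()
        assert payload["doc_id"] == "target"
        assert payload["suggested_concepts"] == sorted(res.suggested)
        assert set(payload["degradations"]) == set(res.suggested) or len(res.suggested) < 2
        assert all(v >= 0 for v in payload["degradations"].values())
        assert {"select", "matrix", "search"} <= set(res.timings)
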