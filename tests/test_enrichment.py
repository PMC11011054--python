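import numpy as np
import pandas as pd
import pytest

from celltopics.data_io import GeneSetCollection
from celltopics.enrichment import (
    bh_adjust,
    enrich_topics,
    filter_gene_sets,
    hypergeometric_enrich,
    summarize_topic_annotations,
)
from oracles import bh_stepup, hypergeom_tail_bruteforce, hypergeom_tail_enumeration


def collection_of_sizes(sizes, name="coll"):
    """Disjoint gene sets with the requested sizes (known union)."""
    sets = {}
    start = 0
    for i, size in enumerate(sizes):
        sets[f"s{i}"] = frozenset(f"g{j}" for j in range(start, start + size))
        start += size
    return GeneSetCollection(name, sets)


class TestFilter:
    def test_boundary_cases_at_100_genes(self):
        """In a 100-gene collection a 16-set is dropped, a 15-set kept."""
        coll = collection_of_sizes([16, 15, 69])
        assert coll.total_genes == 100
        out = filter_gene_sets(coll, max_ratio=0.15)
        assert "s0" not in out.sets  # 0.16 > 0.15
        assert "s1" in out.sets  # 0.15 is not > 0.15

    def test_max_ratio_one_is_identity(self):
        coll = collection_of_sizes([5, 10, 30])
        out = filter_gene_sets(coll, max_ratio=1.0)
        assert out.sets == coll.sets

    def test_filtered_collection_is_subset(self, rng):
        coll = collection_of_sizes(list(rng.integers(1, 40, size=12)))
        out = filter_gene_sets(coll, max_ratio=0.15)
        assert set(out.sets) <= set(coll.sets)

    def test_everything_filtered_warns(self):
        coll = collection_of_sizes([50, 50])
        with pytest.warns(UserWarning, match="no gene set"):
            out = filter_gene_sets(coll, max_ratio=0.15)
        assert len(out.sets) == 0


class TestHypergeometric:
    def test_worked_example_vs_enumeration(self):
        """N=10, K=5, n=4, k=4: p = C(5,4)/C(10,4) = 5/210."""
        universe = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection("c", {"S": frozenset(universe[:5])})
        topic = universe[:4]  # 4 genes, all inside S
        out = hypergeometric_enrich(topic, coll, universe)
        assert out.loc[0, "p_value"] == pytest.approx(5 / 210, abs=1e-12)
        assert out.loc[0, "p_value"] == pytest.approx(
            hypergeom_tail_enumeration(10, 5, 4, 4), abs=1e-12
        )

    def test_zero_overlap_gives_one(self):
        universe = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection("c", {"S": frozenset(universe[5:])})
        out = hypergeometric_enrich(universe[:3], coll, universe)
        assert out.loc[0, "p_value"] == 1.0

    def test_random_instances_match_bruteforce_tail(self, rng):
        universe = [f"g{i}" for i in range(40)]
        for _ in range(25):
            K = int(rng.integers(1, 30))
            n = int(rng.integers(1, 20))
            members = frozenset(rng.choice(universe, size=K, replace=False))
            topic = rng.choice(universe, size=n, replace=False)
            coll = GeneSetCollection("c", {"S": members})
            p = hypergeometric_enrich(topic, coll, universe).loc[0, "p_value"]
            k = len(set(topic) & members)
            assert p == pytest.approx(hypergeom_tail_bruteforce(40, K, n, k), abs=1e-12)

    def test_invariant_to_gene_renaming(self, rng):
        universe = [f"g{i}" for i in range(20)]
        perm = {g: f"x{j}" for g, j in zip(universe, rng.permutation(20))}
        coll = GeneSetCollection("c", {"S": frozenset(universe[:8])})
        topic = universe[4:10]
        p1 = hypergeometric_enrich(topic, coll, universe).loc[0, "p_value"]
        coll2 = GeneSetCollection("c", {"S": frozenset(perm[g] for g in universe[:8])})
        p2 = hypergeometric_enrich(
            [perm[g] for g in topic], coll2, [perm[g] for g in universe]
        ).loc[0, "p_value"]
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_empty_universe_rejected(self):
        coll = GeneSetCollection("c", {"S": frozenset({"g1"})})
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_enrich(["g1"], coll, [])


class TestBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04], atol=1e-12
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_matches_stepup_oracle_and_is_monotone(self, rng):
        for _ in range(20):
            p = rng.random(size=rng.integers(1, 25))
            q = bh_adjust(p)
            np.testing.assert_allclose(q, bh_stepup(p), atol=1e-12)
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(q[order]) >= -1e-15)
            assert np.all((q >= p - 1e-15) & (q <= 1.0))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_fdr_control_on_null_simulations(self):
        """BH at alpha=0.1 keeps the false-discovery proportion near alpha."""
        rng = np.random.default_rng(0)
        alpha, fdps = 0.1, []
        for _ in range(200):
            p = rng.random(50)  # all nulls: any rejection is false
            rejected = bh_adjust(p) <= alpha
            fdps.append(1.0 if rejected.any() else 0.0)
        assert np.mean(fdps) <= alpha + 0.05


class TestSummarize:
    def make_results(self, rows):
        return pd.DataFrame(
            rows, columns=["topic", "gene_set", "collection", "overlap", "q_value"]
        )

    def test_single_topic_single_set(self):
        res = self.make_results([("T1", "G", "c", 5, 0.001)])
        out = summarize_topic_annotations(res)
        assert out["T1"] == "G"

    def test_shared_best_set_dedup(self):
        """The topic with smaller q keeps the set; the other falls back."""
        res = self.make_results(
            [
                ("T1", "G", "c", 5, 0.001),
                ("T1", "H", "c", 4, 0.02),
                ("T2", "G", "c", 5, 0.01),
                ("T2", "H", "c", 4, 0.03),
            ]
        )
        out = summarize_topic_annotations(res)
        assert out["T1"] == "G"
        assert out["T2"] == "H"

    def test_insignificant_topic_unannotated(self):
        res = self.make_results([("T1", "G", "c", 5, 0.2)])
        out = summarize_topic_annotations(res, fdr_threshold=0.05)
        assert out["T1"] == "unannotated"

    def test_matches_bruteforce_on_random_q_tables(self, rng):
        """Sequential dedup equals an explicit reference implementation."""
        for _ in range(20):
            topics = [f"T{i}" for i in range(4)]
            sets = [f"S{j}" for j in range(5)]
            rows = [
                (t, s, "c", int(rng.integers(1, 9)), float(np.round(rng.random(), 6)))
                for t in topics
                for s in sets
            ]
            res = self.make_results(rows)
            out = summarize_topic_annotations(res, fdr_threshold=1.0)
            # reference: repeatedly give the globally best (q, overlap, set, topic)
            # claim its set, then drop that topic and set
            tbl = res.copy()
            expect = {}
            remaining = set(topics)
            while remaining and len(tbl):
                tbl = tbl[tbl["topic"].isin(remaining)]
                if not len(tbl):
                    break
                best = tbl.sort_values(
                    ["q_value", "overlap", "gene_set", "topic"],
                    ascending=[True, False, True, True],
                ).iloc[0]
                expect[best["topic"]] = best["gene_set"]
                remaining.discard(best["topic"])
                tbl = tbl[tbl["gene_set"] != best["gene_set"]]
            for t in topics:
                expect.setdefault(t, "unannotated")
            assert out.to_dict() == expect


class TestEnrichTopics:
    def test_end_to_end_small(self, rng):
        universe = [f"g{i}" for i in range(30)]
        coll = GeneSetCollection(
            "c",
            {
                "right": frozenset(universe[:6]),
                "wrong": frozenset(universe[20:26]),
            },
        )
        results = enrich_topics({"T1": universe[:6]}, coll, universe, max_ratio=1.0)
        assert set(results["gene_set"]) == {"right", "wrong"}
        best = results.sort_values("q_value").iloc[0]
        assert best["gene_set"] == "right"
        assert (results["q_value"] >= results["p_value"] - 1e-15).all()
        summary = summarize_topic_annotations(results)
        assert summary["T1"] == "right"
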