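import math
from fractions import Fraction

import numpy as np
import pytest

from submito.annotation_transfer import (
    EVIDENCE_RANK,
    PairwiseHit,
    SequenceCluster,
    align_pair,
    build_clusters,
    enrich_cluster,
    merge_annotations,
    overrepresentation_pvalue,
    transfer_annotations,
)
from submito.io_formats import GOAnnotation, ProteinRecord
from submito.synthetic_data import generate_go_world


def hypergeom_tail_oracle(k, n, K, N) -> Fraction:
    """Exhaustive enumeration of P(X >= k) with exact rational arithmetic."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return total


class TestAlignPair:
    def test_identical_sequences_align_perfectly(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2 + "ACDEFGHIKL"
        hit = align_pair(ProteinRecord("a", seq), ProteinRecord("b", seq))
        assert hit.identity == pytest.approx(100.0)
        assert hit.coverage == pytest.approx(100.0)

    def test_unrelated_sequences_fall_below_thresholds(self):
        a = ProteinRecord("a", "KKKKKKKKKKKKKKKKKKKKKKKKKKKKKK")
        b = ProteinRecord("b", "WCWCWCWCWCWCWCWCWCWCWCWCWCWCWC")
        hit = align_pair(a, b)
        assert not hit.passes()

    def test_hand_constructed_half_identical_pair(self):
        # 60-mer vs a copy with 30 substitutions; the substituted letters
        # score positively against the originals (I<->V under BLOSUM62), so
        # the optimal local alignment is the full ungapped 60 columns and
        # the identity is exactly the hand-counted 30/60.
        a = ProteinRecord("a", "KI" * 30)
        b = ProteinRecord("b", "KV" * 30)
        hit = align_pair(a, b)
        assert hit.alignment_length == 60
        assert hit.identity == pytest.approx(50.0)
        assert hit.coverage == pytest.approx(100.0)


class TestThresholds:
    def test_identity_threshold_is_strict(self):
        at_boundary = PairwiseHit("a", "b", identity=40.0, coverage=95.0,
                                  alignment_length=100)
        above = PairwiseHit("a", "b", identity=40.1, coverage=95.0,
                            alignment_length=100)
        assert not at_boundary.passes()
        assert above.passes()

    def test_coverage_threshold_is_inclusive(self):
        at_boundary = PairwiseHit("a", "b", identity=60.0, coverage=90.0,
                                  alignment_length=100)
        below = PairwiseHit("a", "b", identity=60.0, coverage=89.9,
                            alignment_length=100)
        assert at_boundary.passes()
        assert not below.passes()


class TestBuildClusters:
    def test_single_linkage_is_transitive(self, monkeypatch):
        # edges a-b and b-c only -> one cluster {a, b, c}
        records = [ProteinRecord(x, "ACDEFGHIKL") for x in "abc"]
        edges = {frozenset(["a", "b"]), frozenset(["b", "c"])}

        def fake_align(r1, r2):
            linked = frozenset([r1.id, r2.id]) in edges
            return PairwiseHit(r1.id, r2.id, 99.0 if linked else 5.0,
                               100.0 if linked else 10.0, 10)

        monkeypatch.setattr("submito.annotation_transfer.align_pair", fake_align)
        clusters = build_clusters(records)
        assert len(clusters) == 1
        assert clusters[0].members == frozenset("abc")

    def test_duplicate_ids_rejected(self):
        records = [ProteinRecord("a", "ACDEF"), ProteinRecord("a", "ACDEF")]
        with pytest.raises(ValueError, match="duplicate"):
            build_clusters(records)

    def test_planted_families_recovered_with_singletons(self):
        records, _, _ = generate_go_world(
            n_clusters=3, cluster_size=4, background_size=5,
            founder_length=60, seed=11,
        )
        clusters = build_clusters(records)
        families = sorted(
            tuple(sorted(c.members)) for c in clusters if not c.singleton
        )
        assert len(families) == 3
        for fam in families:
            prefixes = {pid.split("_")[0] for pid in fam}
            assert len(prefixes) == 1 and len(fam) == 4
        singletons = [c for c in clusters if c.singleton]
        assert len(singletons) == 5
        # partition property
        assert sum(len(c) for c in clusters) == len(records)


class TestEnrichment:
    def test_term_in_all_members_absent_elsewhere(self):
        cluster = SequenceCluster(frozenset(f"c{i}" for i in range(5)))
        anns = [
            GOAnnotation(f"c{i}", "GO:0000001", "BP", "EXP", "GOA_manual")
            for i in range(5)
        ]
        background = anns + [
            GOAnnotation(f"b{i}", "GO:0000002", "BP", "IEA", "GOA_IEA")
            for i in range(95)
        ]
        (result,) = enrich_cluster(cluster, anns, background)
        expected = Fraction(1, math.comb(100, 5))
        assert result.p_value == pytest.approx(float(expected), abs=1e-12)
        assert result.significant

    def test_uniform_term_is_not_significant(self):
        cluster = SequenceCluster(frozenset(f"c{i}" for i in range(5)))
        background = [
            GOAnnotation(pid, "GO:0000001", "BP", "EXP", "GOA_manual")
            for pid in [f"c{i}" for i in range(5)] + [f"b{i}" for i in range(50)]
        ]
        (result,) = enrich_cluster(cluster, background[:5], background)
        assert result.p_value == pytest.approx(1.0, abs=1e-9)
        assert not result.significant

    def test_bonferroni_divisor_counts_cluster_terms(self):
        # a raw p-value of ~0.005 fails at alpha 0.01 once 10 terms are tested
        cluster = SequenceCluster(frozenset(["c0", "c1"]))
        anns = [GOAnnotation("c0", f"GO:{t:07d}", "BP", "EXP", "GOA_manual")
                for t in range(1, 11)]
        background = anns + [
            GOAnnotation(f"b{i}", "GO:0000001", "BP", "IEA", "GOA_IEA")
            for i in range(40)
        ]
        results = enrich_cluster(cluster, anns, background)
        assert all(r.n_terms_tested == 10 for r in results)
        for r in results:
            assert r.significant == (r.p_value <= 0.01 / 10)

    def test_pvalues_match_exhaustive_oracle_small_universes(self):
        for N in range(2, 16):
            for K in range(N + 1):
                for n in range(1, N + 1):
                    for k in range(max(0, n - (N - K)), min(n, K) + 1):
                        p = overrepresentation_pvalue(k, n, K, N)
                        oracle = float(hypergeom_tail_oracle(k, n, K, N))
                        assert p == pytest.approx(oracle, abs=1e-10)

    def test_empty_background_rejected(self):
        cluster = SequenceCluster(frozenset(["a"]))
        with pytest.raises(ValueError, match="background"):
            enrich_cluster(cluster, [], [])


class TestTransferAndMerge:
    def _enriched(self, cluster, significant=True):
        return enrich_cluster(
            cluster,
            [GOAnnotation(pid, "GO:0000009", "BP", "EXP", "GOA_manual")
             for pid in sorted(cluster.members)[:2]],
            [GOAnnotation(pid, "GO:0000009", "BP", "EXP", "GOA_manual")
             for pid in sorted(cluster.members)[:2]]
            + [GOAnnotation(f"b{i}", "GO:0000002", "BP", "IEA", "GOA_IEA")
               for i in range(60)],
        )

    def test_transfer_fills_unannotated_members_only(self):
        cluster = SequenceCluster(frozenset(["c0", "c1", "c2", "c3"]))
        existing = [
            GOAnnotation(pid, "GO:0000009", "BP", "EXP", "GOA_manual")
            for pid in ["c0", "c1"]
        ]
        enriched = self._enriched(cluster)
        assert enriched[0].significant
        new = transfer_annotations(cluster, enriched, existing)
        assert {a.protein_id for a in new} == {"c2", "c3"}
        assert all(a.source == "BAR" for a in new)
        # never duplicates existing (protein, term) pairs
        assert not ({(a.protein_id, a.term) for a in new}
                    & {(a.protein_id, a.term) for a in existing})

    def test_no_significant_terms_transfers_nothing(self):
        cluster = SequenceCluster(frozenset(["c0", "c1"]))
        background = [
            GOAnnotation(pid, "GO:0000001", "BP", "EXP", "GOA_manual")
            for pid in ["c0", "b0", "b1", "b2"]
        ]
        enriched = enrich_cluster(cluster, background[:1], background)
        assert not any(r.significant for r in enriched)
        assert transfer_annotations(cluster, enriched, background[:1]) == []

    def test_merge_prefers_manual_over_iea_over_transfer(self):
        manual = GOAnnotation("p", "GO:0000001", "BP", "EXP", "GOA_manual")
        iea = GOAnnotation("p", "GO:0000001", "BP", "IEA", "GOA_IEA")
        bar = GOAnnotation("p", "GO:0000001", "BP", "IEA", "BAR")
        assert merge_annotations([manual], [iea]) == [manual]
        assert merge_annotations([iea], [bar]) == [iea]
        assert merge_annotations([bar, iea, manual]) == [manual]

    def test_merge_concatenates_disjoint_pools(self):
        a = [GOAnnotation("p1", "GO:0000001", "BP", "EXP", "GOA_manual")]
        b = [GOAnnotation("p2", "GO:0000002", "MF", "IEA", "GOA_IEA")]
        merged = merge_annotations(a, b)
        assert sorted(m.protein_id for m in merged) == ["p1", "p2"]

    def test_merged_size_never_exceeds_pool_sum(self):
        rng = np.random.default_rng(12)
        sources = list(EVIDENCE_RANK)
        pools = []
        for _ in range(3):
            pool = [
                GOAnnotation(
                    f"p{rng.integers(5)}",
                    f"GO:{int(rng.integers(1, 4)):07d}",
                    "BP",
                    "IEA",
                    sources[rng.integers(3)],
                )
                for _ in range(20)
            ]
            pools.append(pool)
        merged = merge_annotations(*pools)
        assert len(merged) <= sum(len(p) for p in pools)
        keys = [m.key() for m in merged]
        assert len(keys) == len(set(keys))
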