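import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from invgsea import (
    GeneSet,
    GeneSetCollection,
    compute_es,
    enrich_collection,
    leading_edge,
    permutation_test,
)
from invgsea.dge import RankedList, rank_genes
from invgsea.enrichment import EnrichmentProfile, _p_and_nes
from invgsea.genesets import read_gmt, write_gmt

from conftest import two_group_matrix
from oracles import brute_es, brute_gene_set_p, brute_running_scores


def random_instance(rng, n_max=50, k_min=1):
    n = int(rng.integers(max(4, k_min + 2), n_max + 1))
    genes = np.array([f"g{i:03d}" for i in range(n)], dtype=object)
    scores = np.round(rng.normal(size=n), 6)
    ranked = RankedList.from_scores(genes, scores)
    k = int(rng.integers(k_min, max(k_min + 1, n - 1)))
    members = frozenset(str(g) for g in rng.choice(genes, size=k, replace=False))
    return ranked, GeneSet("S", members)


class TestEnrichmentScore:
    def test_worked_example_weight_one(self, toy_ranked):
        gs = GeneSet("s", frozenset({"g1", "g3"}))
        prof = compute_es(toy_ranked, gs, w=1)
        np.testing.assert_allclose(
            prof.running_score, [0.75, 0.75 - 1 / 3, 2 / 3, 1 / 3, 0.0], atol=1e-12
        )
        assert prof.es == 0.75
        assert prof.es_position == 1
        assert leading_edge(prof, toy_ranked, gs) == frozenset({"G1"})

    def test_singleton_extremes_weight_zero(self):
        ranked = RankedList(
            np.array(["a", "b", "c", "d"], dtype=object),
            np.array([2.0, 1.0, -1.0, -2.0]),
        )
        top = compute_es(ranked, GeneSet("t", frozenset({"a"})), w=0)
        assert (top.es, top.es_position) == (1.0, 1)
        bottom = compute_es(ranked, GeneSet("b", frozenset({"d"})), w=0)
        assert (bottom.es, bottom.es_position) == (-1.0, 3)
        assert leading_edge(top, ranked, GeneSet("t", frozenset({"a"}))) == {"A"}

    def test_matches_brute_force_prefix_sums(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            ranked, gs = random_instance(rng, n_max=30)
            for w in (0.0, 1.0, 1.5):
                prof = compute_es(ranked, gs, w=w)
                hits = [g in gs.members for g in ranked.genes]
                np.testing.assert_allclose(
                    prof.running_score,
                    brute_running_scores(ranked.scores, hits, w),
                    atol=1e-12,
                )
                assert prof.es == pytest.approx(
                    brute_es(ranked.scores, hits, w), abs=1e-12
                )

    def test_weight_zero_equals_ks_statistic(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            ranked, gs = random_instance(rng, k_min=2)
            es = compute_es(ranked, gs, w=0).es
            pos = np.arange(1, ranked.N + 1)
            hit = np.fromiter((g in gs.members for g in ranked.genes), bool, ranked.N)
            ks = ks_2samp(pos[hit], pos[~hit]).statistic
            assert abs(abs(es) - ks) < 1e-12

    def test_monotone_transform_invariance_at_weight_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ranked, gs = random_instance(rng)
            transformed = RankedList.from_scores(
                ranked.genes, np.exp(ranked.scores / 2.0)
            )
            assert compute_es(transformed, gs, w=0).es == pytest.approx(
                compute_es(ranked, gs, w=0).es, abs=1e-12
            )

    def test_reversing_list_negates_es(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            ranked, gs = random_instance(rng)
            reversed_ranked = RankedList(
                ranked.genes[::-1].copy(), -ranked.scores[::-1].copy()
            )
            assert compute_es(reversed_ranked, gs, w=0).es == pytest.approx(
                -compute_es(ranked, gs, w=0).es, abs=1e-12
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_profile_invariants(self, data):
        n = data.draw(st.integers(4, 40))
        scores = data.draw(
            st.lists(
                st.floats(-10, 10, allow_nan=False, width=32), min_size=n, max_size=n
            )
        )
        k = data.draw(st.integers(1, n - 1))
        idx = data.draw(
            st.lists(st.integers(0, n - 1), min_size=k, max_size=k, unique=True)
        )
        genes = np.array([f"g{i:02d}" for i in range(n)], dtype=object)
        ranked = RankedList.from_scores(genes, scores)
        members = frozenset(f"G{i:02d}" for i in idx)
        try:
            prof = compute_es(ranked, GeneSet("s", members), w=1)
        except ValueError:
            return  # degenerate all-zero weights are a documented error
        assert abs(prof.running_score[-1]) < 1e-9
        assert -1.0 - 1e-12 <= prof.es <= 1.0 + 1e-12
        assert abs(prof.es) == pytest.approx(np.max(np.abs(prof.running_score)))
        le = leading_edge(prof, ranked, GeneSet("s", members))
        assert le <= members

    def test_error_cases(self, toy_ranked):
        with pytest.raises(ValueError, match="no members"):
            compute_es(toy_ranked, GeneSet("x", frozenset({"zz"})))
        with pytest.raises(ValueError, match="whole ranked list"):
            compute_es(
                toy_ranked, GeneSet("x", frozenset({"g1", "g2", "g3", "g4", "g5"}))
            )
        degenerate = RankedList(
            np.array(["a", "b", "c"], dtype=object), np.array([0.0, 0.0, 1.0])
        )
        with pytest.raises(ValueError, match="degenerate"):
            # hits a and b carry |r|^w = 0 at w=1
            compute_es(degenerate, GeneSet("x", frozenset({"a", "b"})), w=1)

    def test_zero_es_leading_edge_empty(self, toy_ranked):
        prof = EnrichmentProfile(np.zeros(5), 0.0, 1, 1.0)
        assert leading_edge(prof, toy_ranked, GeneSet("s", frozenset({"g1"}))) == frozenset()


class TestPermutationEstimator:
    def test_p_is_one_when_all_permutations_tie(self):
        p, nes, _ = _p_and_nes(0.5, np.full(100, 0.5))
        assert p == 1.0
        assert nes == pytest.approx(1.0)

    def test_nes_magnitude_one_at_mean(self):
        perm = np.array([0.2, 0.4, 0.6, -0.3, -0.5])
        p, nes, _ = _p_and_nes(0.4, perm)  # mean same-sign |ES*| = 0.4
        assert abs(nes) == pytest.approx(1.0)

    def test_too_few_permutations_rejected(self, toy_ranked):
        with pytest.raises(ValueError, match=">= 10"):
            permutation_test(
                GeneSet("s", frozenset({"g1"})), ranked=toy_ranked,
                n_permutations=5, mode="gene_set", seed=1,
            )

    def test_seed_required(self, toy_ranked):
        with pytest.raises(ValueError, match="seed"):
            permutation_test(
                GeneSet("s", frozenset({"g1"})), ranked=toy_ranked,
                mode="gene_set",
            )

    def test_gene_set_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(12):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(1, 4))
            genes = np.array([f"g{i}" for i in range(n)], dtype=object)
            scores = np.round(rng.normal(size=n), 4)
            ranked = RankedList.from_scores(genes, scores)
            members = frozenset(
                str(g) for g in rng.choice(genes, size=k, replace=False)
            )
            res = permutation_test(
                GeneSet("s", members), ranked=ranked, n_permutations=1000,
                mode="gene_set", seed=3, w=1.0,
            )
            hit_idx = sorted(ranked.position(g.upper()) for g in members)
            obs, p_expect = brute_gene_set_p(list(ranked.scores), hit_idx, 1.0)
            assert res.es == pytest.approx(obs, abs=1e-12)
            assert res.p_value == pytest.approx(p_expect, abs=1e-12)


class TestEnrichCollection:
    def test_single_set_fdr_equals_p(self, standard_contrast):
        _, expr_a, _, truth = standard_contrast
        up = [g for g, s in truth.de_genes_A.items() if s > 0][:30]
        coll = GeneSetCollection([GeneSet("UP", frozenset(up))])
        res = enrich_collection(
            coll, expr=expr_a, treated="trt", reference="ctrl",
            n_permutations=50, seed=2,
        )
        assert len(res) == 1
        assert res[0].fdr_q == res[0].p_value

    def test_spiked_set_ranks_first_with_floor_p(self, standard_contrast):
        _, expr_a, _, truth = standard_contrast
        rng = np.random.default_rng(7)
        up = [g for g, s in truth.de_genes_A.items() if s > 0][:40]
        genes = expr_a.genes
        random_sets = [
            GeneSet(f"R{i}", frozenset(rng.choice(genes, size=40, replace=False)))
            for i in range(5)
        ]
        coll = GeneSetCollection([GeneSet("SPIKE", frozenset(up)), *random_sets])
        res = enrich_collection(
            coll, expr=expr_a, treated="trt", reference="ctrl",
            n_permutations=100, seed=2,
        )
        assert res[0].set_name == "SPIKE"
        # at the add-one estimator floor: no same-sign permutation beat it,
        # so p = 1/(1 + n_same_sign) for an integer n_same_sign <= n_perm
        inv = 1.0 / res[0].p_value
        assert inv == pytest.approx(round(inv), abs=1e-9)
        assert 1 <= round(inv) - 1 <= res[0].n_permutations
        assert res[0].p_value <= 1.0 / (1.0 + 0.25 * res[0].n_permutations)
        assert res[0].nes > max(r.nes for r in res[1:])

    def test_empty_after_filter_rejected(self, toy_ranked):
        coll = GeneSetCollection([GeneSet("tiny", frozenset({"g1"}))])
        with pytest.raises(ValueError, match="size filter"):
            enrich_collection(
                coll, ranked=toy_ranked, mode="gene_set", seed=1, min_size=5
            )

    def test_results_sorted_by_nes(self, standard_contrast):
        _, expr_a, _, _ = standard_contrast
        rng = np.random.default_rng(8)
        coll = GeneSetCollection(
            [
                GeneSet(f"R{i}", frozenset(rng.choice(expr_a.genes, 30, replace=False)))
                for i in range(6)
            ]
        )
        res = enrich_collection(
            coll, expr=expr_a, treated="trt", reference="ctrl",
            n_permutations=50, seed=4,
        )
        nes = [r.nes for r in res]
        assert nes == sorted(nes, reverse=True)


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            [
                GeneSet("PATH_A", frozenset({"TP53", "EGF"}), "demo"),
                GeneSet("PATH_B", frozenset({"STAT3", "LOX", "CAV2"}), ""),
            ]
        )
        path = tmp_path / "c.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert {s.name: s.members for s in back} == {
            s.name: s.members for s in coll
        }

    def test_malformed_row_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("ONLY_NAME\n")
        with pytest.raises(ValueError, match="bad.gmt:1"):
            read_gmt(p)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneSetCollection(
                [GeneSet("X", frozenset({"a"})), GeneSet("X", frozenset({"b"}))]
            )
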