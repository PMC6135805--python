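"""Pre-ranked GSEA, gene-set summarization and clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from secrenet.enrichment import (
    GeneSetCollection,
    PrerankedGSEA,
    enrichment_score,
    geneset_pc1,
    gsea_preranked,
    hypergeometric_overlap,
    linkage_to_newick,
    standardize_slsm,
    summarize_gene_sets,
    ward_cluster,
)


def oracle_es(ranking: pd.Series, gene_set, p=1.0) -> float:
    """O(N) running-sum scan, coded independently of the implementation."""
    df = pd.DataFrame({"s": ranking.astype(float)})
    df["g"] = df.index.astype(str)
    df = df.sort_values(["s", "g"], ascending=[False, True])
    scores = df["s"].to_numpy()
    hits = np.array([g in gene_set for g in df["g"]])
    n, ns = len(scores), int(hits.sum())
    w = np.abs(scores) ** p
    nr = w[hits].sum()
    if nr == 0:
        w = np.ones(n)
        nr = float(ns)
    run, hi, lo = 0.0, 0.0, 0.0
    for i in range(n):
        run += w[i] / nr if hits[i] else -1.0 / (n - ns)
        hi = max(hi, run)
        lo = min(lo, run)
    return hi if hi >= -lo - 1e-9 * max(1.0, hi, -lo) else lo


class TestEnrichmentScore:
    def test_top_set_reaches_plus_one_unweighted(self):
        r = pd.Series(np.arange(20, 0, -1, dtype=float),
                      index=[f"g{i:02d}" for i in range(20)])
        assert enrichment_score(r, set(r.index[:5]), 0.0) == pytest.approx(1.0)

    def test_bottom_set_reaches_minus_one_unweighted(self):
        r = pd.Series(np.arange(20, 0, -1, dtype=float),
                      index=[f"g{i:02d}" for i in range(20)])
        assert enrichment_score(r, set(r.index[-5:]), 0.0) == pytest.approx(-1.0)

    def test_matches_bruteforce_oracle_on_random_instances(self, rng, make_ranking):
        for _ in range(200):
            n = int(rng.integers(10, 51))
            s = int(rng.integers(2, 9))
            ranking = make_ranking(rng, n)
            gs = set(rng.choice(ranking.index, size=s, replace=False))
            p = float(rng.choice([0.0, 1.0, 1.5]))
            assert enrichment_score(ranking, gs, p) == pytest.approx(
                oracle_es(ranking, gs, p), abs=1e-12
            )

    def test_negating_scores_negates_es(self, rng, make_ranking):
        for _ in range(30):
            ranking = make_ranking(rng, 40)
            gs = set(rng.choice(ranking.index, size=6, replace=False))
            assert enrichment_score(-ranking, gs) == pytest.approx(
                -enrichment_score(ranking, gs), abs=1e-9
            )

    def test_es_bounded(self, rng, make_ranking):
        for _ in range(50):
            ranking = make_ranking(rng, 30)
            gs = set(rng.choice(ranking.index, size=5, replace=False))
            assert abs(enrichment_score(ranking, gs)) <= 1.0 + 1e-12


class TestGseaPermutation:
    def test_fixed_seed_reproducible(self, rng, make_ranking):
        ranking = make_ranking(rng, 300)
        sets = GeneSetCollection(
            {f"S{i}": set(rng.choice(ranking.index, size=20, replace=False))
             for i in range(8)}
        )
        a = gsea_preranked(ranking, sets, n_perm=200, seed=42)
        b = gsea_preranked(ranking, sets, n_perm=200, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.leading_edge == b.leading_edge

    def test_disjoint_set_skipped_with_warning(self, rng, make_ranking):
        ranking = make_ranking(rng, 50)
        sets = GeneSetCollection({"ghost": {"NOPE1", "NOPE2", "NOPE3", "NOPE4", "NOPE5"}})
        with pytest.warns(UserWarning, match="shares no genes"):
            res = gsea_preranked(ranking, sets, n_perm=100, seed=1)
        assert len(res.table) == 0

    def test_small_nperm_warns(self, rng, make_ranking):
        ranking = make_ranking(rng, 60)
        sets = GeneSetCollection(
            {"s": set(rng.choice(ranking.index, size=8, replace=False))}
        )
        with pytest.warns(UserWarning, match="unstable"):
            gsea_preranked(ranking, sets, n_perm=50, seed=1)

    def test_leading_edge_subset_of_set(self, rng, make_ranking):
        ranking = make_ranking(rng, 200)
        members = set(rng.choice(ranking.index, size=25, replace=False))
        sets = GeneSetCollection({"s": members})
        res = gsea_preranked(ranking, sets, n_perm=100, seed=3)
        assert set(res.leading_edge["s"]) <= members

    def test_model_class_wraps_function(self, rng, make_ranking):
        ranking = make_ranking(rng, 100)
        sets = GeneSetCollection(
            {"s": set(rng.choice(ranking.index, size=10, replace=False))}
        )
        res = PrerankedGSEA(ranking, sets).fit(n_perm=150, seed=9)
        direct = gsea_preranked(ranking, sets, n_perm=150, seed=9)
        pd.testing.assert_frame_equal(res.table, direct.table)
        assert "Pre-ranked GSEA" in res.summary()


class TestSlsm:
    def test_two_groups_give_inverse_sqrt2(self):
        expr = pd.DataFrame(
            {"a1": [1.0], "a2": [1.0], "b1": [3.0], "b2": [3.0]}, index=["g"]
        )
        groups = pd.Series(["A", "A", "B", "B"], index=expr.columns)
        slsm = standardize_slsm(expr, groups)
        assert slsm.loc["g"].tolist() == pytest.approx(
            [-1 / math.sqrt(2), 1 / math.sqrt(2)]
        )

    def test_constant_gene_becomes_zero_row(self):
        expr = pd.DataFrame({"a": [2.0], "b": [2.0]}, index=["flat"])
        groups = pd.Series(["A", "B"], index=expr.columns)
        with pytest.warns(UserWarning, match="constant"):
            slsm = standardize_slsm(expr, groups)
        assert (slsm.loc["flat"] == 0).all()

    def test_rows_standardized(self, rng):
        expr = pd.DataFrame(rng.normal(size=(30, 9)),
                            columns=[f"s{i}" for i in range(9)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=expr.columns)
        slsm = standardize_slsm(expr, groups)
        assert np.allclose(slsm.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(slsm.std(axis=1, ddof=1), 1, atol=1e-12)


class TestGenesetPc1:
    def test_identical_profiles_explain_everything(self):
        row = [1.0, -1.0, 0.5, -0.5]
        slsm = pd.DataFrame([row, row, row], index=["a", "b", "c"],
                            columns=list("wxyz"))
        _, ve = geneset_pc1(slsm, {"a", "b", "c"})
        assert ve == pytest.approx(1.0)

    def test_singleton_returns_row(self):
        slsm = pd.DataFrame([[0.3, -0.3, 0.1, -0.1]], index=["solo"],
                            columns=list("wxyz"))
        scores, ve = geneset_pc1(slsm, {"solo"})
        assert scores.tolist() == pytest.approx([0.3, -0.3, 0.1, -0.1])
        assert ve == 1.0

    def test_matches_eigendecomposition(self, rng):
        slsm = pd.DataFrame(rng.normal(size=(10, 4)),
                            index=[f"g{i}" for i in range(10)],
                            columns=list("abcd"))
        scores, ve = geneset_pc1(slsm, set(slsm.index))
        x = slsm.to_numpy() - slsm.to_numpy().mean(axis=1, keepdims=True)
        eigvals = np.linalg.eigvalsh(x @ x.T)[::-1]
        assert ve == pytest.approx(eigvals[0] / eigvals.sum(), abs=1e-10)
        # scores live in the top right-singular subspace
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        assert abs(abs(np.corrcoef(scores, vt[0])[0, 1]) - 1) < 1e-10


class TestWard:
    def test_identical_rows_merge_first_at_zero(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=["a", "b", "c"]
        )
        link = ward_cluster(profiles)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}
        assert link[0, 2] == pytest.approx(0.0)

    def test_points_on_line_merge_nearest_pair(self):
        profiles = pd.DataFrame([[0.0], [1.0], [10.0]], index=list("abc"))
        link = ward_cluster(profiles)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}

    def test_row_permutation_gives_isomorphic_tree(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(8, 3)),
                                index=[f"r{i}" for i in range(8)])
        link_a = ward_cluster(profiles)
        perm = rng.permutation(8)
        link_b = ward_cluster(profiles.iloc[perm])

        def merge_heights(link):
            return sorted(np.round(link[:, 2], 9).tolist())

        assert merge_heights(link_a) == merge_heights(link_b)

    def test_newick_serialization_roundtrip_labels(self):
        profiles = pd.DataFrame([[0.0], [1.0], [10.0]], index=list("abc"))
        link = ward_cluster(profiles)
        nwk = linkage_to_newick(link, list(profiles.index))
        assert nwk.endswith(";")
        for label in "abc":
            assert label in nwk


class TestHypergeometric:
    def test_full_overlap_of_universe(self):
        u = {f"g{i}" for i in range(10)}
        p, fold = hypergeometric_overlap(u, u, u)
        assert p == pytest.approx(1.0)

    def test_hand_enumeration(self):
        universe = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(5)}
        target = {f"g{i}" for i in range(4)}
        p, fold = hypergeometric_overlap(query, target, universe)
        assert p == pytest.approx(6 / 252, abs=1e-12)
        assert fold == pytest.approx(4 / (5 * 4 / 10))

    def test_zero_overlap_large_expectation(self):
        universe = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(10)}
        target = {f"g{i}" for i in range(10, 20)}
        p, _ = hypergeometric_overlap(query, target, universe)
        assert p > 0.99


class TestSummarize:
    def test_pipeline_summary_produces_tree(self, rng):
        expr = pd.DataFrame(rng.normal(size=(60, 8)),
                            index=[f"g{i:02d}" for i in range(60)],
                            columns=[f"s{i}" for i in range(8)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=expr.columns)
        sets = GeneSetCollection({
            "one": set(expr.index[:20]),
            "two": set(expr.index[20:40]),
            "three": set(expr.index[40:]),
        })
        summary = summarize_gene_sets(expr, groups, sets)
        assert summary.pc1.shape == (3, 2)
        assert summary.newick is not None
        assert (summary.variance_explained <= 1.0 + 1e-9).all()


class TestGmtRoundtrip:
    def test_write_read(self, tmp_path):
        sets = GeneSetCollection({"alpha": {"A", "B"}, "beta": {"C"}},
                                 {"alpha": "first", "beta": "second"})
        p = tmp_path / "sets.gmt"
        sets.to_gmt(p)
        back = GeneSetCollection.from_gmt(p)
        assert back.sets == sets.sets
        assert back.descriptions["alpha"] == "first"

    def test_malformed_gmt_raises(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("name_only\tdesc\n")
        with pytest.raises(ValueError, match="line 1"):
            GeneSetCollection.from_gmt(p)
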