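"""Normalization, variance attribution, batch adjustment and per-gene tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from secrenet.degs import (
    DifferentialExpression,
    abundance_filter,
    adjust_batch,
    bh_fdr,
    call_degs,
    contrast_tstat,
    cpm_log2,
    pcva,
    per_gene_anova,
    tmm_factors,
)


def brute_force_tmm(counts: pd.DataFrame, logratio_trim=0.30, abs_trim=0.05):
    """Independent straight-loop TMM for oracle comparison."""
    lib = counts.sum(axis=0).astype(float)
    cpm = counts / lib * 1e6
    f75 = cpm.quantile(0.75)
    ref = (f75 - f75.mean()).abs().idxmin()
    out = {}
    for s in counts.columns:
        if s == ref:
            out[s] = 1.0
            continue
        pairs = [
            (ys, yr)
            for ys, yr in zip(counts[s], counts[ref])
            if ys > 0 and yr > 0
        ]
        m = [np.log2((ys / lib[s]) / (yr / lib[ref])) for ys, yr in pairs]
        a = [0.5 * np.log2((ys / lib[s]) * (yr / lib[ref])) for ys, yr in pairs]
        w = [
            (lib[s] - ys) / (lib[s] * ys) + (lib[ref] - yr) / (lib[ref] * yr)
            for ys, yr in pairs
        ]
        n = len(m)
        if max(abs(x) for x in m) < 1e-6:
            out[s] = 1.0
            continue
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
        num = den = 0.0
        for mi, wi, rmi, rai in zip(m, w, rm, ra):
            if lo_m <= rmi <= hi_m and lo_a <= rai <= hi_a:
                num += mi / wi
                den += 1.0 / wi
        out[s] = 2.0 ** (num / den)
    fac = pd.Series(out)[counts.columns]
    return fac / np.exp(np.mean(np.log(fac)))


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30], "c": [10, 20, 30]})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_doubled_library_absorbed(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, size=200) + 1
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        f = tmm_factors(counts)
        cpm = (counts / (counts.sum() * f)).to_numpy()
        assert np.allclose(cpm[:, 0], cpm[:, 1], atol=1e-9)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.02, size=(300, 4)),
            columns=list("wxyz"),
        )
        counts += 1  # avoid all-zero rows
        mine = tmm_factors(counts)
        oracle = brute_force_tmm(counts)
        assert np.allclose(mine, oracle, atol=1e-10)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(rng.poisson(40, size=(100, 5)) + 1)
        f = tmm_factors(counts)
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-12

    def test_zero_library_raises(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="zero total"):
            tmm_factors(counts)

    def test_matches_edger_reference_implementation(self, tmp_path):
        """Cross-check against edgeR's calcNormFactors via Rscript."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(3)
        mat = rng.negative_binomial(5, 0.01, size=(400, 6)).astype(int)
        mat[rng.random(mat.shape) < 0.1] = 0
        counts = pd.DataFrame(mat, columns=[f"s{j}" for j in range(6)])
        csv = tmp_path / "m.tsv"
        counts.to_csv(csv, sep="\t")
        script = (
            "suppressMessages(library(edgeR));"
            f"x<-as.matrix(read.delim('{csv}',row.names=1));"
            "cat(calcNormFactors(x,method='TMM'),sep='\\n')"
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        if proc.returncode != 0:
            pytest.skip(f"edgeR unavailable: {proc.stderr[:200]}")
        ref = np.array([float(x) for x in proc.stdout.split()])
        assert np.allclose(tmm_factors(counts).to_numpy(), ref, atol=1e-6)


class TestCpmLog2:
    def test_plugin_arithmetic(self):
        # zero count, prior 0.5, effective library exactly one million
        counts = pd.DataFrame({"s": [0, 10**6]})
        expr = cpm_log2(counts, factors=pd.Series({"s": 1.0}), prior_count=0.5)
        assert expr.iloc[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(30, size=(50, 3)) + 1)
        a = cpm_log2(counts, prior_count=1e-9)
        b = cpm_log2(counts * 2, prior_count=1e-9)
        assert np.allclose(a, b, atol=1e-6)

    def test_oracle_on_random_matrix(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(20, size=(40, 4)))
        f = pd.Series(np.ones(4), index=counts.columns)
        expr = cpm_log2(counts, f, prior_count=0.5)
        lib = counts.sum(axis=0)
        for g in range(40):
            for s in range(4):
                expected = np.log2((counts.iloc[g, s] + 0.5) / (lib.iloc[s] / 1e6))
                assert expr.iloc[g, s] == pytest.approx(expected, abs=1e-12)


class TestAbundanceFilter:
    def test_boundary_inclusive(self):
        expr = pd.DataFrame({"s1": [2.9, 3.0], "s2": [2.9, 3.0]}, index=["low", "edge"])
        kept, diag = abundance_filter(expr, 3.0)
        assert list(kept.index) == ["edge"]
        assert set(diag.index) == {"low", "edge"}

    def test_matches_recount(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(3, 2, size=(200, 6)))
        kept, _ = abundance_filter(expr, 3.0)
        brute = sum(1 for i in range(200) if expr.iloc[i].mean() >= 3.0)
        assert len(kept) == brute


class TestPerGeneAnova:
    def test_equal_group_means_give_zero_f(self):
        expr = pd.DataFrame({"a1": [1.0], "a2": [2.0], "b1": [1.0], "b2": [2.0]})
        groups = pd.Series(["A", "A", "B", "B"], index=expr.columns)
        res = per_gene_anova(expr, groups)
        assert res["F"].iloc[0] == 0.0
        assert res["p_anova"].iloc[0] == 1.0

    def test_hand_computed_example(self):
        # groups (1,2,3) vs (4,5,6): SSB=13.5, SSW=4, df=(1,4) -> F=13.5
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
                            columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=expr.columns)
        res = per_gene_anova(expr, groups)
        assert res["F"].iloc[0] == pytest.approx(13.5, abs=1e-12)
        assert res["p_anova"].iloc[0] == pytest.approx(0.021312, abs=1e-5)

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(30, 9)),
                            columns=[f"s{i}" for i in range(9)])
        groups = pd.Series(["A"] * 5 + ["B"] * 4, index=expr.columns)
        f = per_gene_anova(expr, groups)["F"]
        t = contrast_tstat(expr, groups, "A", "B")
        assert np.allclose(f, t**2, atol=1e-10)

    def test_matches_scipy_oneway(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(50, 12)),
                            columns=[f"s{i}" for i in range(12)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=expr.columns)
        res = per_gene_anova(expr, groups)
        for i in range(50):
            f, p = stats.f_oneway(expr.iloc[i, :4], expr.iloc[i, 4:8], expr.iloc[i, 8:])
            assert res["F"].iloc[i] == pytest.approx(f, rel=1e-10)
            assert res["p_anova"].iloc[i] == pytest.approx(p, rel=1e-8)


class TestContrastT:
    def test_antisymmetry(self):
        rng = np.random.default_rng(10)
        expr = pd.DataFrame(rng.normal(size=(20, 8)),
                            columns=[f"s{i}" for i in range(8)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=expr.columns)
        t_ab = contrast_tstat(expr, groups, "A", "B")
        t_ba = contrast_tstat(expr, groups, "B", "A")
        assert np.allclose(t_ab, -t_ba)

    def test_equal_means_give_zero(self):
        expr = pd.DataFrame({"a1": [1.0], "a2": [3.0], "b1": [2.0], "b2": [2.0]})
        groups = pd.Series(["A", "A", "B", "B"], index=expr.columns)
        assert contrast_tstat(expr, groups, "A", "B").iloc[0] == 0.0


class TestBhFdr:
    def test_stepup_enumeration(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bh_fdr(p)
            m = len(p)
            order = np.argsort(p, kind="stable")
            expected = np.empty(m)
            for rank_pos, idx in enumerate(order):
                cands = [
                    p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
                ]
                expected[idx] = min(1.0, min(cands))
            assert np.allclose(q, expected, atol=1e-12)

    def test_permutation_stability(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))


class TestAdjustBatch:
    @staticmethod
    def toy_annotation():
        return pd.DataFrame(
            {
                "population": ["A", "A", "B", "B", "A", "A", "B", "B"],
                "batch": ["b1"] * 4 + ["b2"] * 4,
            },
            index=[f"s{i}" for i in range(8)],
        )

    def test_pure_population_signal_unchanged(self):
        ann = self.toy_annotation()
        base = np.array([1.0, 1.0, 4.0, 4.0, 1.0, 1.0, 4.0, 4.0])
        expr = pd.DataFrame([base, base * 2], columns=ann.index)
        out = adjust_batch(expr, ann)
        assert np.allclose(out, expr, atol=1e-9)

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(13)
        ann = self.toy_annotation()
        delta = 1.7
        noise_sd = 0.3
        n_genes = 400
        expr = pd.DataFrame(
            rng.normal(5, 1, size=(n_genes, 1))
            + rng.normal(0, noise_sd, size=(n_genes, 8)),
            columns=ann.index,
        )
        expr.loc[:, ann["batch"] == "b2"] += delta
        out = adjust_batch(expr, ann)
        removed = (expr - out).loc[:, ann["batch"] == "b2"].mean(axis=1)
        # the removed per-gene shift averages delta/2 after grand-mean
        # centering on a balanced two-batch design
        se = noise_sd / np.sqrt(n_genes)
        assert abs(removed.mean() - delta / 2) < 2 * se

    def test_confounded_design_raises(self):
        ann = pd.DataFrame(
            {"population": ["A", "A", "B", "B"], "batch": ["x", "x", "y", "y"]},
            index=[f"s{i}" for i in range(4)],
        )
        expr = pd.DataFrame(np.ones((3, 4)), columns=ann.index)
        with pytest.raises(ValueError, match="confounded"):
            adjust_batch(expr, ann)


class TestPcva:
    def test_constant_batch_contributes_nothing(self):
        rng = np.random.default_rng(14)
        ann = pd.DataFrame(
            {
                "population": ["A"] * 4 + ["B"] * 4,
                "batch": ["b"] * 8,
            },
            index=[f"s{i}" for i in range(8)],
        )
        expr = pd.DataFrame(rng.normal(size=(100, 8)), columns=ann.index)
        with pytest.warns(UserWarning, match="constant"):
            rep = pcva(expr, ann, factors=("population", "batch"))
        batch_row = rep.set_index("factor").loc["batch", "contribution_pct"]
        assert batch_row == 0.0

    def test_shares_sum_to_hundred(self):
        from secrenet.synthetic import generate_counts

        study, _ = generate_counts(network=None, factors=[], n_genes=400,
                                   seed=15)
        expr = cpm_log2(study.counts)
        rep = pcva(expr, study.annotation)
        assert rep["contribution_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        assert (rep["contribution_pct"] >= 0).all()

    def test_strong_batch_dominates_then_adjustment_removes_it(self):
        from secrenet.synthetic import generate_counts

        study, _ = generate_counts(network=None, factors=[], n_genes=600,
                                   batch_effect_sd=1.5, seed=16)
        expr = cpm_log2(study.counts, tmm_factors(study.counts))
        raw = pcva(expr, study.annotation).set_index("factor")
        assert (
            raw.loc["batch", "contribution_pct"]
            > raw.loc["population", "contribution_pct"]
        )
        adj = adjust_batch(expr, study.annotation)
        after = pcva(adj, study.annotation).set_index("factor")
        assert after.loc["batch", "contribution_pct"] < 5.0


class TestDegModel:
    def test_deg_flag_matches_threshold(self):
        from secrenet.synthetic import generate_counts

        study, _ = generate_counts(network=None, factors=[], n_genes=500, seed=17)
        res = DifferentialExpression(study).fit(fdr=0.05)
        assert res.deg_genes == set(res.table.index[res.table["q"] <= 0.05])
        assert call_degs(res.table, 0.0) == set()

    def test_summary_mentions_populations(self):
        from secrenet.synthetic import generate_counts

        study, _ = generate_counts(network=None, factors=[], n_genes=300, seed=18)
        res = DifferentialExpression(study).fit()
        text = res.summary()
        assert "bloodASC" in text and "bmLLPC" in text
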