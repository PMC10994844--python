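import numpy as np
import pandas as pd
import pytest

from txatlas.expression import (
    DEResult,
    cpm,
    enrichment_score,
    estimate_common_dispersion,
    filter_expressed,
    nb_de_test,
    preranked_gsea,
    rank_metric,
    significant_de,
)
from txatlas.models import ExpressionMatrix
from txatlas.synthetic import simulate_counts

CMAP = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}


def matrix_from(counts, cmap, libs=None):
    return ExpressionMatrix(pd.DataFrame(counts), cmap, library_sizes=libs)


class TestCpm:
    def test_formula(self):
        counts = pd.DataFrame({"s": [10, 0]}, index=["g1", "g2"])
        m = ExpressionMatrix(counts, {"s": "A"}, library_sizes={"s": 1e6})
        values = cpm(m)
        assert values.loc["g1", "s"] == pytest.approx(10.0)
        assert values.loc["g2", "s"] == 0.0

    def test_threshold_equivalence_at_fifteen_million(self):
        counts = pd.DataFrame({"s": [10]}, index=["g1"])
        m = ExpressionMatrix(counts, {"s": "A"}, library_sizes={"s": 15_072_000})
        assert round(float(cpm(m).loc["g1", "s"]), 4) == 0.6635

    def test_columns_sum_to_one_million_with_default_libraries(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(20, (50, 4)),
                              columns=list(CMAP)[:4])
        m = ExpressionMatrix(counts, CMAP)
        assert np.allclose(cpm(m).sum(axis=0), 1e6)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s": [0]})
        with pytest.raises(ValueError, match="positive"):
            ExpressionMatrix(counts, {"s": "A"}, library_sizes={"s": 0})


class TestFilterExpressed:
    def test_retained_if_all_replicates_of_one_condition_pass(self):
        counts = pd.DataFrame(
            {"s0": [20, 5], "s1": [20, 5], "s2": [20, 5], "s3": [0, 5], "s4": [0, 5], "s5": [0, 5]},
            index=["g_on", "g_low"],
        )
        libs = {s: 1e7 for s in counts.columns}
        m = ExpressionMatrix(counts, CMAP, library_sizes=libs)
        # g_on: CPM 2.0 in all replicates of condition A; g_low: CPM 0.5 everywhere
        assert filter_expressed(m, cpm_threshold=0.6635) == ["g_on"]

    def test_all_samples_scheme(self):
        counts = pd.DataFrame(
            {s: [20] for s in CMAP} | {"s5": [0]}, index=["g"]
        )
        m = ExpressionMatrix(counts[list(CMAP)], CMAP, library_sizes={s: 1e7 for s in CMAP})
        assert filter_expressed(m, scheme="all_samples") == []

    def test_zero_threshold_keeps_nonzero_genes(self):
        counts = pd.DataFrame({s: [3, 0] for s in CMAP}, index=["g1", "g2"])
        m = ExpressionMatrix(counts, CMAP)
        assert filter_expressed(m, cpm_threshold=0.0) == ["g1"]


class TestDeTest:
    def test_null_type_one_error_calibrated(self):
        m, _ = simulate_counts(10_000, CMAP, 2e5, dispersion=0.05, seed=10)
        de = nb_de_test(m, ("B", "A"))
        frac = float((de.table["pvalue"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_power_on_planted_fold_changes(self):
        genes = [f"g{i + 1:05d}" for i in range(2000)]
        planted = {g: 4.0 for g in genes[:100]}
        m, _ = simulate_counts(
            2000, CMAP, 1e6, dispersion=0.05, planted_de=planted, seed=11
        )
        calls = significant_de(nb_de_test(m, ("B", "A")))
        assert (calls.loc[list(planted)] == "up").mean() >= 0.90

    def test_identical_counts_give_zero_lfc(self):
        counts = pd.DataFrame({s: [50, 7] for s in CMAP}, index=["g1", "g2"])
        m = ExpressionMatrix(counts, CMAP)
        de = nb_de_test(m, ("B", "A"))
        assert de.table["log2fc"].abs().max() == 0.0

    def test_all_zero_group_rejected(self):
        counts = pd.DataFrame(
            {"s0": [1], "s1": [2], "s2": [1], "s3": [0], "s4": [0], "s5": [0]}
        )
        m = ExpressionMatrix(counts, CMAP, library_sizes={s: 1e6 for s in CMAP})
        with pytest.raises(ValueError, match="all-zero"):
            nb_de_test(m, ("B", "A"))

    def test_single_replicate_group_rejected(self):
        counts = pd.DataFrame({"s0": [5], "s1": [5], "s2": [5]})
        m = ExpressionMatrix(counts, {"s0": "A", "s1": "A", "s2": "B"})
        with pytest.raises(ValueError, match="replicates"):
            nb_de_test(m, ("B", "A"))

    def test_dispersion_estimate_tracks_truth(self):
        m, _ = simulate_counts(4000, CMAP, 5e5, dispersion=0.1, seed=12)
        assert estimate_common_dispersion(m) == pytest.approx(0.1, rel=0.25)


def de_result(rows):
    table = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
    return DEResult(table=table, test_condition="t", control_condition="c", dispersion=0.1)


class TestThresholdsAndRanking:
    def test_significance_thresholds(self):
        de = de_result(
            [
                {"log2fc": 2.5, "pvalue": 1e-4, "fdr": 0.01},
                {"log2fc": 2.5, "pvalue": 0.04, "fdr": 0.2},
                {"log2fc": -3.0, "pvalue": 1e-5, "fdr": 0.001},
                {"log2fc": 1.5, "pvalue": 1e-5, "fdr": 0.001},
            ]
        )
        assert list(significant_de(de)) == ["up", "neither", "down", "neither"]

    def test_rank_metric_values(self):
        de = de_result(
            [
                {"log2fc": 1.0, "pvalue": 0.01, "fdr": 0.1},
                {"log2fc": -1.0, "pvalue": 0.01, "fdr": 0.1},
                {"log2fc": 0.5, "pvalue": 1.0, "fdr": 1.0},
            ]
        )
        scores = rank_metric(de)
        assert scores.loc["g0"] == pytest.approx(2.0)
        assert scores.loc["g1"] == pytest.approx(-2.0)
        assert scores.loc["g2"] == 0.0
        assert list(scores.index) == ["g0", "g2", "g1"]  # descending, id tie-break

    def test_zero_pvalue_floored_with_flag(self):
        de = de_result([{"log2fc": 1.0, "pvalue": 0.0, "fdr": 0.0}])
        scores = rank_metric(de)
        assert np.isfinite(scores.iloc[0]) and scores.attrs["pvalue_floored"]

    def test_bh_fdr_monotone_in_pvalue_rank(self):
        m, _ = simulate_counts(800, CMAP, 2e5, dispersion=0.05, seed=13)
        de = nb_de_test(m, ("B", "A"))
        ordered = de.table.sort_values("pvalue")["fdr"].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()


def make_ranking(n=1000, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(0, 2, n))[::-1]
    return pd.Series(scores, index=[f"g{i:04d}" for i in range(n)])


class TestGsea:
    def test_top_ranked_set_has_extreme_score(self):
        ranking = make_ranking()
        top = {"top": list(ranking.index[:20])}
        res = preranked_gsea(ranking, top, n_perm=2000, seed=1)
        assert res.table.loc["top", "es"] > 0.9
        assert res.table.loc["top", "pvalue"] <= 1 / 2000 + 1e-9

    def test_es_sign_flips_with_negated_ranking(self):
        ranking = make_ranking(seed=2)
        sets = {"top": list(ranking.index[:25])}
        es_pos = preranked_gsea(ranking, sets, n_perm=200, seed=3).table.loc["top", "es"]
        neg = (-ranking).sort_values(ascending=False)
        es_neg = preranked_gsea(neg, sets, n_perm=200, seed=3).table.loc["top", "es"]
        assert es_pos == pytest.approx(-es_neg, abs=1e-12)

    def test_es_bounded(self):
        rng = np.random.default_rng(4)
        ranking = make_ranking(seed=4)
        for _ in range(20):
            mask = np.zeros(len(ranking), bool)
            mask[rng.choice(len(ranking), 30, replace=False)] = True
            es = enrichment_score(ranking.to_numpy(), mask)
            assert -1 <= es <= 1

    def test_small_sets_dropped_unless_exempt(self):
        ranking = make_ranking(seed=5)
        sets = {"tiny": list(ranking.index[:5]), "kept": list(ranking.index[:12])}
        res = preranked_gsea(ranking, sets, n_perm=200, seed=6, min_size=10)
        assert list(res.table.index) == ["kept"]
        res2 = preranked_gsea(
            ranking, sets, n_perm=200, seed=6, min_size=10, exempt_sets=["tiny"]
        )
        assert set(res2.table.index) == {"tiny", "kept"}

    def test_low_permutation_count_rejected(self):
        ranking = make_ranking(seed=7)
        with pytest.raises(ValueError, match="n_perm"):
            preranked_gsea(ranking, {"s": list(ranking.index[:12])}, n_perm=50)

    def test_null_pvalues_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        ranking = make_ranking(seed=8)
        sets = {
            f"rand{i}": list(rng.choice(ranking.index, 20, replace=False))
            for i in range(100)
        }
        res = preranked_gsea(ranking, sets, n_perm=400, seed=9)
        ks = stats.kstest(res.table["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_agrees_with_external_prerank_implementation(self, tmp_path):
        gseapy = pytest.importorskip("gseapy")
        ranking = make_ranking(n=300, seed=10)
        members = list(ranking.index[10:40])
        res = preranked_gsea(ranking, {"s1": members}, n_perm=200, seed=11)
        rnk = ranking.reset_index()
        rnk.columns = ["gene", "score"]
        out = gseapy.prerank(
            rnk=rnk, gene_sets={"s1": members}, permutation_num=50,
            outdir=None, seed=1, min_size=5, max_size=500, no_plot=True,
        ).res2d
        external_es = float(out["ES"].iloc[0])
        assert res.table.loc["s1", "es"] == pytest.approx(external_es, abs=0.05)
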