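import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from conftest import make_count_matrix
from mscvar import preprocess as pp
from mscvar.containers import ExpressionMatrix
from mscvar.simulate import SimSpec, null_spec, simulate_cohort
from mscvar.variability import (
    dm_statistic,
    rolling_median_residual,
    select_hvgs,
    squared_cv,
)
from oracles import dm_bruteforce, rolling_median_residual_bruteforce


def _cpm(counts, gene_ids=None):
    return pp.compute_cpm(make_count_matrix(counts, gene_ids=gene_ids))


class TestSquaredCV:
    def test_constant_gene_has_zero_cv2(self):
        em = ExpressionMatrix(
            pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"], columns=list("abc")),
            "cpm",
        )
        assert squared_cv(em)["cv2"].iloc[0] == 0.0

    def test_two_point_formula(self):
        em = ExpressionMatrix(
            pd.DataFrame([[1.0, 3.0]], index=["g"], columns=list("ab")), "cpm"
        )
        row = squared_cv(em).iloc[0]
        assert row["mean_cpm"] == 2.0
        assert row["cv2"] == pytest.approx(0.5)

    def test_matches_direct_formula_on_random_genes(self, rng):
        vals = rng.gamma(2.0, 50.0, size=(100, 7))
        em = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(100)],
                         columns=[f"s{j}" for j in range(7)]),
            "cpm",
        )
        out = squared_cv(em)
        for i in range(100):
            mean = vals[i].mean()
            var = vals[i].var(ddof=1)
            np.testing.assert_allclose(out["cv2"].iloc[i], var / mean**2,
                                       rtol=1e-12)


class TestRollingMedianResidual:
    def test_constant_y_gives_zero_residuals(self, rng):
        x = pd.Series(rng.normal(size=40), index=[f"g{i}" for i in range(40)])
        y = pd.Series(3.0, index=x.index)
        resid = rolling_median_residual(y, x, n_windows=5, overlap=2)
        np.testing.assert_allclose(resid, 0.0)

    def test_matches_bruteforce_window_enumeration(self, rng):
        ids = [f"g{i:03d}" for i in range(120)]
        y = rng.normal(size=120)
        x = rng.normal(size=120)
        resid = rolling_median_residual(
            pd.Series(y, index=ids), pd.Series(x, index=ids),
            n_windows=4, overlap=10,
        )
        expected = rolling_median_residual_bruteforce(
            list(y), list(x), ids, n_windows=4, overlap=10
        )
        np.testing.assert_allclose(resid.to_numpy(), expected, atol=1e-12)

    def test_too_few_items_reduces_window_count(self, rng):
        ids = list("abcdef")
        y = pd.Series(rng.normal(size=6), index=ids)
        x = pd.Series(rng.normal(size=6), index=ids)
        with pytest.warns(UserWarning, match="reducing"):
            resid = rolling_median_residual(y, x, n_windows=50, overlap=25)
        assert np.isfinite(resid).all()


class TestDMStatistic:
    def test_gene_order_permutation_invariant(self, rng):
        counts = rng.negative_binomial(5, 0.02, size=(80, 6))
        ids = [f"g{i}" for i in range(80)]
        lengths = pd.Series(rng.integers(500, 5000, 80).astype(float), index=ids)
        dm1 = dm_statistic(_cpm(counts, ids), lengths, n_windows=6, overlap=3)
        perm = rng.permutation(80)
        dm2 = dm_statistic(
            _cpm(counts[perm], [ids[i] for i in perm]),
            lengths, n_windows=6, overlap=3,
        )
        for g in ids:
            np.testing.assert_allclose(
                dm1.table.loc[g, "dm"], dm2.table.loc[g, "dm"], atol=1e-12
            )

    def test_library_scaling_invariant(self, rng):
        counts = rng.negative_binomial(5, 0.02, size=(60, 5))
        ids = [f"g{i}" for i in range(60)]
        lengths = pd.Series(rng.integers(500, 5000, 60).astype(float), index=ids)
        dm1 = dm_statistic(_cpm(counts, ids), lengths, n_windows=5, overlap=2)
        dm2 = dm_statistic(_cpm(counts * 2, ids), lengths, n_windows=5, overlap=2)
        np.testing.assert_allclose(
            dm1.table["dm"], dm2.table["dm"], atol=1e-10
        )

    def test_matches_end_to_end_bruteforce(self, rng):
        counts = rng.negative_binomial(8, 0.03, size=(200, 10)) + 1
        ids = [f"g{i:03d}" for i in range(200)]
        lengths = rng.integers(300, 8000, 200).astype(float)
        res = dm_statistic(
            _cpm(counts, ids), pd.Series(lengths, index=ids),
            n_windows=10, overlap=5,
        )
        cpm = counts / counts.sum(axis=0, keepdims=True) * 1e6
        expected = dm_bruteforce(cpm, ids, lengths, n_windows=10, overlap=5)
        np.testing.assert_allclose(
            res.table["dm"].to_numpy(), expected, atol=1e-10
        )

    def test_zero_variance_genes_get_sentinel_below_minimum(self, rng):
        counts = rng.negative_binomial(8, 0.03, size=(50, 4)) + 1
        counts[7] = 1000
        # equalize library sizes so a count-constant gene is CPM-constant
        counts[49] = 0
        counts[49] = counts.sum(axis=0).max() - counts.sum(axis=0)
        ids = [f"g{i}" for i in range(50)]
        res = dm_statistic(_cpm(counts, ids), None, n_windows=4, overlap=2)
        table = res.table
        assert table.loc["g7", "zero_cv2"]
        others = table.loc[~table["zero_cv2"], "dm"]
        assert table.loc["g7", "dm"] == pytest.approx(others.min() - 1.0)

    def test_without_lengths_flag_recorded(self, rng):
        counts = rng.negative_binomial(8, 0.03, size=(40, 4)) + 1
        with pytest.warns(UserWarning, match="lengths absent"):
            res = dm_statistic(_cpm(counts), None, n_windows=4, overlap=2)
        assert not res.length_corrected

    def test_mean_independence_on_trend_only_simulation(self):
        # dispersion varies with the mean but no planted outliers:
        # DM should be uncorrelated with mean expression
        rhos = []
        for seed in range(3):
            cm, _, _ = simulate_cohort(
                null_spec(n_genes=1500, samples_per_group=10, paired=False,
                          seed=seed + 100)
            )
            filt = pp.filter_expressed(cm)
            res = dm_statistic(pp.compute_cpm(filt), filt.gene_lengths)
            t = res.table[~res.table["zero_cv2"]]
            rhos.append(abs(spearmanr(t["dm"], t["mean_cpm"]).statistic))
        assert max(rhos) < 0.15


class TestSelectHVGs:
    def test_threshold_and_ordering(self):
        table = pd.DataFrame(
            {"dm": [2.5, 0.9, 1.01, 2.5, -0.5]},
            index=["a", "b", "c", "d", "e"],
        )
        assert select_hvgs(table) == ["a", "d", "c"]

    def test_all_below_threshold_warns_empty(self):
        table = pd.DataFrame({"dm": [0.5, -1.0]}, index=["a", "b"])
        with pytest.warns(UserWarning):
            assert select_hvgs(table) == []

    def test_recovers_planted_variable_genes(self):
        # small planted-truth check; the full-size recovery runs in the
        # acceptance suite
        hits, total = 0, 0
        for seed in (1, 2):
            spec = SimSpec(n_genes=800, n_hvg=50, n_crg=0, n_drg=0,
                           n_signature=0, samples_per_group=6,
                           paired=False, seed=seed)
            cm, _, truth = simulate_cohort(spec)
            filt = pp.filter_expressed(cm)
            res = dm_statistic(pp.compute_cpm(filt), filt.gene_lengths)
            hvgs = set(select_hvgs(res))
            planted = set(truth.genes.index[truth.genes["hvg"]])
            hits += len(hvgs & planted)
            total += len(planted)
        assert hits / total >= 0.9
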