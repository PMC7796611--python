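import numpy as np
import pandas as pd
import pytest

from conftest import make_count_matrix, random_count_matrix
from mscvar import preprocess as pp
from mscvar.containers import ExpressionMatrix, ValidationError


class TestCPM:
    def test_million_library_is_identity(self):
        counts = np.array([[400_000], [600_000]])
        cpm = pp.compute_cpm(make_count_matrix(counts))
        np.testing.assert_allclose(cpm.values.to_numpy(), counts)

    def test_matches_per_cell_formula(self, rng):
        cm = random_count_matrix(rng, n_genes=5, n_samples=3)
        cpm = pp.compute_cpm(cm).values.to_numpy()
        raw = cm.counts.to_numpy().astype(float)
        lib = raw.sum(axis=0)
        for g in range(5):
            for s in range(3):
                np.testing.assert_allclose(
                    cpm[g, s], raw[g, s] / lib[s] * 1e6, rtol=1e-10
                )

    def test_columns_sum_to_million(self, rng):
        cm = random_count_matrix(rng, n_genes=80, n_samples=5)
        for em in (pp.compute_cpm(cm),):
            np.testing.assert_allclose(
                em.values.sum(axis=0), 1e6, rtol=1e-6
            )

    def test_zero_library_sample_named(self):
        cm = make_count_matrix([[1, 0], [2, 0]])
        with pytest.raises(ValidationError, match="s1"):
            pp.compute_cpm(cm)


class TestTPM:
    def test_equal_lengths_proportional_to_cpm(self, rng):
        cm = random_count_matrix(rng, n_genes=20, n_samples=4)
        cm = make_count_matrix(cm.counts.to_numpy(), lengths=[1000] * 20)
        tpm = pp.compute_tpm(cm).values.to_numpy()
        cpm = pp.compute_cpm(cm).values.to_numpy()
        np.testing.assert_allclose(tpm, cpm, rtol=1e-10)

    def test_hand_computed_four_gene_example(self):
        counts = np.array([[100], [200], [50], [100]])
        lengths = [1000, 2000, 500, 1000]
        cm = make_count_matrix(counts, lengths=lengths)
        rates = counts[:, 0] / np.array(lengths)
        expected = rates / rates.sum() * 1e6
        tpm = pp.compute_tpm(cm).values.to_numpy()[:, 0]
        np.testing.assert_allclose(tpm, expected, rtol=1e-10)
        np.testing.assert_allclose(tpm.sum(), 1e6, rtol=1e-9)

    def test_requires_lengths(self, rng):
        cm = random_count_matrix(rng)
        with pytest.raises(ValidationError, match="lengths"):
            pp.compute_tpm(cm)


class TestExpressedFilter:
    def test_boundary_of_ceil_rule(self, rng):
        # 10 samples: threshold is ceil(0.1*10)=1 sample above CPM 1
        base = np.full((3, 10), 2000)
        base[1] = 0
        base[1, 0] = 50  # CPM ~ 8000 in sample 0 only -> retained
        base[2] = 0      # never above threshold -> dropped
        cm = make_count_matrix(base)
        kept = pp.filter_expressed(cm)
        assert kept.gene_ids == ["g0", "g1"]

    def test_idempotent(self, rng):
        cm = random_count_matrix(rng, n_genes=200, n_samples=12)
        once = pp.filter_expressed(cm)
        twice = pp.filter_expressed(once)
        assert once.gene_ids == twice.gene_ids

    def test_gene_order_preserved(self, rng):
        cm = random_count_matrix(rng, n_genes=100, n_samples=6)
        kept = pp.filter_expressed(cm)
        original = [g for g in cm.gene_ids if g in set(kept.gene_ids)]
        assert kept.gene_ids == original


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10, 200, 3000, 40, 500])
        cm = make_count_matrix(np.tile(col[:, None], (1, 4)))
        nf = pp.tmm_factors(cm)
        np.testing.assert_allclose(nf.table["tmm_factor"], 1.0)

    def test_doubled_sample_absorbed_by_library_size(self, rng):
        # the trimmed M statistics are exactly scale-invariant, but the
        # precision weights depend on raw counts, so the published TMM
        # algorithm is only approximately invariant to per-sample scaling
        counts = rng.negative_binomial(5, 0.05, size=(300, 3))
        counts = np.column_stack([counts, counts[:, 0] * 2])
        nf = pp.tmm_factors(make_count_matrix(counts))
        f = nf.table["tmm_factor"].to_numpy()
        np.testing.assert_allclose(f[0], f[3], rtol=0.02)

    def test_scaling_one_sample_leaves_factors_unchanged(self, rng):
        counts = rng.negative_binomial(5, 0.05, size=(400, 5)).astype(float)
        nf1 = pp.tmm_factors(make_count_matrix(counts))
        scaled = counts.copy()
        scaled[:, 2] *= 7
        nf2 = pp.tmm_factors(make_count_matrix(scaled))
        np.testing.assert_allclose(
            nf1.table["tmm_factor"], nf2.table["tmm_factor"], atol=0.02
        )

    def test_geometric_mean_is_one(self, rng):
        cm = random_count_matrix(rng, n_genes=500, n_samples=8)
        nf = pp.tmm_factors(cm)
        assert abs(np.mean(np.log(nf.table["tmm_factor"]))) < 1e-8

    def test_requires_two_samples(self):
        with pytest.raises(ValidationError):
            pp.tmm_factors(make_count_matrix([[5], [10]]))


class TestLogNormalize:
    def test_hand_formula_with_unit_factors(self):
        cm = make_count_matrix([[0, 10], [5, 20], [15, 70]])
        nf = pp.tmm_factors(
            make_count_matrix(np.tile([[10], [20], [70]], (1, 2)))
        )
        # use unit factors from identical columns but this cohort's sizes
        nf.table["library_size"] = cm.library_sizes().to_numpy()
        out = pp.log_normalize(cm, nf).values.to_numpy()
        lib = cm.counts.sum(axis=0).to_numpy()
        expected = np.log2(cm.counts.to_numpy() / lib * 1e6 + 1)
        np.testing.assert_allclose(out, expected, rtol=1e-10)
        assert out[0, 0] == 0.0  # zero count -> log2(0 + 1)

    def test_monotone_in_counts_within_sample(self, rng):
        cm = random_count_matrix(rng, n_genes=50, n_samples=4)
        nf = pp.tmm_factors(cm)
        out = pp.log_normalize(cm, nf)
        col = out.values.iloc[:, 0]
        raw = cm.counts.iloc[:, 0]
        order = np.argsort(raw.to_numpy(), kind="stable")
        assert (np.diff(col.to_numpy()[order]) >= -1e-12).all()


class TestCorrelationQC:
    def _logcpm(self, counts):
        cm = make_count_matrix(counts)
        return pp.log_normalize(cm, pp.tmm_factors(cm))

    def test_duplicate_samples_pass_and_outlier_fails(self, rng):
        base = rng.negative_binomial(20, 0.02, size=200).astype(float)
        cohort = np.column_stack([
            rng.poisson(base) for _ in range(5)
        ] + [base, base])
        noise = rng.integers(0, 2000, size=(200, 1))
        counts = np.column_stack([cohort, noise])
        qc = pp.correlation_qc(self._logcpm(counts))
        assert qc["pass"].iloc[5] and qc["pass"].iloc[6]
        assert qc["median_r"].iloc[5] > 0.95
        assert not qc["pass"].iloc[7]  # pure-noise sample

    def test_permutation_equivariant(self, rng):
        counts = rng.negative_binomial(10, 0.02, size=(150, 6))
        em = self._logcpm(counts)
        qc = pp.correlation_qc(em)
        perm = list(np.array(em.sample_ids)[[3, 1, 5, 0, 2, 4]])
        qc_perm = pp.correlation_qc(
            ExpressionMatrix(em.values[perm], "logcpm")
        )
        for sid in em.sample_ids:
            np.testing.assert_allclose(
                qc.loc[sid, "median_r"], qc_perm.loc[sid, "median_r"]
            )

    def test_constant_sample_flagged_with_reason(self, rng):
        counts = rng.negative_binomial(10, 0.02, size=(100, 4)).astype(float)
        counts[:, 0] = 7.0
        em = ExpressionMatrix(
            pd.DataFrame(counts, index=[f"g{i}" for i in range(100)],
                         columns=list("abcd")),
            "logcpm",
        )
        qc = pp.correlation_qc(em)
        assert not qc.loc["a", "pass"]
        assert "constant" in qc.loc["a", "reason"]


class TestMarkerQC:
    def test_planted_markers_rank_as_expected(self, rng):
        n = 200
        counts = rng.negative_binomial(10, 0.02, size=(n, 5))
        ids = [f"g{i}" for i in range(n)]
        ids[0], ids[1] = "ENG", "PTPRC"
        counts[0] = 50_000   # constitutively high positive marker
        counts[1] = 0        # absent negative marker
        cm = make_count_matrix(counts, gene_ids=ids, lengths=[1000] * n)
        report = pp.marker_qc(pp.compute_tpm(cm))
        assert (
            report.loc["ENG", "median_rank_percentile"]
            > report.loc["PTPRC", "median_rank_percentile"]
        )
        assert not report.loc["ENG", "missing"]

    def test_missing_marker_reported_not_fatal(self, rng):
        cm = random_count_matrix(rng, n_genes=30, with_lengths=True)
        report = pp.marker_qc(pp.compute_tpm(cm))
        assert report["missing"].all()
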