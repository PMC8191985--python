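"""Expression plumbing: FPKM/logCPM formula oracles, filtering, PCA,
correlation and the simple DE stage."""

import numpy as np
import pandas as pd
import pytest

from hybridase.exprqc import (
    CountsMatrix,
    average_dual_counts,
    cross_dataset_correlation,
    filter_low_expression,
    fpkm,
    log_cpm,
    pca_summary,
    simple_de_test,
)
from hybridase.types import ValidationError


def matrix(values, samples=None, groups=None, genes=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    groups = groups or {s: "VV" for s in samples}
    return CountsMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=groups,
    )


class TestAverage:
    def test_elementwise_mean(self):
        out = average_dual_counts(matrix([[10.0]]), matrix([[20.0]]))
        assert out.values.iloc[0, 0] == 15.0

    def test_identity_on_identical_matrices(self):
        m = matrix([[3.0, 4.0], [5.0, 6.0]])
        out = average_dual_counts(m, m)
        assert (out.values == m.values).all().all()

    def test_mismatched_gene_sets_error_lists_difference(self):
        a = matrix([[1.0]], genes=["gA"])
        b = matrix([[1.0]], genes=["gB"])
        with pytest.raises(ValidationError, match="gA"):
            average_dual_counts(a, b)

    def test_column_order_does_not_matter(self):
        a = matrix([[1.0, 2.0]], samples=["s1", "s2"],
                   groups={"s1": "VV", "s2": "GG"})
        b = matrix([[4.0, 3.0]], samples=["s2", "s1"],
                   groups={"s1": "VV", "s2": "GG"})
        out = average_dual_counts(a, b)
        assert list(out.values.loc["g0"]) == [2.0, 3.0]


class TestFpkm:
    def test_formula_worked_example(self):
        # one gene carries the whole 1e6-read library; length 1 kb
        m = matrix([[10.0], [1e6 - 10.0]])
        lengths = pd.Series({"g0": 1000, "g1": 1000})
        assert fpkm(m, lengths).iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        m = matrix([[0.0], [100.0]])
        lengths = pd.Series({"g0": 500, "g1": 500})
        assert fpkm(m, lengths).iloc[0, 0] == 0.0

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 500, size=(30, 4)).astype(float)
        m = matrix(vals)
        lengths = pd.Series(rng.integers(200, 5000, size=30).astype(float),
                            index=m.values.index)
        got = fpkm(m, lengths).values
        lib = vals.sum(axis=0)
        expected = vals * 1e9 / lengths.values[:, None] / lib[None, :]
        assert np.allclose(got, expected, rtol=1e-9)

    def test_zero_library_rejected(self):
        m = matrix([[0.0]])
        with pytest.raises(ValidationError, match="library"):
            fpkm(m, pd.Series({"g0": 100}))


class TestFilter:
    def lengths(self, m):
        return pd.Series(1000.0, index=m.values.index)

    def test_kept_if_one_group_mean_clears_threshold(self):
        groups = {"a": "VV", "b": "GG"}
        # libraries ~1e6 via the filler gene; with 1 kb genes FPKM == count
        # in units of reads: gene0 high in VV only, gene1 < 0.5 everywhere
        m = matrix([[1000.0, 0.0], [0.2, 0.2], [1e6, 1e6]],
                   samples=["a", "b"], groups=groups)
        out = filter_low_expression(m, self.lengths(m))
        assert list(out.values.index) == ["g0", "g2"]

    def test_boundary_mean_exactly_threshold_kept(self):
        # single sample, two genes; choose counts so gene0's FPKM is 0.5
        m = matrix([[1.0], [1999999.0]])
        out = filter_low_expression(m, self.lengths(m), threshold=0.5)
        assert "g0" in out.values.index

    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(1)
        m = matrix(rng.integers(0, 2000, size=(40, 6)).astype(float))
        once = filter_low_expression(m, self.lengths(m))
        twice = filter_low_expression(once, pd.Series(1000.0, index=once.values.index))
        assert set(once.values.index) <= set(m.values.index)
        assert list(once.values.index) == list(twice.values.index)


class TestLogCpm:
    def test_limit_matches_plain_log2_cpm(self):
        m = matrix([[100.0], [1e6 - 100.0]])
        got = log_cpm(m, prior=1e-9).iloc[0, 0]
        assert got == pytest.approx(np.log2(100), abs=1e-5)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 300, size=(20, 5)).astype(float)
        m = matrix(vals)
        got = log_cpm(m, prior=0.5).values
        lib = vals.sum(axis=0)
        expected = np.log2((vals + 0.5) / (lib + 1.0)[None, :] * 1e6)
        assert np.allclose(got, expected, rtol=1e-12)

    def test_all_zero_sample_is_constant_column(self):
        m = matrix([[0.0, 5.0], [0.0, 7.0]])
        col = log_cpm(m).iloc[:, 0]
        assert col.nunique() == 1


class TestPca:
    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(3)
        logcpm = pd.DataFrame(rng.normal(size=(50, 6)),
                              columns=[f"s{i}" for i in range(6)])
        pca = pca_summary(logcpm)
        assert pca.proportions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_cluster_fixture_separates_on_pc1(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=50)
        cols = {}
        for i in range(3):
            cols[f"A{i}"] = base + 5 + rng.normal(scale=0.1, size=50)
        for i in range(3):
            cols[f"B{i}"] = base - 5 + rng.normal(scale=0.1, size=50)
        pca = pca_summary(pd.DataFrame(cols))
        pc1 = pca.projections["PC1"]
        assert pca.proportions[0] > pca.proportions[1:].max()
        assert (pc1[:3].values > 0).all() != (pc1[3:].values > 0).all()

    def test_sample_permutation_permutes_projections(self):
        rng = np.random.default_rng(5)
        logcpm = pd.DataFrame(rng.normal(size=(30, 5)),
                              columns=list("abcde"))
        p1 = pca_summary(logcpm).projections
        p2 = pca_summary(logcpm[list("edcba")]).projections
        assert np.allclose(np.abs(p1.loc[list("abcde")].values),
                           np.abs(p2.loc[list("abcde")].values))

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValidationError):
            pca_summary(pd.DataFrame({"s": [1.0, 2.0]}))


class TestCorrelation:
    def test_identical_vectors(self):
        v = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert cross_dataset_correlation(v, v) == pytest.approx(1.0)

    def test_exact_negation(self):
        v = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert cross_dataset_correlation(v, -v) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        a = pd.Series(rng.normal(size=40))
        b = pd.Series(rng.normal(size=40))
        r = cross_dataset_correlation(a, b)
        za = (a - a.mean()) / a.std(ddof=0)
        zb = (b - b.mean()) / b.std(ddof=0)
        assert r == pytest.approx((za * zb).mean())

    def test_constant_vector_signalled(self):
        v = pd.Series([1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            cross_dataset_correlation(v, pd.Series([1.0, 2.0, 3.0]))


class TestDe:
    def groups(self):
        return {f"v{i}": "VV" for i in range(3)} | {f"g{i}": "GG" for i in range(3)}

    def test_identical_groups_not_de(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(20, 3))
        logcpm = pd.DataFrame(
            np.hstack([base, base]),
            columns=[f"v{i}" for i in range(3)] + [f"g{i}" for i in range(3)],
        )
        de = simple_de_test(logcpm, self.groups(), ("VV", "GG"))
        assert not de["is_DE"].any()
        assert np.allclose(de["log2FC"], 0.0)

    def test_planted_fold_changes_recovered(self):
        rng = np.random.default_rng(8)
        n = 200
        vals = rng.normal(5, 0.05, size=(n, 6))
        vals[:20, :3] += 4  # 16-fold in the first group
        logcpm = pd.DataFrame(
            vals, columns=[f"v{i}" for i in range(3)] + [f"g{i}" for i in range(3)]
        )
        de = simple_de_test(logcpm, self.groups(), ("VV", "GG"))
        assert de["is_DE"][:20].mean() >= 0.9
        assert not de["is_DE"][20:].any()
        assert de["log2FC"][:20].mean() == pytest.approx(4.0, abs=0.1)

    def test_small_group_rejected(self):
        logcpm = pd.DataFrame(np.zeros((5, 3)), columns=["v0", "v1", "g0"])
        groups = {"v0": "VV", "v1": "VV", "g0": "GG"}
        with pytest.raises(ValidationError):
            simple_de_test(logcpm, groups, ("VV", "GG"))
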