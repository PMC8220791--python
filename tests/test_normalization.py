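import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from quantbench import count_normalization as norm
from quantbench.errors import (
    ConsistencyError,
    NoReferenceGeneError,
    TrimExhaustedError,
)

from conftest import make_matrix
from oracles import median_ratio_factors_bruteforce, tmm_factor_bruteforce


class TestMedianRatio:
    def test_toy_two_samples(self):
        m = make_matrix([[2.0, 4.0], [4.0, 8.0]])
        f = norm.size_factors_median_ratio(m)
        np.testing.assert_allclose(f.factor, [0.70710678, 1.41421356], rtol=1e-7)
        normed = norm.apply_factors(m, f)
        np.testing.assert_allclose(normed.values[:, 0], normed.values[:, 1])
        np.testing.assert_allclose(normed.values[:, 0], [2.8284271, 5.6568542])

    def test_identical_samples_factor_one(self):
        m = make_matrix(np.tile([[3.0], [9.0], [27.0]], (1, 4)))
        np.testing.assert_allclose(
            norm.size_factors_median_ratio(m).factor, 1.0
        )

    def test_zero_gene_excluded_from_reference(self):
        m = make_matrix([[0.0, 0.0], [4.0, 8.0]])
        f = norm.size_factors_median_ratio(m)
        np.testing.assert_allclose(f.factor, [0.70710678, 1.41421356], rtol=1e-7)

    def test_no_reference_gene_raises(self):
        m = make_matrix([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(NoReferenceGeneError):
            norm.size_factors_median_ratio(m)

    def test_depth_scaling_recovered(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=40).astype(float)
        scales = np.array([0.5, 1.0, 2.0, 4.0])
        m = make_matrix(base[:, None] * scales[None, :])
        f = norm.size_factors_median_ratio(m)
        ratio = f.factor / scales
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.poisson(50, size=(30, 4)).astype(float)
        x[rng.random(x.shape) < 0.1] = 0.0
        x[0] = [20, 30, 40, 50]  # ensure a reference gene exists
        f = norm.size_factors_median_ratio(m := make_matrix(x))
        expected = median_ratio_factors_bruteforce(
            [np.rint(x[:, j]).tolist() for j in range(4)]
        )
        np.testing.assert_allclose(f.factor, expected, rtol=1e-12)

    def test_gene_reordering_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(30, size=(25, 3)).astype(float) + 1
        perm = rng.permutation(25)
        f1 = norm.size_factors_median_ratio(make_matrix(x))
        f2 = norm.size_factors_median_ratio(make_matrix(x[perm]))
        np.testing.assert_allclose(f1.factor, f2.factor)


class TestApplyFactors:
    def test_unit_factors_identity(self):
        m = make_matrix([[2.0, 3.0], [4.0, 5.0]])
        f = norm.NormalizationFactors(
            m.sample_ids, np.ones(2), "median_ratio", m.values.sum(axis=0)
        )
        np.testing.assert_array_equal(norm.apply_factors(m, f).values, m.values)

    def test_scaling_inverse(self):
        base = np.array([[2.0], [4.0]])
        c = 3.0
        m = make_matrix(np.hstack([base, base * c]))
        f = norm.NormalizationFactors(
            m.sample_ids, np.array([1.0, c]), "median_ratio", m.values.sum(axis=0)
        )
        out = norm.apply_factors(m, f)
        np.testing.assert_allclose(out.values[:, 1], base[:, 0])

    def test_sample_mismatch_rejected(self):
        m = make_matrix([[1.0, 2.0]])
        f = norm.NormalizationFactors(
            ["x", "y"], np.ones(2), "median_ratio", np.ones(2)
        )
        with pytest.raises(ConsistencyError):
            norm.apply_factors(m, f)


class TestTmm:
    def test_identical_samples_factor_one(self):
        col = np.array([100.0, 200.0, 50.0, 400.0])
        m = make_matrix(np.tile(col[:, None], (1, 3)))
        np.testing.assert_allclose(norm.tmm_factors(m).factor, 1.0, atol=1e-12)

    def test_depth_only_difference_factor_one(self):
        col = np.arange(1.0, 41.0)
        m = make_matrix(np.hstack([col[:, None], 3 * col[:, None]]))
        np.testing.assert_allclose(norm.tmm_factors(m).factor, 1.0, atol=1e-12)

    def test_untrimmed_unweighted_toy(self):
        """One 7-fold gene among equals: factor 2^((3*log2(0.4)+log2(2.8))/4)."""
        a = np.array([100.0, 100.0, 100.0, 100.0])
        b = np.array([100.0, 100.0, 100.0, 700.0])
        m = make_matrix(np.column_stack([a, b]))
        f = norm.tmm_factors(
            m, reference="s1", logratio_trim=0.0, abs_trim=0.0, weighted=False
        )
        before_rescale = f.factor[1] / f.factor[0]  # geomean-1 rescale preserved ratio
        expected = 2 ** ((3 * np.log2(0.4) + np.log2(2.8)) / 4)
        assert before_rescale == pytest.approx(expected**1, rel=1e-10)
        assert expected == pytest.approx(0.6506, abs=5e-5)

    def test_symmetry_untrimmed_unweighted(self):
        rng = np.random.default_rng(7)
        x = rng.poisson(80, size=(50, 2)).astype(float) + 1
        m = make_matrix(x)
        fab = norm.tmm_factors(
            m, reference="s1", logratio_trim=0.0, abs_trim=0.0, weighted=False
        )
        fba = norm.tmm_factors(
            m, reference="s2", logratio_trim=0.0, abs_trim=0.0, weighted=False
        )
        assert fab.factor[1] / fab.factor[0] == pytest.approx(
            fba.factor[1] / fba.factor[0], rel=1e-10
        )

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_bruteforce_oracle_default_trims(self, seed, weighted):
        rng = np.random.default_rng(seed)
        x = rng.negative_binomial(5, 0.05, size=(200, 3)).astype(float)
        x[0] += 1  # avoid empty both-positive sets
        m = make_matrix(x)
        f = norm.tmm_factors(m, reference="s1", weighted=weighted)
        lib = x.sum(axis=0)
        for j, sid in enumerate(["s2", "s3"]):
            expected = tmm_factor_bruteforce(
                x[:, j + 1], x[:, 0], lib[j + 1], lib[0], 0.30, 0.05, weighted
            )
            assert f.factor[j + 1] / f.factor[0] == pytest.approx(
                expected, rel=1e-10
            )

    def test_factors_geometric_mean_one(self):
        rng = np.random.default_rng(11)
        x = rng.poisson(60, size=(100, 5)).astype(float) + 1
        f = norm.tmm_factors(make_matrix(x))
        assert np.exp(np.mean(np.log(f.factor))) == pytest.approx(1.0, rel=1e-12)

    def test_gene_reordering_invariant(self):
        rng = np.random.default_rng(13)
        x = rng.poisson(40, size=(60, 3)).astype(float) + 1
        perm = rng.permutation(60)
        f1 = norm.tmm_factors(make_matrix(x), reference="s1")
        f2 = norm.tmm_factors(make_matrix(x[perm]), reference="s1")
        np.testing.assert_allclose(f1.factor, f2.factor)

    def test_trim_exhausted_error(self):
        # M-ranks keep the middle two genes, A-ranks keep the other two:
        # the intersection of kept genes is empty
        qs = [0.5, 0.0707, 14.14, 2.0]
        qr = [2.0, 0.1414, 7.07, 0.5]
        m = make_matrix(np.column_stack([qr, qs]))
        with pytest.raises(TrimExhaustedError):
            norm.tmm_factors(m, reference="s1", logratio_trim=0.3, abs_trim=0.3)

    @given(
        x=hnp.arrays(float, (30, 2), elements=st.floats(1, 1e4)),
    )
    def test_symmetry_property(self, x):
        m = make_matrix(x)
        fab = norm.tmm_factors(
            m, reference="s1", logratio_trim=0.0, abs_trim=0.0, weighted=False
        )
        fba = norm.tmm_factors(
            m, reference="s2", logratio_trim=0.0, abs_trim=0.0, weighted=False
        )
        r1 = fab.factor[1] / fab.factor[0]
        r2 = fba.factor[0] / fba.factor[1]
        assert r1 * r2 == pytest.approx(1.0, rel=1e-9)


class TestTmmOnTpm:
    def test_identical_columns_identity(self):
        col = np.array([5e5, 3e5, 2e5])
        m = make_matrix(np.tile(col[:, None], (1, 3)), measure="tpm")
        out = norm.tmm_on_tpm(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_factors_geomean_one(self, contaminated_dataset):
        from quantbench import rsem_io

        samples, _g, _t = contaminated_dataset
        tpm = rsem_io.assemble_matrix(samples, "tpm")
        out = norm.tmm_on_tpm(tpm)
        f = out.meta["tmm_factors"].factor
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, rel=1e-10)

    def test_contaminated_columns_realigned(self, contaminated_dataset):
        """TMM-on-TPM shrinks the replicate-to-replicate shift of
        non-dominant genes in contaminated models; dominant genes stay off."""
        from quantbench import rsem_io

        samples, grouping, truth = contaminated_dataset
        tpm = rsem_io.assemble_matrix(samples, "tpm")
        out = norm.tmm_on_tpm(tpm)
        dom = np.isin(tpm.gene_ids, truth.dominant_gene_ids)
        model = next(m for m, c in truth.contaminated.items() if c)
        reps = grouping.samples_of(model)
        fr = [truth.dominant_fraction[s] for s in reps]
        a, b = reps[int(np.argmin(fr))], reps[int(np.argmax(fr))]

        def shift(mat):
            la = np.log2(mat.column(a)[~dom] + 1)
            lb = np.log2(mat.column(b)[~dom] + 1)
            return abs(np.median(la - lb))

        assert shift(out) < shift(tpm)
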