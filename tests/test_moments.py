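import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cokurt.errors import (
    DegenerateFeatureError,
    DegenerateSpectrumError,
    DistributionError,
    WindowTooShortError,
)
from cokurt.moments import (
    CokurtosisTensor,
    SpectralFactors,
    cokurtosis_tensor,
    derive_features,
    feature_moment_metric,
    fmm_of,
    hellinger_distance,
    hosvd_factors,
    standardize,
)


def brute_force_cokurtosis(Z: np.ndarray) -> np.ndarray:
    """Quadruple-loop evaluation of the cumulant formula (the oracle)."""
    m = Z.shape[1]

    def E(*cols):
        return float(np.mean(np.prod([Z[:, c] for c in cols], axis=0)))

    T = np.empty((m, m, m, m))
    for i, j, k, l in itertools.product(range(m), repeat=4):
        T[i, j, k, l] = (
            E(i, j, k, l) - E(i, j) * E(k, l) - E(i, k) * E(j, l) - E(i, l) * E(j, k)
        )
    return T


class TestStandardize:
    def test_two_point_column(self):
        Z = standardize(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(Z.values, [[-1.0], [1.0]])

    def test_identity_on_standardized_input(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 3))
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        np.testing.assert_allclose(standardize(X).values, X, atol=1e-10)

    def test_constant_column_raises(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 5.0)])
        with pytest.raises(DegenerateFeatureError, match="f1"):
            standardize(X)

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(1)
        X = rng.normal(10.0, 3.0, size=(64, 2))
        Z = standardize(X)
        np.testing.assert_allclose(Z.inverse(), X, atol=1e-10)


class TestCokurtosisTensor:
    def test_rademacher_diagonal(self):
        # two-point {-1, +1} sample: E[x^4] - 3 E[x^2]^2 = 1 - 3 = -2
        T = cokurtosis_tensor(np.array([[-1.0], [1.0]]))
        assert T.entries[0, 0, 0, 0] == pytest.approx(-2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(8, 51)), int(rng.integers(2, 5))
        Z = standardize(rng.normal(size=(n, m))).values
        T = cokurtosis_tensor(Z).entries
        np.testing.assert_allclose(T, brute_force_cokurtosis(Z), atol=1e-10)

    def test_full_index_symmetry(self):
        rng = np.random.default_rng(7)
        Z = standardize(rng.gamma(2.0, size=(200, 3))).values
        T = cokurtosis_tensor(Z).entries
        for perm in itertools.permutations(range(4)):
            np.testing.assert_allclose(T, T.transpose(perm), atol=1e-10)

    def test_gaussian_null_large_n(self):
        rng = np.random.default_rng(11)
        Z = standardize(rng.normal(size=(100_000, 2))).values
        T = cokurtosis_tensor(Z).entries
        assert np.abs(T).max() < 0.05

    def test_gaussian_null_rate(self):
        # mean |T| should scale ~ n^{-1/2}: sqrt(n) * mean|T| roughly flat
        scaled = []
        for n in (1000, 4000, 16000):
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                Z = standardize(rng.normal(size=(n, 2))).values
                vals.append(np.abs(cokurtosis_tensor(Z).entries).mean())
            scaled.append(np.sqrt(n) * np.mean(vals))
        assert max(scaled) / min(scaled) < 2.0

    def test_diagonal_is_excess_kurtosis(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(size=2000)
        Z = standardize(x[:, None]).values
        T = cokurtosis_tensor(Z)
        kurt = np.mean(Z[:, 0] ** 4) - 3.0
        assert T.entries[0, 0, 0, 0] == pytest.approx(kurt, abs=1e-10)


class TestHosvd:
    def test_rank_one_symmetric(self):
        v = np.array([1.0, 0.0])
        T = 2.0 * np.einsum("i,j,k,l->ijkl", v, v, v, v)
        S = hosvd_factors(CokurtosisTensor(entries=T))
        np.testing.assert_allclose(S.singular_values, [2.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(S.singular_vectors[:, 0]), v, atol=1e-12)

    def test_zero_tensor(self):
        S = hosvd_factors(CokurtosisTensor(entries=np.zeros((3, 3, 3, 3))))
        np.testing.assert_allclose(S.singular_values, 0.0)

    def test_descending_orthonormal(self):
        rng = np.random.default_rng(5)
        Z = standardize(rng.gamma(1.5, size=(300, 4))).values
        S = hosvd_factors(cokurtosis_tensor(Z))
        assert np.all(np.diff(S.singular_values) <= 1e-12)
        assert np.all(S.singular_values >= 0)
        V = S.singular_vectors
        np.testing.assert_allclose(V.T @ V, np.eye(4), atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(5)
        Z = standardize(rng.gamma(1.5, size=(300, 3))).values
        S1 = hosvd_factors(cokurtosis_tensor(Z))
        S2 = hosvd_factors(cokurtosis_tensor(Z))
        np.testing.assert_array_equal(S1.singular_vectors, S2.singular_vectors)
        for k in range(3):
            col = S1.singular_vectors[:, k]
            assert col[np.argmax(np.abs(col))] >= 0


class TestFeatureMomentMetric:
    def test_spectrum_concentrated_on_second_feature(self):
        S = SpectralFactors(
            singular_values=np.array([3.0, 0.0]),
            singular_vectors=np.array([[0.0, 1.0], [1.0, 0.0]]),
        )
        np.testing.assert_allclose(feature_moment_metric(S).values, [0.0, 1.0])

    def test_symmetric_spectrum(self):
        S = SpectralFactors(
            singular_values=np.array([1.0, 1.0]), singular_vectors=np.eye(2)
        )
        np.testing.assert_allclose(feature_moment_metric(S).values, [0.5, 0.5])

    def test_zero_spectrum_raises(self):
        S = SpectralFactors(
            singular_values=np.zeros(2), singular_vectors=np.eye(2)
        )
        with pytest.raises(DegenerateSpectrumError):
            feature_moment_metric(S)

    @given(
        st.integers(min_value=2, max_value=6),
        st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_sums_to_unity(self, m, seed):
        rng = np.random.default_rng(seed)
        lam = rng.uniform(0.0, 10.0, size=m)
        lam[rng.integers(m)] += 0.1  # guarantee a nonzero total
        V, _ = np.linalg.qr(rng.normal(size=(m, m)))
        F = feature_moment_metric(
            SpectralFactors(singular_values=lam, singular_vectors=V)
        ).values
        assert abs(F.sum() - 1.0) < 1e-10
        assert np.all(F >= -1e-12) and np.all(F <= 1.0 + 1e-12)


class TestHellinger:
    def test_identity(self):
        p = np.array([0.2, 0.3, 0.5])
        assert hellinger_distance(p, p) == 0.0

    def test_disjoint_support_maximum(self):
        assert hellinger_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_closed_form(self):
        # sqrt(1 - (sqrt(.125) + sqrt(.375)))
        h = hellinger_distance([0.5, 0.5], [0.25, 0.75])
        assert h == pytest.approx(0.18459, abs=1e-5)

    def test_l2_form(self):
        h = hellinger_distance([0.5, 0.5], [0.25, 0.75], form="l2")
        assert h == pytest.approx(np.sqrt(0.0625 + 0.0625) / np.sqrt(2))

    def test_length_mismatch_raises(self):
        with pytest.raises(DistributionError):
            hellinger_distance([1.0], [0.5, 0.5])

    def test_negative_entry_raises(self):
        with pytest.raises(DistributionError):
            hellinger_distance([1.5, -0.5], [0.5, 0.5])

    @given(
        st.integers(min_value=2, max_value=8),
        st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_metric_axioms(self, m, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(m))
        q = rng.dirichlet(np.ones(m))
        h = hellinger_distance(p, q)
        assert 0.0 <= h <= 1.0 + 1e-12
        assert h == pytest.approx(hellinger_distance(q, p))
        assert hellinger_distance(p, p) < 1e-12


class TestDeriveFeatures:
    def test_single_block_hand_computed(self):
        D = derive_features([60.0, 62.0, 100.0, 61.0], block=4)
        np.testing.assert_allclose(D.values, [[70.75, 61.5, 60.0, 100.0]])
        assert D.feature_names == ["mean", "median", "min", "max"]

    def test_constant_series_constant_columns(self):
        D = derive_features(np.full(16, 70.0), block=4)
        assert np.ptp(D.values, axis=0).max() == 0.0

    def test_ramp_block_means(self):
        # linear ramp: consecutive block means differ by slope * block length
        slope, block = 2.0, 5
        x = slope * np.arange(10.0)
        D = derive_features(x, block=block)
        means = D.values[:, 0]
        assert means[1] - means[0] == pytest.approx(slope * block)

    def test_too_short_raises(self):
        with pytest.raises(WindowTooShortError):
            derive_features([1.0, 2.0], block=4)


class TestOutlierAlignment:
    def test_planted_outliers_align(self):
        from cokurt.simulate import ToySpec, toy_outlier_dataset

        hits = 0
        for seed in range(20):
            data, u = toy_outlier_dataset(ToySpec(n=1000), seed=seed)
            Z = standardize(data)
            S = hosvd_factors(cokurtosis_tensor(Z))
            u_std = u / Z.sds
            u_std = u_std / np.linalg.norm(u_std)
            if abs(u_std @ S.singular_vectors[:, 0]) > 0.9:
                hits += 1
        assert hits >= 19
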