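import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pefi import (
    IndicatorField,
    as_intensity_image,
    fcm_fit,
    fuzzy_event_entropy,
    indicator_code,
    krige_probability_field,
    pefi_features,
    scan_image,
    semivariance_at,
)
from pefi.geostat import drift_basis, empirical_semivariogram


def make_partition(seed=5, shape=(10, 10), c=2):
    gen = np.random.default_rng(seed)
    img = as_intensity_image(gen.random(shape))
    return fcm_fit(img, c=c, seed=seed), shape


@pytest.mark.parametrize(
    "membership, alpha, expected",
    [(0.75, 0.7, 1), (0.75, 0.8, 0), (0.7, 0.7, 1)],  # boundary is inclusive
)
def test_indicator_threshold(membership, alpha, expected):
    part, _ = make_partition()
    mu = part.memberships.copy()
    mu[:, 0] = membership
    mu[:, 1] = 1 - membership
    part2 = type(part)(memberships=mu, centers=part.centers, m=part.m)
    field = indicator_code(part2, 0, alpha, (10, 10))
    assert field.values.flat[0] == expected


def test_indicator_rejects_bad_alpha():
    part, shape = make_partition()
    for alpha in (0.0, 1.2, -0.1):
        with pytest.raises(ValueError):
            indicator_code(part, 0, alpha, shape)


def test_indicator_monotone_in_alpha():
    part, shape = make_partition(seed=21)
    for k in range(part.c):
        previous = None
        for alpha in (0.3, 0.5, 0.7, 0.9):
            field = indicator_code(part, k, alpha, shape)
            if previous is not None:
                # raising alpha never turns a 0 into a 1
                assert np.all(field.values <= previous)
            previous = field.values


@pytest.mark.parametrize("constant", [0, 1])
def test_constant_indicator_kriges_to_constant(constant):
    field = IndicatorField(
        values=np.full((8, 8), constant, dtype=np.uint8), cluster_index=0, alpha=0.5
    )
    kriged = krige_probability_field(field, k_neighbors=5)
    assert np.all(kriged.values == float(constant))


def _dense_field_oracle(z, K, method, degree, n_lags):
    """Per-pixel reference: nearest neighbors + explicit system inversion."""
    rows, cols = z.shape
    table = empirical_semivariogram(z.astype(float), n_lags=n_lags)
    coords = [(r, c) for r in range(rows) for c in range(cols)]
    out = np.empty(rows * cols)
    for i, (r, c) in enumerate(coords):
        ranked = sorted(
            (j for j in range(len(coords)) if j != i),
            key=lambda j: (math.dist(coords[i], coords[j]), j),
        )[:K]
        P = np.array([coords[j] for j in ranked], dtype=float)
        G = np.zeros((K, K))
        for a in range(K):
            for b in range(K):
                if a != b:
                    G[a, b] = semivariance_at(table, math.dist(P[a], P[b]))
        g = np.array([semivariance_at(table, math.dist(p, (r, c))) for p in P])
        if method == "OK":
            A = np.zeros((K + 1, K + 1))
            A[:K, :K] = G
            A[K, :K] = A[:K, K] = 1.0
            rhs = np.r_[g, 1.0]
        else:
            F = drift_basis(P, degree)
            L = F.shape[1]
            A = np.zeros((K + L, K + L))
            A[:K, :K] = G
            A[:K, K:] = F
            A[K:, :K] = F.T
            rhs = np.r_[g, drift_basis(np.array([r, c], dtype=float), degree)[0]]
        w = np.linalg.solve(A, rhs)[:K]
        out[i] = w @ z.ravel()[ranked]
    return np.clip(out, 0.0, 1.0).reshape(rows, cols)


@pytest.mark.parametrize("method, degree", [("OK", 1), ("UK", 1)])
def test_kriged_field_matches_dense_oracle(method, degree):
    gen = np.random.default_rng(3)
    z = (gen.random((12, 12)) > 0.4).astype(np.uint8)
    field = IndicatorField(values=z, cluster_index=0, alpha=0.5)
    kriged = krige_probability_field(
        field, k_neighbors=5, method=method, drift_degree=degree
    )
    oracle = _dense_field_oracle(z, K=5, method=method, degree=degree, n_lags=10)
    np.testing.assert_allclose(kriged.values, oracle, atol=1e-8)
    assert kriged.values.min() >= 0.0 and kriged.values.max() <= 1.0


def test_window_too_small_for_neighbors():
    field = IndicatorField(
        values=np.array([[0, 1], [1, 0]], dtype=np.uint8), cluster_index=0, alpha=0.5
    )
    with pytest.raises(ValueError):
        krige_probability_field(field, k_neighbors=5)


class TestFuzzyEventEntropy:
    def test_uniform_full_membership(self):
        assert fuzzy_event_entropy(np.ones(4), np.full(4, 0.25)) == pytest.approx(2.0)

    def test_null_membership(self):
        assert fuzzy_event_entropy(np.zeros(8), np.full(8, 0.125)) == 0.0

    def test_hand_case(self):
        assert fuzzy_event_entropy([1.0, 0.0], [0.5, 0.5]) == pytest.approx(0.5)

    def test_zero_mass(self):
        assert fuzzy_event_entropy(np.ones(5), np.zeros(5)) == 0.0

    def test_unnormalized_input_is_rescaled(self):
        # normalization makes scaling the raw field irrelevant
        a = fuzzy_event_entropy(np.ones(4), np.array([1.0, 1.0, 2.0, 4.0]))
        b = fuzzy_event_entropy(np.ones(4), np.array([0.125, 0.125, 0.25, 0.5]))
        assert a == pytest.approx(b)

    def test_errors(self):
        with pytest.raises(ValueError):
            fuzzy_event_entropy([1.0], [0.5, 0.5])
        with pytest.raises(ValueError):
            fuzzy_event_entropy([1.0, 1.0], [0.5, -0.1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 10)), min_size=1, max_size=40
        )
    )
    def test_entropy_bounded_by_log_n(self, pairs):
        mu = np.array([p[0] for p in pairs])
        prob = np.array([p[1] for p in pairs])
        h = fuzzy_event_entropy(mu, prob)
        assert 0.0 <= h <= np.log2(len(pairs)) + 1e-9


def test_vector_length_is_clusters_times_alphas(rng):
    window = as_intensity_image(rng.random((12, 12)))
    vec = pefi_features(window, c=3, alphas=(0.5, 0.6, 0.7, 0.8, 0.9), seed=2)
    assert vec.entries.shape == (15,)
    assert np.all(vec.entries >= 0)


def test_features_deterministic(rng):
    window = as_intensity_image(rng.random((10, 10)))
    a = pefi_features(window, c=2, seed=4)
    b = pefi_features(window, c=2, seed=4)
    assert np.array_equal(a.entries, b.entries)


def test_crisp_checkerboard_constant_across_alpha():
    r, c = np.indices((12, 12))
    window = as_intensity_image(((r + c) % 2).astype(float))
    vec = pefi_features(window, c=2, alphas=(0.5, 0.6, 0.7, 0.8, 0.9), seed=0)
    per_cluster = vec.entries.reshape(2, 5)
    # crisp memberships make all alpha cuts identical within each cluster
    assert np.abs(per_cluster - per_cluster[:, :1]).max() <= 1e-9


def test_uk_degree_zero_matches_ok(rng):
    window = as_intensity_image(rng.random((10, 10)))
    ok = pefi_features(window, c=2, method="OK", seed=6)
    uk0 = pefi_features(window, c=2, method="UK", drift_degree=0, seed=6)
    np.testing.assert_allclose(uk0.entries, ok.entries, atol=1e-8)


def test_constant_window_raises_degenerate_error():
    from pefi import DegenerateImageError

    with pytest.raises(DegenerateImageError):
        pefi_features(as_intensity_image(np.full((8, 8), 0.5)), c=2)


class TestScanImage:
    params = dict(c=2, alphas=(0.5, 0.9), k_neighbors=5, seed=0)

    def test_tiling_count(self, rng):
        image = as_intensity_image(rng.random((16, 16)))
        windows = scan_image(image, (8, 8), stride=(8, 8), **self.params)
        assert len(windows) == 4

    def test_unit_stride_count(self, rng):
        image = as_intensity_image(rng.random((8, 7)))
        windows = scan_image(image, (7, 6), stride=(1, 1), **self.params)
        assert len(windows) == (8 - 7 + 1) * (7 - 6 + 1)

    def test_origins_match_enumeration(self, rng):
        image = as_intensity_image(rng.random((14, 11)))
        windows = scan_image(image, (6, 5), stride=(4, 3), **self.params)
        expected = [
            (r0, c0)
            for r0 in range(0, 14 - 6 + 1, 4)
            for c0 in range(0, 11 - 5 + 1, 3)
        ]
        assert [origin for origin, _ in windows] == expected

    def test_window_larger_than_image(self, rng):
        image = as_intensity_image(rng.random((6, 6)))
        with pytest.raises(ValueError):
            scan_image(image, (8, 8), **self.params)
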