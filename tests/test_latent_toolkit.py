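"""Style transform, factorization, walks, Fréchet distance, labeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist
from scipy.stats import ortho_group

from capsule_eval import (
    AffineStyleMap,
    AttributeDirection,
    FeatureStats,
    ValidationError,
    WalkSpec,
    fit_feature_stats,
    frechet_distance,
    label_pathology_attributes,
    latent_walk,
    make_planted_generator,
    sefa_directions,
    style_vector,
)
from capsule_eval.latent_toolkit import disk_radius


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestStyleVector:
    def test_identity_map_returns_the_code(self):
        m = AffineStyleMap(A=np.eye(3), b=np.zeros(3))
        w = np.array([1.0, -2.0, 0.5])
        assert np.allclose(style_vector(m, w), w)

    def test_hand_affine_arithmetic(self):
        m = AffineStyleMap(A=[[1, 0], [0, 2]], b=[1, 1])
        assert np.allclose(style_vector(m, [1, 1]), [2, 3])

    def test_linearity_up_to_bias(self):
        rng = np.random.default_rng(0)
        m = AffineStyleMap(A=rng.standard_normal((4, 3)),
                           b=rng.standard_normal(4))
        w1, w2 = rng.standard_normal(3), rng.standard_normal(3)
        lhs = style_vector(m, w1 + w2) - m.b
        rhs = (style_vector(m, w1) - m.b) + (style_vector(m, w2) - m.b)
        assert np.allclose(lhs, rhs)

    def test_dimension_mismatch_rejected(self):
        m = AffineStyleMap(A=np.eye(2), b=np.zeros(2))
        with pytest.raises(ValidationError):
            style_vector(m, np.zeros(3))


class TestSefa:
    def test_diagonal_map_recovers_axis_with_squared_singular_value(self):
        m = AffineStyleMap(A=np.diag([3.0, 1.0]), b=np.zeros(2))
        (top,) = sefa_directions(m, 1)
        assert np.allclose(np.abs(top.a), [1, 0])
        assert top.eigenvalue == pytest.approx(9.0)

    def test_planted_spectrum_recovery(self):
        rng = np.random.default_rng(7)
        U = ortho_group.rvs(6, random_state=rng)[:, :3]
        V = ortho_group.rvs(5, random_state=rng)[:, :3]
        A = U @ np.diag([5.0, 2.0, 1.0]) @ V.T
        dirs = sefa_directions(AffineStyleMap(A=A, b=np.zeros(6)), 3)
        for i, d in enumerate(dirs):
            assert abs(float(d.a @ V[:, i])) > 0.999
        assert [d.eigenvalue for d in dirs] == pytest.approx([25, 4, 1])

    def test_directions_are_orthonormal_and_sorted(self):
        rng = np.random.default_rng(11)
        m = AffineStyleMap(A=rng.standard_normal((8, 6)), b=np.zeros(8))
        dirs = sefa_directions(m, 4)
        G = np.array([d.a for d in dirs])
        assert np.allclose(G @ G.T, np.eye(4), atol=1e-8)
        eigs = [d.eigenvalue for d in dirs]
        assert eigs == sorted(eigs, reverse=True)
        assert [d.rank for d in dirs] == [1, 2, 3, 4]

    def test_invariance_under_orthogonal_left_multiplication(self):
        # Q A leaves A^T A unchanged, so directions agree up to sign.
        rng = np.random.default_rng(13)
        A = rng.standard_normal((5, 4))
        Q = ortho_group.rvs(5, random_state=rng)
        d1 = sefa_directions(AffineStyleMap(A=A, b=np.zeros(5)), 3)
        d2 = sefa_directions(AffineStyleMap(A=Q @ A, b=np.zeros(5)), 3)
        for a, b in zip(d1, d2):
            assert abs(float(a.a @ b.a)) == pytest.approx(1.0, abs=1e-9)

    def test_multi_layer_maps_stack_rows(self):
        rng = np.random.default_rng(17)
        A1, A2 = rng.standard_normal((3, 4)), rng.standard_normal((5, 4))
        stacked = AffineStyleMap(A=np.vstack([A1, A2]), b=np.zeros(8))
        separate = [AffineStyleMap(A=A1, b=np.zeros(3)),
                    AffineStyleMap(A=A2, b=np.zeros(5))]
        d1 = sefa_directions(stacked, 2)
        d2 = sefa_directions(separate, 2)
        for a, b in zip(d1, d2):
            assert np.allclose(a.a, b.a)
            assert a.eigenvalue == pytest.approx(b.eigenvalue)

    def test_noise_degrades_recovery_gracefully(self):
        rng = np.random.default_rng(19)
        U = ortho_group.rvs(6, random_state=rng)[:, :2]
        V = ortho_group.rvs(6, random_state=rng)[:, :2]
        A = U @ np.diag([5.0, 2.0]) @ V.T
        cosines = []
        for eps in (0.0, 0.05, 0.15):
            noise = rng.standard_normal(A.shape)
            noisy = AffineStyleMap(A=A + eps * noise, b=np.zeros(6))
            top = sefa_directions(noisy, 1)[0]
            cosines.append(abs(float(top.a @ V[:, 0])))
        assert cosines[0] >= cosines[1] >= cosines[2] - 1e-9
        assert cosines[2] > 0.9

    def test_j_bounds_validated(self):
        m = AffineStyleMap(A=np.eye(3), b=np.zeros(3))
        with pytest.raises(ValidationError):
            sefa_directions(m, 4)


class TestWalk:
    def _dir(self, d=3, axis=0):
        a = np.zeros(d)
        a[axis] = 1.0
        return AttributeDirection(a=a, eigenvalue=1.0, rank=1)

    def test_zero_length_interval_yields_single_base_code(self):
        spec = WalkSpec(w_base=np.ones(3), direction=self._dir(),
                        interval=(0.0, 0.0), alpha_step=2.0)
        codes = latent_walk(spec)
        assert len(codes) == 1
        assert np.allclose(codes[0], np.ones(3))

    def test_codes_move_against_the_direction(self):
        # w_i = w_base - alpha * a with the default step of 2
        spec = WalkSpec(w_base=np.zeros(3), direction=self._dir(),
                        interval=(0.0, 4.0), alpha_step=2.0)
        firsts = [c[0] for c in latent_walk(spec)]
        assert firsts == [0.0, -2.0, -4.0]

    def test_standard_interval_code_count(self):
        spec = WalkSpec(w_base=np.zeros(2), direction=self._dir(d=2),
                        interval=(0.0, 50.0), alpha_step=2.0)
        assert len(latent_walk(spec)) == 26

    @given(st.floats(0.5, 5.0), st.integers(1, 20))
    @settings(max_examples=50, derandomize=True)
    def test_code_spacing_equals_alpha_step(self, step, n):
        spec = WalkSpec(w_base=np.zeros(3), direction=self._dir(),
                        interval=(0.0, step * n), alpha_step=step)
        codes = latent_walk(spec)
        gaps = [float(np.linalg.norm(b - a))
                for a, b in zip(codes, codes[1:])]
        assert gaps == pytest.approx([step] * len(gaps), rel=1e-9)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            WalkSpec(w_base=np.zeros(3), direction=self._dir(),
                     interval=(5.0, 1.0))
        with pytest.raises(ValidationError):
            WalkSpec(w_base=np.zeros(3), direction=self._dir(),
                     alpha_step=0.0)


class TestFrechet:
    def test_identical_stats_distance_zero(self):
        s = FeatureStats(mean=[1.0, 2.0], covariance=[[2.0, 0.3], [0.3, 1.0]])
        assert frechet_distance(s, s) == pytest.approx(0.0, abs=1e-9)

    def test_one_dimensional_closed_form(self):
        a = FeatureStats(mean=[0.0], covariance=[[1.0]])
        b = FeatureStats(mean=[3.0], covariance=[[1.0]])
        assert frechet_distance(a, b) == pytest.approx(9.0)

    def test_commuting_diagonal_closed_form(self):
        p = FeatureStats(mean=[0, 0], covariance=np.diag([4.0, 1.0]))
        q = FeatureStats(mean=[0, 0], covariance=np.diag([1.0, 4.0]))
        # sum sigma_p + sum sigma_q - 2 sum sqrt(sigma_p sigma_q) = 5+5-8
        assert frechet_distance(p, q) == pytest.approx(2.0)

    def test_symmetric_and_zero_iff_equal_on_random_psd_pairs(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            dim = rng.integers(2, 6)
            X = rng.standard_normal((dim + 3, dim))
            Y = rng.standard_normal((dim + 3, dim))
            p = FeatureStats(mean=rng.standard_normal(dim), covariance=X.T @ X)
            q = FeatureStats(mean=rng.standard_normal(dim), covariance=Y.T @ Y)
            d_pq, d_qp = frechet_distance(p, q), frechet_distance(q, p)
            assert d_pq == pytest.approx(d_qp, rel=1e-6, abs=1e-8)
            assert d_pq > 0
            assert frechet_distance(p, p) == pytest.approx(0.0, abs=1e-8)

    def test_dimension_mismatch_and_non_psd_rejected(self):
        a = FeatureStats(mean=[0.0], covariance=[[1.0]])
        b = FeatureStats(mean=[0.0, 0.0], covariance=np.eye(2))
        with pytest.raises(ValidationError):
            frechet_distance(a, b)
        bad = FeatureStats(mean=[0.0, 0.0],
                           covariance=[[1.0, 0.0], [0.0, -1.0]])
        with pytest.raises(ValidationError):
            frechet_distance(bad, b)


class TestFeatureStats:
    def test_hand_moments(self):
        stats = fit_feature_stats(np.array([[0.0, 0.0], [2.0, 0.0]]))
        assert np.allclose(stats.mean, [1.0, 0.0])
        assert np.allclose(stats.covariance, [[2.0, 0.0], [0.0, 0.0]])

    def test_duplicated_dataset_identical_stats_and_zero_distance(self):
        rng = np.random.default_rng(29)
        X = rng.standard_normal((30, 3))
        a, b = fit_feature_stats(X), fit_feature_stats(X.copy())
        assert np.allclose(a.mean, b.mean)
        assert np.allclose(a.covariance, b.covariance)
        assert frechet_distance(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_single_vector_rejected(self):
        with pytest.raises(ValidationError):
            fit_feature_stats(np.zeros((1, 4)))


class TestPrototypeLabeling:
    def test_exact_hit_flagged_for_any_radius(self):
        flags = label_pathology_attributes(
            {"attr": np.array([[0.0, 0.0]])}, np.array([[0.0, 0.0]]), 1e-9
        )
        assert flags == {"attr": True}

    def test_threshold_boundary(self):
        pts = {"attr": np.array([[1.5, 0.0]])}
        protos = np.array([[0.0, 0.0]])
        assert not label_pathology_attributes(pts, protos, 1.0)["attr"]
        assert label_pathology_attributes(pts, protos, 2.0)["attr"]

    def test_agrees_with_quadratic_all_pairs_oracle(self):
        rng = np.random.default_rng(31)
        pts = {f"a{i}": rng.standard_normal((10, 2)) for i in range(10)}
        protos = rng.standard_normal((5, 2))
        radius = 0.8
        flags = label_pathology_attributes(pts, protos, radius)
        for name, arr in pts.items():
            expected = any(
                np.linalg.norm(x - p) <= radius for x in arr for p in protos
            )
            assert flags[name] == expected

    def test_no_prototypes_rejected(self):
        with pytest.raises(ValidationError):
            label_pathology_attributes({"a": np.zeros((1, 2))},
                                       np.zeros((0, 2)), 1.0)


class TestPlantedGenerator:
    def test_sefa_recovers_planted_directions(self):
        smap, _, V = make_planted_generator(10, 8, [5.0, 2.0, 1.0], seed=41)
        dirs = sefa_directions(smap, 3)
        for i, d in enumerate(dirs):
            assert abs(float(d.a @ V[:, i])) > 0.999

    def test_walk_along_planted_direction_moves_disk_radius_monotonically(self):
        smap, rasterize, V = make_planted_generator(6, 4, [5.0, 2.0], seed=43,
                                                    raster_size=96)
        direction = AttributeDirection(a=_unit(V[:, 0]), eigenvalue=25.0, rank=1)
        spec = WalkSpec(w_base=np.zeros(6), direction=direction,
                        interval=(0.0, 2.0), alpha_step=0.25)
        radii = [disk_radius(rasterize(style_vector(smap, w)))
                 for w in latent_walk(spec)]
        diffs = np.diff(radii)
        # strictly monotone in one direction (sign depends on the planted
        # factor's orientation in style space)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_same_seed_reproduces_map_and_rasters(self):
        a_map, a_rast, _ = make_planted_generator(6, 4, [3.0, 1.0], seed=5)
        b_map, b_rast, _ = make_planted_generator(6, 4, [3.0, 1.0], seed=5)
        assert np.array_equal(a_map.A, b_map.A)
        w = np.ones(6)
        assert np.array_equal(a_rast(style_vector(a_map, w)),
                              b_rast(style_vector(b_map, w)))

    def test_non_decreasing_spectrum_rejected(self):
        with pytest.raises(ValidationError):
            make_planted_generator(4, 4, [1.0, 2.0], seed=0)
        with pytest.raises(ValidationError):
            make_planted_generator(4, 4, [2.0, 2.0], seed=0)


def test_affine_map_validation():
    with pytest.raises(ValidationError):
        AffineStyleMap(A=np.eye(2), b=np.zeros(3))
    with pytest.raises(ValidationError):
        AffineStyleMap(A=np.full((2, 2), np.nan), b=np.zeros(2))


def test_attribute_direction_must_be_unit():
    with pytest.raises(ValidationError):
        AttributeDirection(a=np.array([1.0, 1.0]), eigenvalue=1.0, rank=1)
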