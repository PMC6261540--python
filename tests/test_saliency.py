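import numpy as np
import pytest
from hypothesis import given, strategies as st

from voroperim.io import TestPattern, VisualFieldRecord
from voroperim.models import ModelSpec, TrainedModel, build_cnn
from voroperim.saliency import (
    SaliencyConfig,
    SaliencyMap,
    gradient_map,
    normalize_map,
    piecewise_map,
    smoothgrad,
)
from voroperim.voronoi import region_assignment, to_voronoi_image

from helpers import LinearScorer, region_average_scan


@pytest.fixture
def random_image():
    return np.random.default_rng(0).normal(0, 3, size=(61, 61))


@pytest.fixture
def random_cnn():
    spec = ModelSpec(kind="CNN", seed=17)
    net = build_cnn(spec).astype(np.float64)
    return TrainedModel(spec=spec, net=net)


class TestGradientMap:
    def test_linear_scorer_recovers_weights_exactly(self, random_image):
        w = np.random.default_rng(1).normal(size=(61, 61))
        smap = gradient_map(LinearScorer(w), random_image)
        np.testing.assert_array_equal(smap.values, w)

    def test_matches_central_finite_differences(self, random_cnn, random_image):
        grad = gradient_map(random_cnn, random_image).values
        rng = np.random.default_rng(2)
        # probe pixels where the derivative is not vanishingly small
        candidates = np.argwhere(np.abs(grad) > np.abs(grad).max() * 1e-3)
        picks = candidates[rng.choice(len(candidates), size=5, replace=False)]
        h = 1e-3
        for i, j in picks:
            plus = random_image.copy()
            plus[i, j] += h
            minus = random_image.copy()
            minus[i, j] -= h
            fd = (random_cnn.predict(plus)[0] - random_cnn.predict(minus)[0]) / (2 * h)
            assert abs(fd - grad[i, j]) <= 1e-4 * max(abs(fd), abs(grad[i, j]))

    def test_map_has_image_dimensions(self, random_cnn, random_image):
        assert gradient_map(random_cnn, random_image).values.shape == (61, 61)


class TestSmoothGrad:
    def test_zero_noise_equals_plain_gradient(self, random_cnn, random_image):
        config = SaliencyConfig(n=10, sigma_r=0.0, seed=0)
        smooth = smoothgrad(random_cnn, random_image, config)
        np.testing.assert_array_equal(
            smooth.values, gradient_map(random_cnn, random_image).values
        )

    def test_single_sample_zero_noise_is_gradient(self, random_cnn, random_image):
        config = SaliencyConfig(n=1, sigma_r=0.0, seed=0)
        smooth = smoothgrad(random_cnn, random_image, config)
        np.testing.assert_array_equal(
            smooth.values, gradient_map(random_cnn, random_image).values
        )

    def test_linear_scorer_expectation_is_weight_map(self, random_image):
        w = np.random.default_rng(3).normal(size=(61, 61))
        smooth = smoothgrad(LinearScorer(w), random_image, SaliencyConfig(n=50, seed=4))
        np.testing.assert_allclose(smooth.values, w, atol=1e-12)

    def test_constant_image_degenerates_to_gradient(self, random_cnn):
        constant = np.full((61, 61), 2.0)
        smooth = smoothgrad(random_cnn, constant, SaliencyConfig(n=5, sigma_r=0.05, seed=0))
        np.testing.assert_array_equal(
            smooth.values, gradient_map(random_cnn, constant).values
        )

    def test_seeded_runs_are_bit_identical(self, random_cnn, random_image):
        config = SaliencyConfig(n=20, sigma_r=0.05, seed=12)
        a = smoothgrad(random_cnn, random_image, config)
        b = smoothgrad(random_cnn, random_image, config)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SaliencyConfig(n=0)
        with pytest.raises(ValueError):
            SaliencyConfig(sigma_r=-0.1)


class TestPiecewise:
    @pytest.fixture
    def three_region_map(self):
        pattern = TestPattern(
            "toy3",
            np.array([-15.0, 0.0, 15.0]),
            np.array([0.0, 0.0, 0.0]),
            np.zeros(3, bool),
        )
        return region_assignment(pattern)

    def test_constant_map_unchanged(self, three_region_map):
        smap = SaliencyMap(values=np.full((61, 61), 0.7), kind="smoothgrad")
        out = piecewise_map(smap, three_region_map)
        np.testing.assert_allclose(out.values, 0.7)

    def test_region_means_match_brute_force(self, three_region_map, random_image):
        smap = SaliencyMap(values=random_image, kind="smoothgrad")
        out = piecewise_map(smap, three_region_map)
        expected = region_average_scan(random_image, three_region_map.assignment)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_output_is_constant_within_regions(self, three_region_map, random_image):
        out = piecewise_map(SaliencyMap(values=random_image, kind="smoothgrad"),
                            three_region_map)
        for l in range(3):
            vals = out.values[three_region_map.region_pixels(l)]
            assert np.unique(vals).size == 1

    def test_idempotent(self, three_region_map, random_image):
        once = piecewise_map(SaliencyMap(values=random_image, kind="smoothgrad"),
                             three_region_map)
        twice = piecewise_map(once, three_region_map)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_dimension_mismatch_rejected(self, three_region_map):
        with pytest.raises(ValueError, match="dimensions"):
            piecewise_map(SaliencyMap(values=np.zeros((10, 10)), kind="smoothgrad"),
                          three_region_map)


class TestNormalize:
    def test_min_max_example(self):
        values = np.tile([-2.0, 0.0, 2.0], (61, 21))[:, :61]
        out = normalize_map(SaliencyMap(values=values, kind="gradient"))
        assert out.values.min() == 0.0 and out.values.max() == 1.0
        assert set(np.unique(out.values)) == {0.0, 0.5, 1.0}

    def test_constant_map_becomes_zeros(self):
        out = normalize_map(SaliencyMap(values=np.full((61, 61), 5.0), kind="gradient"))
        assert np.all(out.values == 0.0)
        assert out.normalized

    @given(
        st.floats(min_value=0.1, max_value=10, allow_nan=False),
        st.floats(min_value=-10, max_value=10, allow_nan=False),
    )
    def test_affine_invariance(self, a, b):
        values = np.random.default_rng(8).normal(size=(61, 61))
        base = normalize_map(SaliencyMap(values=values, kind="gradient"))
        scaled = normalize_map(SaliencyMap(values=a * values + b, kind="gradient"))
        np.testing.assert_allclose(scaled.values, base.values, atol=1e-9)


class TestFullPipeline:
    def test_linear_scorer_pipeline_recovers_region_averaged_weights(self):
        pattern = TestPattern(
            "toy4",
            np.array([-12.0, 12.0, 0.0, -3.0]),
            np.array([8.0, 8.0, -10.0, 0.0]),
            np.zeros(4, bool),
        )
        rm = region_assignment(pattern)
        rng = np.random.default_rng(6)
        w = rng.normal(size=(61, 61))
        record = VisualFieldRecord("s", "OD", "toy4", rng.normal(size=4))
        vi = to_voronoi_image(record, rm)
        smooth = smoothgrad(LinearScorer(w), vi, SaliencyConfig(n=25, seed=1))
        final = normalize_map(piecewise_map(smooth, rm))
        expected_raw = region_average_scan(w, rm.assignment)
        lo, hi = expected_raw.min(), expected_raw.max()
        np.testing.assert_allclose(final.values, (expected_raw - lo) / (hi - lo), atol=1e-9)
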