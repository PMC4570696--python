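"""Gabor bank: bandwidth algebra, kernel sampling, convolution, pooling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histoseverity.gaborbank import (
    BankConvolver,
    FilterBank,
    GaborParams,
    apply_bank,
    bandwidth_to_sigma_ratio,
    build_bank,
    convolve_reflect,
    make_kernel,
    orientation_max,
    pooled_response_stack,
    sigma_ratio_to_bandwidth,
)

# exact evaluations of the bandwidth->sigma/lambda closed form,
# recomputed independently with high-precision (sympy) arithmetic
EXACT_RATIOS = {
    1: 0.397515545279095,
    5: 0.141053903163550,
    10: 0.132764233923452,
    15: 0.132513269480989,
    20: 0.132505434493517,
}
RATIO_LIMIT = 0.132505181759698  # sqrt(ln 2) / (2 pi), the b -> inf pole


class TestBandwidthAlgebra:
    @pytest.mark.parametrize("b,expected", sorted(EXACT_RATIOS.items()))
    def test_closed_form(self, b, expected):
        assert bandwidth_to_sigma_ratio(b) == pytest.approx(expected, abs=1e-12)

    def test_limit_approached_from_above(self):
        assert bandwidth_to_sigma_ratio(30) > RATIO_LIMIT
        assert bandwidth_to_sigma_ratio(30) == pytest.approx(RATIO_LIMIT, abs=1e-7)

    @pytest.mark.parametrize("b", [5.0, 10.0, 15.0, 20.0])
    def test_round_trip_printed_grid(self, b):
        assert sigma_ratio_to_bandwidth(bandwidth_to_sigma_ratio(b)) == pytest.approx(
            b, abs=1e-9
        )

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=0.5, max_value=25.0))
    def test_round_trip_property(self, b):
        # near the pole (large b) the inversion is ill-conditioned: the
        # rounding of the ratio itself costs ~eps*x/((x-c) ln 2) in b
        ratio = bandwidth_to_sigma_ratio(b)
        x, c = ratio * math.pi, math.sqrt(math.log(2)) / 2
        cond = np.finfo(float).eps * x / ((x - c) * math.log(2))
        tol = 1e-9 + 10 * cond
        assert abs(sigma_ratio_to_bandwidth(ratio) - b) < tol

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bandwidth_to_sigma_ratio(0.0)
        with pytest.raises(ValueError):
            bandwidth_to_sigma_ratio(-3.0)
        with pytest.raises(ValueError):
            sigma_ratio_to_bandwidth(RATIO_LIMIT)  # at the pole
        with pytest.raises(ValueError):
            sigma_ratio_to_bandwidth(0.01)


class TestKernel:
    def test_center_value_is_one_for_zero_phase(self):
        k = make_kernel(GaborParams(wavelength=20, orientation=0, aspect_ratio=2, bandwidth=5))
        half = k.weights.shape[0] // 2
        assert k.weights[half, half] == pytest.approx(1.0)

    def test_even_symmetry_for_zero_phase(self):
        for theta in (0.0, 30.0, 75.0):
            k = make_kernel(
                GaborParams(wavelength=30, orientation=theta, aspect_ratio=0.5, bandwidth=10)
            )
            assert np.allclose(k.weights, k.weights[::-1, ::-1], atol=1e-12)

    def test_hand_evaluated_sample(self):
        # lam=20, b=5, gamma=0.5, theta=0 at offset (x, y) = (10, 0):
        # sigma = 0.1410539 * 20, value = exp(-100 / (2 sigma^2)) * cos(pi)
        k = make_kernel(GaborParams(wavelength=20, orientation=0, aspect_ratio=0.5, bandwidth=5))
        half = k.weights.shape[0] // 2
        assert k.weights[half, half + 10] == pytest.approx(-0.001868525629, abs=1e-9)

    def test_support_covers_wide_envelope_axis(self):
        p = GaborParams(wavelength=40, orientation=0, aspect_ratio=0.5, bandwidth=20)
        k = make_kernel(p)
        half = k.weights.shape[0] // 2
        assert half == math.ceil(3.0 * max(p.sigma, p.sigma / p.aspect_ratio))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            GaborParams(wavelength=-1, orientation=0, aspect_ratio=1, bandwidth=5)
        with pytest.raises(ValueError):
            GaborParams(wavelength=20, orientation=180, aspect_ratio=1, bandwidth=5)


class TestBank:
    def test_default_grid_builds_216_filters(self, bank):
        assert len(bank) == 216
        assert len(bank.pooled_index) == 36

    def test_bank_size_is_grid_product(self):
        assert len(build_bank(orientations=[0], aspect_ratios=[1], wavelengths=[20], bandwidths=[5])) == 1
        assert (
            len(build_bank(orientations=[0, 90], aspect_ratios=[1], wavelengths=[20], bandwidths=[5]))
            == 2
        )

    def test_canonical_order_theta_innermost(self, bank):
        thetas = [k.params.orientation for k in bank.kernels[:6]]
        assert thetas == [0.0, 30.0, 60.0, 90.0, 120.0, 150.0]
        assert bank.kernels[0].params.bandwidth == 5.0
        assert bank.kernels[-1].params.bandwidth == 20.0

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            build_bank(orientations=[])

    def test_json_round_trip(self, bank):
        again = FilterBank.from_json(bank.to_json())
        assert again.grid == bank.grid
        assert len(again) == len(bank)


SMALL = GaborParams(wavelength=20, orientation=0, aspect_ratio=4, bandwidth=20)


class TestConvolution:
    def test_constant_image_gives_kernel_sum_times_value(self):
        k = make_kernel(SMALL)
        img = np.full((64, 64), 0.7)
        r = convolve_reflect(img, k.weights)
        assert np.allclose(r, 0.7 * k.weights.sum(), atol=1e-10)

    def test_zero_mean_kernel_on_constant_image_is_zero(self):
        k = make_kernel(SMALL).weights
        k = k - k.mean()  # force zero sum
        r = convolve_reflect(np.full((64, 64), 0.3), k)
        assert np.abs(r).max() < 1e-10 * np.abs(k).sum()

    def test_impulse_reproduces_kernel(self):
        k = make_kernel(SMALL)
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        r = convolve_reflect(img, k.weights)
        half = k.weights.shape[0] // 2
        assert np.allclose(
            r[32 - half : 32 + half + 1, 32 - half : 32 + half + 1], k.weights, atol=1e-10
        )

    def test_fft_matches_direct_on_probes(self, rng):
        for params in (
            SMALL,
            GaborParams(wavelength=20, orientation=30, aspect_ratio=2, bandwidth=10),
            GaborParams(wavelength=30, orientation=120, aspect_ratio=4, bandwidth=5),
        ):
            k = make_kernel(params)
            img = rng.random((64, 64))
            assert np.allclose(
                convolve_reflect(img, k.weights, method="fft"),
                convolve_reflect(img, k.weights, method="direct"),
                atol=1e-8,
            )

    def test_linearity(self, rng):
        k = make_kernel(SMALL)
        img = rng.random((64, 64))
        assert np.allclose(
            convolve_reflect(3.5 * img, k.weights),
            3.5 * convolve_reflect(img, k.weights),
            atol=1e-9,
        )

    def test_narrowband_wavelength_selectivity(self):
        # brute-force sweep of grating wavelengths: a narrowband (1-octave)
        # filter responds maximally to its own wavelength
        k = make_kernel(GaborParams(wavelength=20, orientation=0, aspect_ratio=0.5, bandwidth=1))
        x = np.mgrid[0:256, 0:256][1]
        amps = {}
        for lam0 in range(10, 61, 5):
            img = 0.5 + 0.4 * np.cos(2 * np.pi * x / lam0)
            core = convolve_reflect(img, k.weights)[64:192, 64:192]
            amps[lam0] = (core - core.mean()).std()
        assert max(amps, key=amps.get) == 20


class TestPooling:
    def test_pooled_stack_has_36_maps(self, bank, rng):
        responses = rng.random((216, 8, 8))
        stack = orientation_max(responses, bank)
        assert stack.maps.shape == (36, 8, 8)
        assert len(stack.index) == 36

    def test_identical_orientations_pool_to_themselves(self, bank, rng):
        one = rng.random((8, 8))
        responses = np.tile(one, (216, 1, 1))
        stack = orientation_max(responses, bank)
        assert np.allclose(stack.maps, one)

    def test_dominant_orientation_wins(self, bank, rng):
        responses = rng.random((216, 4, 4))
        responses[2::6] += 10.0  # orientation index 2 dominates everywhere
        stack = orientation_max(responses, bank)
        assert np.allclose(stack.maps, responses[2::6])

    def test_incomplete_grid_rejected(self, bank, rng):
        with pytest.raises(ValueError):
            orientation_max(rng.random((215, 4, 4)), bank)

    def test_streaming_matches_two_step(self, rng):
        small = build_bank(orientations=[0, 60, 120], aspect_ratios=[2], wavelengths=[20], bandwidths=[20])
        img = rng.random((512, 512))
        two_step = orientation_max(apply_bank(img, small), small)
        stream = pooled_response_stack(img, small)
        assert np.allclose(stream.maps, two_step.maps, atol=1e-9)

    def test_cached_convolver_matches_convolve_reflect(self, rng):
        small = build_bank(orientations=[0, 90], aspect_ratios=[0.5], wavelengths=[30], bandwidths=[5])
        conv = BankConvolver(small, shape=(96, 96))
        img = rng.random((96, 96))
        got = conv.apply(img)
        for i, k in enumerate(small.kernels):
            assert np.allclose(got[i], convolve_reflect(img, k.weights), atol=1e-10)

    def test_shape_contract(self, bank, rng):
        with pytest.raises(ValueError):
            apply_bank(rng.random((100, 100)), bank)


def test_rotation_tolerance_of_pooled_means(bank):
    """Pooled map means barely move when an oriented texture rotates by 30 deg steps."""

    def stripes(alpha_deg, lam0=25.0):
        a = np.deg2rad(alpha_deg)
        yy, xx = np.mgrid[0:512, 0:512].astype(float)
        return 0.5 + 0.35 * np.cos(2 * np.pi * (xx * np.cos(a) + yy * np.sin(a)) / lam0)

    base = pooled_response_stack(stripes(0), bank).maps.mean(axis=(1, 2))
    for angle in (30.0, 60.0, 90.0):
        rotated = pooled_response_stack(stripes(angle), bank).maps.mean(axis=(1, 2))
        assert np.linalg.norm(rotated - base) / np.linalg.norm(base) < 0.05
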