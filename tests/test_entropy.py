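"""Coarse graining, sample entropy (against a brute-force oracle) and the
multiscale-entropy complexity index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitcog.entropy import (
    MSECurve,
    SampEnParams,
    coarse_grain,
    complexity_index,
    mse_curve,
    sample_entropy,
)
from gaitcog.errors import GaitcogError, InvalidParameterError, SignalTooShortError


def sampen_bruteforce(x, m, r):
    """Independent O(N^2) template-counting oracle (plain loops)."""
    x = list(map(float, x))
    N = len(x)
    P = N - m
    a = b = 0
    for i in range(P):
        for j in range(P):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def pink_noise(n, rng):
    """1/f noise via spectral shaping, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    spectrum = rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs))
    with np.errstate(divide="ignore"):
        spectrum = spectrum / np.sqrt(np.maximum(freqs, freqs[1]))
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    return x / x.std(ddof=1)


class TestCoarseGrain:
    def test_block_means(self):
        np.testing.assert_allclose(coarse_grain([1, 2, 3, 4, 5, 6], 2), [1.5, 3.5, 5.5])

    def test_scale_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=37)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_remainder_dropped(self):
        np.testing.assert_allclose(coarse_grain([1, 2, 3, 4, 5], 2), [1.5, 3.5])

    def test_tau_beyond_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            coarse_grain([1.0, 2.0], 3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=60),
        st.floats(-5, 5),
        st.integers(1, 4),
    )
    def test_linearity(self, xs, a, tau):
        x = np.array(xs)
        np.testing.assert_allclose(
            coarse_grain(a * x, tau), a * coarse_grain(x, tau), atol=1e-9
        )


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(50, 2.5), m=2, r_abs=0.1) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(20, 120))
            x = rng.normal(size=n)
            r = 0.2 * x.std(ddof=1)
            got = sample_entropy(x, m=2, r_abs=r)
            want = sampen_bruteforce(x, 2, r)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_matches_oracle_for_m1(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=80)
        r = 0.3 * x.std(ddof=1)
        assert sample_entropy(x, m=1, r_abs=r) == pytest.approx(
            sampen_bruteforce(x, 1, r), abs=1e-12
        )

    def test_monotone_ramp_with_tiny_tolerance_is_invalid(self):
        x = np.arange(50.0)
        assert np.isnan(sample_entropy(x, m=2, r_abs=0.5))

    def test_too_short_rejected(self):
        with pytest.raises(SignalTooShortError):
            sample_entropy(np.ones(3), m=2, r_abs=0.1)


class TestMSECurve:
    def test_white_noise_entropy_decreases_with_scale(self):
        rng = np.random.default_rng(0)
        curve = mse_curve(rng.normal(size=4000), SampEnParams())
        se = curve.se[curve.valid]
        first, last = se[:5].mean(), se[-5:].mean()
        assert first > last

    def test_tau_max_one_degenerates_to_single_sampen(self):
        x = np.random.default_rng(1).normal(size=300)
        curve = mse_curve(x, SampEnParams(tau_max=1))
        assert len(curve.se) == 1
        r = 0.2 * x.std(ddof=1)
        assert curve.se[0] == pytest.approx(sample_entropy(x, 2, r), abs=1e-12)

    def test_affine_invariance_of_complexity_index(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=1500)
        c1 = mse_curve(x, SampEnParams()).complexity_index
        c2 = mse_curve(5.0 * x - 11.0, SampEnParams()).complexity_index
        assert c2 == pytest.approx(c1, abs=1e-9)

    def test_coarse_lengths(self):
        x = np.random.default_rng(2).normal(size=1000)
        curve = mse_curve(x, SampEnParams(tau_max=10))
        np.testing.assert_array_equal(curve.lengths, [1000 // t for t in range(1, 11)])

    def test_short_scales_marked_invalid(self):
        x = np.random.default_rng(5).normal(size=100)
        with pytest.warns(UserWarning):
            curve = mse_curve(x, SampEnParams(tau_max=40))
        # scales with floor(100/tau) < 20 are always excluded; surviving
        # scales may still drop out when no m+1 template pair matches
        assert not curve.valid[5:].any()
        assert curve.valid[0]
        assert np.isnan(curve.se[5:]).all()

    def test_constant_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            mse_curve(np.ones(500), SampEnParams())

    def test_index_stable_beyond_750_points(self):
        # equal-length redraws from the same process move the index < 10%
        rng = np.random.default_rng(8)
        vals = [
            mse_curve(rng.normal(size=1200), SampEnParams()).complexity_index
            for _ in range(5)
        ]
        mean = np.mean(vals)
        assert np.max(np.abs(vals - mean)) / mean < 0.10

    def test_pink_noise_more_complex_than_white(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            white = rng.normal(size=2000)
            pink = pink_noise(2000, rng)
            cw = mse_curve(white, SampEnParams()).complexity_index
            cp = mse_curve(pink, SampEnParams()).complexity_index
            hits += cp > cw
        assert hits >= 4


class TestComplexityIndex:
    def test_constant_curve_area(self):
        c = 0.7
        curve = MSECurve(
            scales=np.arange(1, 41), lengths=np.full(40, 1000),
            se=np.full(40, c), valid=np.ones(40, bool), params=SampEnParams(),
        )
        assert complexity_index(curve) == pytest.approx(39 * c, abs=1e-12)

    def test_two_point_trapezoid(self):
        curve = MSECurve(
            scales=np.array([1, 2]), lengths=np.array([100, 50]),
            se=np.array([1.0, 3.0]), valid=np.ones(2, bool),
            params=SampEnParams(tau_max=2),
        )
        assert complexity_index(curve) == pytest.approx(2.0, abs=1e-12)

    def test_single_valid_scale_rejected(self):
        curve = MSECurve(
            scales=np.array([1, 2]), lengths=np.array([100, 50]),
            se=np.array([1.0, np.nan]), valid=np.array([True, False]),
            params=SampEnParams(tau_max=2),
        )
        with pytest.raises(GaitcogError):
            complexity_index(curve)
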