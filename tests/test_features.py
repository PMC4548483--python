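"""Feature extraction: framing, cepstra, deltas, functionals, modulation.

The MFCC and ACC paths are checked against independent brute-force
oracles (explicit triangular-filter summation + cosine-sum transform;
direct-summation autocorrelation), not against the vectorized code
under test.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vigivoice.features import (
    AccSpec,
    FilterbankSpec,
    FrameSpec,
    N_FEATURES,
    N_STREAMS,
    extract_features,
    feature_names,
    frame,
    frame_energy,
    hz_to_mel,
    log_delay_acc,
    mfcc,
    modulation_spectrum,
    preemphasize,
    summarize,
    temporal_deltas,
)

FS = 16_000


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_mfcc(windowed_frame, fs, n_coef=19):
    """Direct-summation mel cepstrum: explicit filter weights, explicit
    cosine sums. Independent of the vectorized implementation."""
    n = len(windowed_frame)
    n_fft = 1
    while n_fft < n:
        n_fft *= 2
    spec = np.abs(np.fft.rfft(windowed_frame, n_fft))
    spacing, width = 100.0, 200.0
    n_filt = int(np.floor(hz_to_mel(fs / 2.0) / spacing)) - 1
    energies = []
    for i in range(1, n_filt + 1):
        center = spacing * i
        e, wsum = 0.0, 0.0
        for k in range(len(spec)):
            f_mel = 2595.0 * np.log10(1.0 + (k * fs / n_fft) / 700.0)
            w = max(0.0, 1.0 - abs(f_mel - center) / (width / 2.0))
            e += w * spec[k]
            wsum += w
        energies.append(max(e / wsum if wsum > 0 else 0.0, 1e-10))
    log_e = np.log(energies)
    coefs = []
    for c in range(1, n_coef + 1):
        s = sum(log_e[m] * np.cos(np.pi * c * (2 * m + 1) / (2 * n_filt))
                for m in range(n_filt))
        coefs.append(s * np.sqrt(2.0 / n_filt))
    return np.array(coefs)


def oracle_acc(windowed_frame, fs, spec=None, n_coef=19):
    """Direct-summation autocorrelation interpolated onto the log-delay
    grid, explicit cosine sums."""
    if spec is None:
        spec = AccSpec()
    x = windowed_frame
    n = len(x)
    r = np.array([np.dot(x[:n - l], x[l:]) for l in range(n)])
    if r[0] <= 0:
        return np.zeros(n_coef)
    r = r / r[0]
    delays = np.geomspace(spec.min_delay_s, spec.max_delay_s, spec.n_delays)
    grid = np.interp(delays * fs, np.arange(n), r)
    coefs = []
    for c in range(1, n_coef + 1):
        s = sum(grid[m] * np.cos(np.pi * c * (2 * m + 1) / (2 * spec.n_delays))
                for m in range(spec.n_delays))
        coefs.append(s * np.sqrt(2.0 / spec.n_delays))
    return np.array(coefs)


# ---------------------------------------------------------------------------


class TestPreemphasis:
    def test_identity_at_zero(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(preemphasize(x, 0.0), x)

    def test_constant_killed_at_one(self):
        y = preemphasize(np.ones(50), 1.0)
        np.testing.assert_allclose(y[1:], 0.0)
        assert y[0] == 1.0

    def test_impulse_response(self):
        x = np.zeros(5)
        x[0] = 1.0
        np.testing.assert_allclose(preemphasize(x, 0.97),
                                   [1.0, -0.97, 0.0, 0.0, 0.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            preemphasize(np.array([]))


class TestFraming:
    def test_one_second_gives_96_frames(self):
        f = frame(np.zeros(FS), FS)
        assert f.shape == (96, 800)  # floor((16000-800)/160)+1

    def test_exactly_one_window(self):
        f = frame(np.ones(800), FS)
        assert f.shape == (1, 800)
        np.testing.assert_allclose(f[0], np.hamming(800))

    def test_too_short_reports_minimum(self):
        with pytest.raises(ValueError, match="800"):
            frame(np.zeros(700), FS)


class TestMfcc:
    def test_returns_19_per_frame(self, rng):
        f = frame(rng.standard_normal(FS), FS)
        assert mfcc(f, FS).shape == (f.shape[0], 19)

    def test_matches_bruteforce_oracle(self, rng):
        frames = frame(rng.standard_normal(FS // 2), FS)[:10]
        got = mfcc(frames, FS)
        for i in range(10):
            want = oracle_mfcc(frames[i], FS)
            np.testing.assert_allclose(got[i], want, rtol=1e-8, atol=1e-10)

    def test_white_noise_is_nearly_flat(self, rng):
        # averaged over many frames the log mel spectrum is ~constant, so
        # c1..c19 are small relative to the log-energy scale
        frames = frame(rng.standard_normal(4 * FS), FS)
        c = mfcc(frames, FS).mean(axis=0)
        assert np.max(np.abs(c)) < 1.0

    def test_silence_is_finite_and_constant(self):
        frames = np.zeros((5, 800))
        c = mfcc(frames, FS)
        assert np.all(np.isfinite(c))
        assert np.allclose(c, c[0])

    def test_amplitude_invariance(self, rng):
        frames = frame(rng.standard_normal(FS // 2), FS)
        np.testing.assert_allclose(mfcc(frames, FS), mfcc(3.7 * frames, FS),
                                   atol=1e-9)


class TestAcc:
    def test_returns_19_per_frame(self, rng):
        f = frame(rng.standard_normal(FS), FS)
        assert log_delay_acc(f, FS).shape == (f.shape[0], 19)

    def test_matches_bruteforce_oracle(self, rng):
        frames = frame(rng.standard_normal(FS // 2), FS)[:10]
        got = log_delay_acc(frames, FS)
        for i in range(10):
            want = oracle_acc(frames[i], FS)
            np.testing.assert_allclose(got[i], want, rtol=1e-8, atol=1e-10)

    def test_sinusoid_periodicity_on_grid(self):
        """A 200 Hz sinusoid has normalized autocorrelation ~1 at 5 ms."""
        t = np.arange(800) / FS
        x = np.sin(2 * np.pi * 200.0 * t)
        n = len(x)
        r = np.array([np.dot(x[:n - l], x[l:]) for l in range(n)]) \
            / np.dot(x, x)
        lag_5ms = int(0.005 * FS)
        # biased estimator tapers with lag: compare to the taper itself
        assert r[lag_5ms] == pytest.approx(1.0 - lag_5ms / n, rel=0.05)
        # and the full ACC vector matches the direct-summation oracle
        w = x * np.hamming(n)
        np.testing.assert_allclose(log_delay_acc(w[None, :], FS)[0],
                                   oracle_acc(w, FS), rtol=1e-8, atol=1e-10)

    def test_zero_energy_frame_yields_zero_vector(self):
        frames = np.vstack([np.zeros(800), np.ones(800)])
        c = log_delay_acc(frames, FS)
        np.testing.assert_array_equal(c[0], 0.0)
        assert np.any(c[1] != 0.0)


class TestDeltasAndEnergy:
    def test_constant_stream_zero_deltas(self):
        d, dd = temporal_deltas(np.full(10, 3.3))
        np.testing.assert_allclose(d, 0.0)
        np.testing.assert_allclose(dd, 0.0)

    def test_linear_ramp(self):
        d, dd = temporal_deltas(np.arange(10.0))
        np.testing.assert_allclose(d, 1.0)
        np.testing.assert_allclose(dd[2:], 0.0)

    def test_hand_computed_example(self):
        d, dd = temporal_deltas(np.array([0.0, 1.0, 4.0, 9.0]))
        np.testing.assert_allclose(d[1:], [1.0, 3.0, 5.0])
        np.testing.assert_allclose(dd[2:], [2.0, 2.0])

    def test_short_stream_rejected(self):
        with pytest.raises(ValueError):
            temporal_deltas(np.array([1.0, 2.0]))

    def test_energy_direct_summation_and_scaling(self, rng):
        frames = frame(rng.standard_normal(FS // 4), FS)
        e = frame_energy(frames)
        want = np.array([sum(v * v for v in fr) for fr in frames])
        np.testing.assert_allclose(e, want, rtol=1e-12)
        np.testing.assert_allclose(frame_energy(2.0 * frames), 4.0 * e)

    def test_full_window_sine_energy(self):
        t = np.arange(800) / FS
        x = np.sin(2 * np.pi * 400.0 * t)  # integer periods in the window
        w = np.hamming(800)
        e = frame_energy((x * w)[None, :])[0]
        assert e == pytest.approx(np.sum(w ** 2) / 2.0, rel=1e-2)


class TestSummarize:
    def test_degenerate_constant_stream(self):
        s = summarize(np.full(20, 7.0))
        np.testing.assert_allclose(s[:7], 7.0)
        assert s[7] == 0.0 and s[8] == 0.0

    def test_median_of_1_to_100(self):
        s = summarize(np.arange(1.0, 101.0))
        assert s[3] == pytest.approx(50.5)

    def test_symmetric_stream_zero_skew(self):
        x = np.concatenate([np.arange(-50, 0), np.arange(1, 51)]).astype(float)
        assert abs(summarize(x)[7]) < 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(arrays(np.float64, st.integers(4, 40),
                  elements=st.floats(-1e6, 1e6)))
    def test_permutation_invariance(self, x):
        perm = np.random.default_rng(0).permutation(x)
        np.testing.assert_allclose(summarize(x), summarize(perm),
                                   rtol=1e-9, atol=1e-9)


class TestModulationSpectrum:
    def _am_signal(self, mod_hz, seconds=20.0):
        t = np.arange(int(seconds * FS)) / FS
        carrier = np.sin(2 * np.pi * 1000.0 * t)
        return (1.0 + 0.8 * np.sin(2 * np.pi * mod_hz * t)) * carrier

    def test_returns_40_values_summing_to_one(self):
        m = modulation_spectrum(self._am_signal(4.0), FS)
        assert m.shape == (40,)
        assert m.sum() == pytest.approx(1.0)

    def test_am_tone_peaks_in_correct_band(self):
        m = modulation_spectrum(self._am_signal(4.0), FS)
        edges = np.geomspace(0.1, 50.0, 41)
        band_of_4hz = int(np.searchsorted(edges, 4.0) - 1)
        assert int(np.argmax(m)) == band_of_4hz

    def test_unmodulated_tone_energy_in_lowest_bands(self):
        t = np.arange(20 * FS) / FS
        m = modulation_spectrum(np.sin(2 * np.pi * 1000.0 * t), FS)
        assert int(np.argmax(m)) == 0

    def test_too_short_input_names_minimum(self):
        with pytest.raises(ValueError, match="10 s"):
            modulation_spectrum(np.zeros(FS), FS)


class TestFullVector:
    def test_structural_arithmetic(self):
        assert N_STREAMS == 117
        assert N_FEATURES == 1093
        names = feature_names()
        assert len(names) == 1093
        assert len(set(names)) == 1093
        assert names[0] == "mfcc01_q05" and names[-1] == "mod40"

    def test_extraction_deterministic(self, rng):
        x = rng.standard_normal(12 * FS)
        a = extract_features(x, FS).values
        b = extract_features(x, FS).values
        np.testing.assert_array_equal(a, b)
        assert a.shape == (1093,)

    def test_time_reversal_preserves_mfcc_quantiles(self, rng):
        """Frame statistics are distribution-based, so reversing time (a
        near-permutation of frames) leaves MFCC quantiles ~unchanged."""
        x = rng.standard_normal(12 * FS)
        a = extract_features(x, FS).values
        b = extract_features(x[::-1], FS).values
        # quantile slots of the plain MFCC streams (first 19 streams)
        idx = [s * 9 + q for s in range(19) for q in range(7)]
        scale = np.maximum(np.abs(a[idx]), 1.0)
        assert np.max(np.abs(a[idx] - b[idx]) / scale) < 0.05

    def test_works_at_44100(self, rng):
        x = rng.standard_normal(11 * 44100)
        fv = extract_features(x, 44100)
        assert fv.values.shape == (1093,)
        assert np.all(np.isfinite(fv.values))
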