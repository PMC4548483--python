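"""Acoustic feature extraction: the 1093-dimensional recording summary.

Each recording is reduced to a fixed-length vector built from three
frame-level streams and one envelope-level block:

* 19 mel-frequency cepstral coefficients (MFCCs) per 50 ms frame, plus
  first and second temporal differences;
* 19 autocorrelation coefficients (ACCs) — the cosine transform of the
  frame's normalized autocorrelation resampled onto a logarithmic delay
  axis — plus first and second differences;
* frame energy plus first and second differences;
* a 40-band modulation spectrum of the speech temporal envelope
  (band-pass 300–3500 Hz, rectified, low-pass 80 Hz), bands
  logarithmically spaced over 0.1–50 Hz.

The 117 frame-level streams (19 x 3 x 2 + 3) are each collapsed to nine
distributional statistics (the 5/10/25/50/75/90/95% quantiles, skewness,
and excess kurtosis), giving 117 x 9 + 40 = 1093 values in a fixed,
named order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import dct, rfft, irfft
from scipy.stats import kurtosis as _kurtosis, skew as _skew

__all__ = [
    "FrameSpec",
    "FilterbankSpec",
    "FeatureVector",
    "N_FEATURES",
    "N_STREAMS",
    "N_CEPSTRA",
    "N_MOD_BANDS",
    "STAT_NAMES",
    "feature_names",
    "preemphasize",
    "frame",
    "mfcc",
    "log_delay_acc",
    "temporal_deltas",
    "frame_energy",
    "summarize",
    "modulation_spectrum",
    "extract_features",
]

N_CEPSTRA = 19
N_MOD_BANDS = 40
N_STREAMS = N_CEPSTRA * 6 + 3  # 117
STAT_NAMES = ("q05", "q10", "q25", "q50", "q75", "q90", "q95", "skew", "kurt")
N_FEATURES = N_STREAMS * len(STAT_NAMES) + N_MOD_BANDS  # 1093

_QUANTILES = (5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0)
_LOG_FLOOR = 1e-10


@dataclass(frozen=True)
class FrameSpec:
    """Short-time analysis frame: 50 ms Hamming windows hopped by 10 ms."""

    window_s: float = 0.050
    hop_s: float = 0.010
    preemphasis: float = 0.97

    def __post_init__(self) -> None:
        if not 0 < self.hop_s <= self.window_s:
            raise ValueError(
                f"hop ({self.hop_s}) must be positive and <= window ({self.window_s})")

    def window_samples(self, fs: int) -> int:
        return int(round(self.window_s * fs))

    def hop_samples(self, fs: int) -> int:
        return int(round(self.hop_s * fs))


@dataclass(frozen=True)
class FilterbankSpec:
    """Triangular mel filterbank: 200 mel wide filters spaced by 100 mel.

    Adjacent filters overlap by half their width. The number of filters
    is derived from the Nyquist frequency so that 16 kHz and 44.1 kHz
    audio both get full-band coverage.
    """

    width_mel: float = 200.0
    spacing_mel: float = 100.0

    def n_filters(self, fs: int) -> int:
        return max(1, int(np.floor(hz_to_mel(fs / 2.0) / self.spacing_mel)) - 1)


@dataclass(frozen=True)
class AccSpec:
    """Logarithmic delay grid for the autocorrelation cepstrum.

    64 delays log-spaced over 0.5–25 ms cover periodicities from 40 Hz
    to 2 kHz.
    """

    n_delays: int = 64
    min_delay_s: float = 0.0005
    max_delay_s: float = 0.025


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 1093-value acoustic summary of one recording."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.shape != (N_FEATURES,):
            raise ValueError(
                f"feature vector must have {N_FEATURES} values, got {self.values.shape}")
        if len(self.names) != N_FEATURES:
            raise ValueError("names and values length mismatch")


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def feature_names() -> tuple[str, ...]:
    """Canonical slot names: stream_statistic, then modulation bands."""
    names: list[str] = []
    streams: list[str] = []
    for prefix in ("mfcc", "dmfcc", "ddmfcc"):
        streams += [f"{prefix}{c:02d}" for c in range(1, N_CEPSTRA + 1)]
    for prefix in ("acc", "dacc", "ddacc"):
        streams += [f"{prefix}{c:02d}" for c in range(1, N_CEPSTRA + 1)]
    streams += ["energy", "denergy", "ddenergy"]
    for s in streams:
        names += [f"{s}_{stat}" for stat in STAT_NAMES]
    names += [f"mod{b:02d}" for b in range(1, N_MOD_BANDS + 1)]
    return tuple(names)


_FEATURE_NAMES = None


def _cached_names() -> tuple[str, ...]:
    global _FEATURE_NAMES
    if _FEATURE_NAMES is None:
        _FEATURE_NAMES = feature_names()
    return _FEATURE_NAMES


# ---------------------------------------------------------------------------
# Frame-level operations


def preemphasize(x: np.ndarray, coeff: float = 0.97) -> np.ndarray:
    """First-order high-pass: y[n] = x[n] - coeff * x[n-1]."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot pre-emphasize an empty waveform")
    y = x.copy()
    y[1:] -= coeff * x[:-1]
    return y


def frame(x: np.ndarray, fs: int, spec: FrameSpec | None = None) -> np.ndarray:
    """Slice a waveform into Hamming-windowed frames, shape (n_frames, win).

    Frame count is floor((N - window) / hop) + 1; a trailing remainder
    shorter than one window is dropped.
    """
    if spec is None:
        spec = FrameSpec()
    x = np.asarray(x, dtype=np.float64)
    win = spec.window_samples(fs)
    hop = spec.hop_samples(fs)
    if x.size < win:
        raise ValueError(
            f"waveform has {x.size} samples but at least {win} "
            f"({spec.window_s * 1000:.0f} ms at {fs} Hz) are required")
    n_frames = (x.size - win) // hop + 1
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[::hop][:n_frames]
    return frames * np.hamming(win)


def _mel_filterbank(fs: int, n_fft: int, spec: FilterbankSpec) -> np.ndarray:
    """Triangular filterbank matrix, shape (n_filters, n_fft//2 + 1)."""
    n_filt = spec.n_filters(fs)
    centers_mel = spec.spacing_mel * np.arange(1, n_filt + 1)
    half = spec.width_mel / 2.0
    freqs = np.arange(n_fft // 2 + 1) * fs / n_fft
    freqs_mel = hz_to_mel(freqs)
    lower = centers_mel[:, None] - half
    upper = centers_mel[:, None] + half
    up = (freqs_mel[None, :] - lower) / half
    down = (upper - freqs_mel[None, :]) / half
    fb = np.maximum(0.0, np.minimum(up, down))
    # unit-area filters: a spectrally flat input yields a flat log mel
    # spectrum regardless of how many FFT bins each filter spans
    sums = fb.sum(axis=1, keepdims=True)
    return fb / np.where(sums > 0, sums, 1.0)


def mfcc(
    frames: np.ndarray,
    fs: int,
    fbspec: FilterbankSpec | None = None,
) -> np.ndarray:
    """Mel-frequency cepstral coefficients 1..19 per frame.

    Magnitude spectrum -> triangular mel filterbank -> log (floored to
    avoid -inf on silence) -> orthonormal type-II cosine transform,
    keeping coefficients 1..19 (the 0th, which tracks overall level, is
    carried separately by the energy stream).
    """
    if fbspec is None:
        fbspec = FilterbankSpec()
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    n_fft = 1 << int(np.ceil(np.log2(frames.shape[1])))
    spectrum = np.abs(rfft(frames, n=n_fft, axis=1))
    fb = _mel_filterbank(fs, n_fft, fbspec)
    energies = spectrum @ fb.T
    log_e = np.log(np.maximum(energies, _LOG_FLOOR))
    ceps = dct(log_e, type=2, norm="ortho", axis=1)
    return ceps[:, 1:N_CEPSTRA + 1]


def log_delay_acc(
    frames: np.ndarray,
    fs: int,
    spec: AccSpec | None = None,
) -> np.ndarray:
    """Autocorrelation coefficients 1..19 per frame.

    The biased normalized autocorrelation (r[0] = 1) of each frame is
    evaluated on a logarithmically spaced delay grid by linear
    interpolation, then cosine-transformed; coefficients 1..19 are kept.
    Zero-energy frames yield a zero vector.
    """
    if spec is None:
        spec = AccSpec()
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    win = frames.shape[1]
    n_fft = 1 << int(np.ceil(np.log2(2 * win)))
    ps = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    acorr = irfft(ps, n=n_fft, axis=1)[:, :win]
    r0 = acorr[:, 0].copy()
    dead = r0 <= 0.0
    r0[dead] = 1.0
    acorr = acorr / r0[:, None]

    delays = np.geomspace(spec.min_delay_s, spec.max_delay_s, spec.n_delays)
    lags = delays * fs
    idx = np.minimum(lags.astype(int), win - 2)
    frac = np.clip(lags - idx, 0.0, 1.0)
    grid = acorr[:, idx] * (1.0 - frac) + acorr[:, idx + 1] * frac
    grid[dead] = 0.0
    ceps = dct(grid, type=2, norm="ortho", axis=1)
    ceps[dead] = 0.0
    return ceps[:, 1:N_CEPSTRA + 1]


def temporal_deltas(stream: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second temporal differences of a frame-level stream.

    Simple first differences, edge-padded by repeating the first value
    so Δ and ΔΔ have the same length as the input.
    """
    stream = np.asarray(stream, dtype=np.float64)
    if stream.shape[0] < 3:
        raise ValueError(
            f"temporal differences need >= 3 frames, got {stream.shape[0]}")
    d = np.diff(stream, axis=0)
    d = np.concatenate([d[:1], d], axis=0)
    dd = np.diff(d, axis=0)
    dd = np.concatenate([dd[:1], dd], axis=0)
    return d, dd


def frame_energy(frames: np.ndarray) -> np.ndarray:
    """Sum of squared windowed samples per frame."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    return np.sum(frames ** 2, axis=1)


def summarize(stream: np.ndarray) -> np.ndarray:
    """Nine distributional statistics of a frame-level stream.

    The 5/10/25/50/75/90/95% quantiles (linear interpolation), skewness,
    and excess kurtosis (population moments), in that order. A
    zero-variance stream gets skewness and kurtosis 0.
    """
    stream = np.asarray(stream, dtype=np.float64)
    if stream.ndim != 1:
        raise ValueError("summarize expects a 1-D stream")
    if stream.size < 4:
        raise ValueError(f"need >= 4 frames to summarize, got {stream.size}")
    qs = np.percentile(stream, _QUANTILES)
    if np.ptp(stream) == 0.0:
        sk, ku = 0.0, 0.0
    else:
        sk = float(_skew(stream, bias=True))
        ku = float(_kurtosis(stream, fisher=True, bias=True))
    return np.concatenate([qs, [sk, ku]])


def _summarize_matrix(streams: np.ndarray) -> np.ndarray:
    """summarize() applied to each column of (n_frames, n_streams)."""
    qs = np.percentile(streams, _QUANTILES, axis=0)  # (7, k)
    mu = streams.mean(axis=0)
    cen = streams - mu
    var = np.mean(cen ** 2, axis=0)
    safe = np.where(var > 0, var, 1.0)
    sk = np.where(var > 0, np.mean(cen ** 3, axis=0) / safe ** 1.5, 0.0)
    ku = np.where(var > 0, np.mean(cen ** 4, axis=0) / safe ** 2 - 3.0, 0.0)
    return np.vstack([qs, sk, ku]).T  # (k, 9)


# ---------------------------------------------------------------------------
# Modulation spectrum


def modulation_spectrum(
    x: np.ndarray,
    fs: int,
    n_bands: int = N_MOD_BANDS,
    band_lo_hz: float = 0.1,
    band_hi_hz: float = 50.0,
    envelope_fs: int = 200,
) -> np.ndarray:
    """Energy of the speech temporal envelope in 40 log-spaced bands.

    The envelope is |band-pass(x, 300-3500 Hz)| low-passed at 80 Hz
    (4th-order zero-phase Butterworth filters) and decimated to 200 Hz.
    Its magnitude-squared spectrum (DC removed) is integrated over
    ``n_bands`` contiguous log-spaced bands covering
    [band_lo_hz, band_hi_hz] and normalized by the total in-range
    energy, so the values sum to 1 for any non-silent input.
    """
    x = np.asarray(x, dtype=np.float64)
    min_s = 1.0 / band_lo_hz
    if x.size < min_s * fs:
        raise ValueError(
            f"modulation spectrum needs >= {min_s:.0f} s of audio to resolve "
            f"{band_lo_hz} Hz; got {x.size / fs:.2f} s")
    nyq = fs / 2.0
    hi = min(3500.0, 0.95 * nyq)
    sos_bp = signal.butter(4, [300.0 / nyq, hi / nyq], btype="band", output="sos")
    env = np.abs(signal.sosfiltfilt(sos_bp, x))
    sos_lp = signal.butter(4, 80.0 / nyq, btype="low", output="sos")
    env = signal.sosfiltfilt(sos_lp, env)
    dec = max(1, fs // envelope_fs)
    # anti-aliased decimation: residual rectification ripple above the
    # new Nyquist would otherwise fold into the modulation bands
    env = signal.resample_poly(env, 1, dec)
    efs = fs / dec

    # Hann window on the mean-removed envelope keeps sidelobe leakage
    # from out-of-range lines out of the modulation bands
    env = (env - env.mean()) * np.hanning(env.size)
    spec = np.abs(rfft(env)) ** 2
    freqs = np.fft.rfftfreq(env.size, d=1.0 / efs)
    edges = np.geomspace(band_lo_hz, band_hi_hz, n_bands + 1)
    band_idx = np.searchsorted(edges, freqs, side="right") - 1
    in_range = (band_idx >= 0) & (band_idx < n_bands) & (freqs > 0)
    bands = np.bincount(band_idx[in_range], weights=spec[in_range],
                        minlength=n_bands)
    total = bands.sum()
    if total > 0:
        bands = bands / total
    return bands


# ---------------------------------------------------------------------------
# Full vector


def extract_features(
    x: np.ndarray,
    fs: int,
    frame_spec: FrameSpec | None = None,
    fbspec: FilterbankSpec | None = None,
    acc_spec: AccSpec | None = None,
) -> FeatureVector:
    """Extract the full ordered 1093-value feature vector of a recording.

    Layout: [MFCC(19), ΔMFCC, ΔΔMFCC, ACC(19), ΔACC, ΔΔACC, energy,
    Δenergy, ΔΔenergy] — 117 streams, each summarized by 9 statistics
    (1053 values) — followed by the 40 modulation bands.
    """
    if frame_spec is None:
        frame_spec = FrameSpec()
    x = np.asarray(x, dtype=np.float64)
    y = preemphasize(x, frame_spec.preemphasis)
    frames = frame(y, fs, frame_spec)
    if frames.shape[0] < 4:
        raise ValueError(
            f"recording too short: {frames.shape[0]} frames, need >= 4")

    m = mfcc(frames, fs, fbspec)
    dm, ddm = temporal_deltas(m)
    a = log_delay_acc(frames, fs, acc_spec)
    da, dda = temporal_deltas(a)
    e = frame_energy(frames)[:, None]
    de, dde = temporal_deltas(e)

    streams = np.hstack([m, dm, ddm, a, da, dda, e, de, dde])
    if streams.shape[1] != N_STREAMS:
        raise AssertionError(
            f"stream block has {streams.shape[1]} streams, expected {N_STREAMS}")
    stats = _summarize_matrix(streams).ravel()
    mod = modulation_spectrum(x, fs)
    values = np.concatenate([stats, mod])
    if not np.all(np.isfinite(values)):
        bad = np.flatnonzero(~np.isfinite(values))
        names = _cached_names()
        raise ValueError(
            f"non-finite features at {[names[i] for i in bad[:5]]}")
    return FeatureVector(values=values, names=_cached_names())
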