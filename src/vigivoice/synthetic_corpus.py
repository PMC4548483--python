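"""Synthetic wakefulness-study corpus: schedule, scores, and speech.

This module generates a complete study corpus — WAV files plus metadata
and psychophysiological test (PPT) score tables — with the schedule and
statistical structure the downstream analyses assume:

* subjects enter isolation at 10:00 on day 1 and stay awake ~60 h;
* speech is recorded roughly every 6 h (with jitter), some subjects add a
  baseline recording 24 h before isolation, one records again minutes
  after isolation ends;
* PPT batteries run every ~6 h, offset ~3 h from the recordings;
* the four PPT scores follow a linear mixed model driven by hours awake
  (sleep latency) and the circadian phase covariate, with subject random
  intercepts;
* speech acoustics drift monotonically with a latent fatigue level
  F = latency / 3600 min, clamped to [0, 1].

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import math
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .circadian import PhaseSpec, phase_value
from .types import (
    PPT_TESTS,
    LatentFatigueParams,
    PPTSession,
    Recording,
    StudyConfig,
    VoiceDriftParams,
)

__all__ = [
    "generate_schedule",
    "latent_fatigue",
    "generate_ppt_scores",
    "simulate_ppt_dataset",
    "synthesize_recording",
    "write_corpus",
    "read_corpus",
    "build_corpus",
    "FULL_SCALE_LATENCY_MIN",
]

#: Full-scale sleep latency: 60 h awake, in minutes. Latent fatigue F is
#: latency divided by this, clamped to [0, 1].
FULL_SCALE_LATENCY_MIN = 3600.0

_BASELINE_LEAD_H = 24.0


def generate_schedule(config: StudyConfig) -> tuple[list[Recording], list[PPTSession]]:
    """Lay out recording and PPT-session times for every subject.

    Recording times are ``isolation_start + k * recording_interval`` plus
    seeded uniform jitter; baselines sit 24 h before isolation start and
    post-isolation recordings a few minutes after its end. PPT sessions
    are offset from the recording grid by ``ppt_offset_hours`` and are
    not jittered. Deterministic for a fixed ``config.rng_seed``.

    Raises
    ------
    ValueError
        If any scheduled recording would fall outside
        [isolation_start - 24 h, isolation_end + 1 h].
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0xC0]))
    lo, hi = config.duration_bounds_s
    window_lo = config.isolation_start - timedelta(hours=_BASELINE_LEAD_H)
    window_hi = config.isolation_end + timedelta(hours=1.0)

    recordings: list[Recording] = []
    sessions: list[PPTSession] = []
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        times: list[tuple[datetime, bool]] = []
        if config.baselines_per_subject[s]:
            for _ in range(config.baselines_per_subject[s]):
                jit = rng.uniform(0.0, config.recording_jitter_min)
                t = (config.isolation_start - timedelta(hours=_BASELINE_LEAD_H)
                     + timedelta(minutes=jit))
                times.append((t, True))
        for k in range(config.slots_per_subject[s]):
            jit = rng.uniform(-config.recording_jitter_min, config.recording_jitter_min)
            t = (config.isolation_start
                 + timedelta(hours=k * config.recording_interval_hours, minutes=jit))
            times.append((t, False))
        for _ in range(config.post_per_subject[s]):
            t = config.isolation_end + timedelta(minutes=config.post_delay_min)
            times.append((t, False))
        for t, is_baseline in times:
            if not window_lo <= t <= window_hi:
                raise ValueError(
                    f"recording time {t:%Y-%m-%d %H:%M} for {sid} falls outside "
                    f"[{window_lo:%Y-%m-%d %H:%M}, {window_hi:%Y-%m-%d %H:%M}]")
            recordings.append(Recording(
                subject_id=sid,
                start_time=t,
                duration_s=float(rng.uniform(lo, hi)),
                is_baseline=is_baseline,
                sample_rate=config.sample_rate,
            ))
        for k in range(config.ppt_sessions_per_subject[s]):
            t = (config.isolation_start
                 + timedelta(hours=config.ppt_offset_hours
                             + k * config.ppt_interval_hours))
            sessions.append(PPTSession(subject_id=sid, session_time=t))
    return recordings, sessions


def latent_fatigue(
    time: datetime,
    wake_time: datetime,
    phase_spec: PhaseSpec | None = None,
) -> tuple[float, float, float]:
    """Latency, circadian phase, and normalized fatigue at a clock time.

    Returns
    -------
    (latency_min, phase, F):
        ``latency_min`` — minutes of continuous wakefulness since
        ``wake_time``, clamped at 0 (baseline recordings made before the
        study start count as fully rested);
        ``phase`` — the cosine time-of-day covariate in [-1, 1];
        ``F`` — latency divided by 3600 min (60 h full scale), clamped
        to [0, 1].
    """
    if time < wake_time - timedelta(hours=24):
        raise ValueError(f"time {time} precedes wake_time - 24 h")
    latency = max(0.0, (time - wake_time).total_seconds() / 60.0)
    phase = phase_value(time, phase_spec)
    fatigue = min(1.0, latency / FULL_SCALE_LATENCY_MIN)
    return latency, phase, fatigue


def generate_ppt_scores(
    sessions: Sequence[PPTSession],
    params: LatentFatigueParams,
    seed: int,
    wake_time: datetime | None = None,
    phase_spec: PhaseSpec | None = None,
) -> list[PPTSession]:
    """Fill in the four PPT scores of each session from the latent model.

    score = intercept + b_subject + latency_slope * hours_awake
            + phase_slope * phase + eps,
    with b_subject ~ N(0, subject_sd^2) drawn once per subject per test
    and eps ~ N(0, residual_sd^2) per session. Memory scores are rounded
    to the nearest non-negative integer because they are error counts.

    ``wake_time`` defaults to the earliest session time.
    """
    if not sessions:
        return []
    if wake_time is None:
        wake_time = min(s.session_time for s in sessions)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5C0]))
    subjects = sorted({s.subject_id for s in sessions})
    intercepts = {
        (sid, test): rng.normal(0.0, params.effect(test).subject_sd)
        for sid in subjects for test in PPT_TESTS
    }
    out: list[PPTSession] = []
    for sess in sessions:
        latency_min, phase, _ = latent_fatigue(sess.session_time, wake_time, phase_spec)
        hours = latency_min / 60.0
        scores: dict[str, float] = {}
        for test in PPT_TESTS:
            eff = params.effect(test)
            val = (eff.intercept + intercepts[(sess.subject_id, test)]
                   + eff.latency_slope * hours + eff.phase_slope * phase
                   + rng.normal(0.0, eff.residual_sd))
            scores[test] = val
        out.append(PPTSession(
            subject_id=sess.subject_id,
            session_time=sess.session_time,
            simple_rt=max(scores["simple_rt"], 1e-6),
            planned_rt=max(scores["planned_rt"], 1e-6),
            memory=int(max(0, round(scores["memory"]))),
            cognition=max(scores["cognition"], 1e-6),
        ))
    return out


def simulate_ppt_dataset(
    n_subjects: int,
    sessions_per_subject: int,
    params: LatentFatigueParams | None = None,
    seed: int = 0,
    session_interval_hours: float = 6.0,
    start: datetime = datetime(2020, 1, 1, 13, 0),
) -> pd.DataFrame:
    """Simulate a PPT score table with latency/phase covariates attached.

    Convenience wrapper used for parameter-recovery studies: every
    subject completes ``sessions_per_subject`` batteries at fixed
    intervals from ``start`` (subjects presumed awake from 3 h before the
    first battery, mirroring the usual recording/PPT offset). Returns a
    tidy DataFrame with columns subject_id, session_time, latency_h,
    phase, and one column per PPT test.
    """
    if params is None:
        params = LatentFatigueParams()
    wake = start - timedelta(hours=3.0)
    sessions = [
        PPTSession(subject_id=f"S{s + 1:03d}",
                   session_time=start + timedelta(hours=k * session_interval_hours))
        for s in range(n_subjects) for k in range(sessions_per_subject)
    ]
    scored = generate_ppt_scores(sessions, params, seed=seed, wake_time=wake)
    rows = []
    for sess in scored:
        latency_min, phase, _ = latent_fatigue(sess.session_time, wake)
        rows.append({
            "subject_id": sess.subject_id,
            "session_time": sess.session_time,
            "latency_h": latency_min / 60.0,
            "phase": phase,
            **{test: sess.score(test) for test in PPT_TESTS},
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Speech synthesis


def _resonator_coeffs(freq_hz: float, bw_hz: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Second-order all-pole resonator (digital formant) coefficients."""
    r = math.exp(-math.pi * bw_hz / fs)
    theta = 2.0 * math.pi * freq_hz / fs
    a = np.array([1.0, -2.0 * r * math.cos(theta), r * r])
    # unity gain at the resonance frequency
    b = np.array([(1.0 - r) * math.sqrt(1.0 - 2.0 * r * math.cos(2.0 * theta) + r * r)])
    return b, a


def synthesize_recording(
    rec: Recording,
    fatigue: float,
    drift: VoiceDriftParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render a recording as a source-filter speech-like waveform.

    The waveform alternates voiced segments — an impulse train at the
    (fatigue-drifted) fundamental filtered through four formant
    resonators, with per-segment formant jitter whose variance shrinks
    with fatigue — and silent pauses whose total proportion grows with
    fatigue. A one-pole lowpass whose strength grows with fatigue
    mimics increasing spectral tilt. Peak-normalized below full scale;
    deterministic per seed.
    """
    if drift is None:
        drift = VoiceDriftParams()
    if rec.duration_s <= 0:
        raise ValueError(f"duration must be positive, got {rec.duration_s}")
    if not 0.0 <= fatigue <= 1.0:
        raise ValueError(f"fatigue must lie in [0, 1], got {fatigue}")

    fs = rec.sample_rate
    n_total = int(round(rec.duration_s * fs))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA0D10]))

    pause_frac = drift.base_pause_fraction + drift.pause_gain * fatigue
    f0 = drift.base_f0_hz * (1.0 - drift.f0_gain * fatigue)
    jitter_sd = drift.base_formant_jitter * (1.0 - drift.formant_var_gain * fatigue)

    out = np.zeros(n_total)
    pos = 0
    while pos < n_total:
        seg_s = drift.voiced_segment_s * rng.uniform(0.7, 1.3)
        n_seg = min(int(seg_s * fs), n_total - pos)
        if n_seg <= 0:
            break
        # impulse train source at a slightly wavering fundamental
        seg_f0 = f0 * (1.0 + rng.normal(0.0, 0.02))
        period = max(2, int(round(fs / seg_f0)))
        src = np.zeros(n_seg)
        src[::period] = 1.0
        src += drift.noise_level * rng.standard_normal(n_seg)
        # per-segment formant jitter, variance shrinking with fatigue
        voiced = src
        for f_c, bw in zip(drift.formants_hz, drift.formant_bandwidths_hz):
            f_seg = f_c * (1.0 + rng.normal(0.0, jitter_sd))
            f_seg = float(np.clip(f_seg, 50.0, 0.45 * fs))
            b, a = _resonator_coeffs(f_seg, bw, fs)
            voiced = signal.lfilter(b, a, voiced)
        out[pos:pos + n_seg] = voiced
        pos += n_seg
        # silent pause keeping the long-run pause proportion at pause_frac
        mean_pause = seg_s * pause_frac / max(1e-9, 1.0 - pause_frac)
        pause_s = mean_pause * rng.uniform(0.5, 1.5)
        pos += int(pause_s * fs)

    tilt = drift.tilt_gain * fatigue
    if tilt > 0:
        out = signal.lfilter([1.0 - tilt], [1.0, -tilt], out)
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= 0.9 / peak
    return out


# ---------------------------------------------------------------------------
# Corpus I/O


def write_corpus(
    out_dir: str | Path,
    recordings: Sequence[Recording],
    sessions: Sequence[PPTSession],
    waveforms: Mapping[str, np.ndarray] | None = None,
) -> Path:
    """Write a corpus to disk: one 16-bit PCM WAV per recording plus
    ``recordings.csv`` and ``ppt_sessions.csv``.

    ``waveforms`` maps recording_id to a float waveform in [-1, 1]; a
    recording without a waveform gets a metadata row but no WAV file.
    Round-trips losslessly through :func:`read_corpus` (metadata exactly;
    audio to 16-bit quantization).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        wav_dir = out_dir / "wav"
        wav_dir.mkdir(exist_ok=True)
        rec_rows = []
        for rec in recordings:
            wav_path = rec.wav_path
            if waveforms is not None and rec.recording_id in waveforms:
                wav_path = str(Path("wav") / f"{rec.recording_id}.wav")
                x = np.asarray(waveforms[rec.recording_id], dtype=np.float64)
                pcm = np.clip(x, -1.0, 1.0)
                wavfile.write(out_dir / wav_path, rec.sample_rate,
                              (pcm * 32767.0).astype(np.int16))
            rec_rows.append({
                "subject_id": rec.subject_id,
                "start_time": rec.start_time.isoformat(),
                "duration_s": rec.duration_s,
                "is_baseline": rec.is_baseline,
                "wav_path": wav_path if wav_path else "",
                "sample_rate": rec.sample_rate,
            })
        sess_rows = [{
            "subject_id": s.subject_id,
            "session_time": s.session_time.isoformat(),
            "simple_rt_ms": s.simple_rt,
            "planned_rt_ms": s.planned_rt,
            "memory_errors": s.memory,
            "cognition_s": s.cognition,
        } for s in sessions]
        rec_cols = ["subject_id", "start_time", "duration_s", "is_baseline",
                    "wav_path", "sample_rate"]
        sess_cols = ["subject_id", "session_time", "simple_rt_ms",
                     "planned_rt_ms", "memory_errors", "cognition_s"]
        pd.DataFrame(rec_rows, columns=rec_cols).to_csv(
            out_dir / "recordings.csv", index=False)
        pd.DataFrame(sess_rows, columns=sess_cols).to_csv(
            out_dir / "ppt_sessions.csv", index=False)
    except OSError as exc:
        raise OSError(f"failed to write corpus under {out_dir}: {exc}") from exc
    return out_dir


def read_corpus(corpus_dir: str | Path) -> tuple[list[Recording], list[PPTSession]]:
    """Read a corpus written by :func:`write_corpus`."""
    corpus_dir = Path(corpus_dir)
    rec_df = pd.read_csv(corpus_dir / "recordings.csv",
                         dtype={"wav_path": "string"})
    sess_df = pd.read_csv(corpus_dir / "ppt_sessions.csv")
    recordings = [
        Recording(
            subject_id=str(r.subject_id),
            start_time=datetime.fromisoformat(r.start_time),
            duration_s=float(r.duration_s),
            is_baseline=bool(r.is_baseline),
            wav_path=(str(r.wav_path) if pd.notna(r.wav_path) and r.wav_path else None),
            sample_rate=int(r.sample_rate),
        )
        for r in rec_df.itertuples()
    ]
    sessions = [
        PPTSession(
            subject_id=str(r.subject_id),
            session_time=datetime.fromisoformat(r.session_time),
            simple_rt=(float(r.simple_rt_ms) if pd.notna(r.simple_rt_ms) else None),
            planned_rt=(float(r.planned_rt_ms) if pd.notna(r.planned_rt_ms) else None),
            memory=(int(r.memory_errors) if pd.notna(r.memory_errors) else None),
            cognition=(float(r.cognition_s) if pd.notna(r.cognition_s) else None),
        )
        for r in sess_df.itertuples()
    ]
    return recordings, sessions


def load_waveform(corpus_dir: str | Path, rec: Recording) -> np.ndarray:
    """Load a recording's audio as a float waveform in [-1, 1]."""
    if not rec.wav_path:
        raise FileNotFoundError(f"recording {rec.recording_id} has no WAV file")
    fs, data = wavfile.read(Path(corpus_dir) / rec.wav_path)
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    else:
        x = data.astype(np.float64)
    if x.ndim > 1:
        x = x.mean(axis=1)
    return x


def build_corpus(
    config: StudyConfig,
    out_dir: str | Path,
    fatigue_params: LatentFatigueParams | None = None,
    drift: VoiceDriftParams | None = None,
    phase_spec: PhaseSpec | None = None,
) -> tuple[list[Recording], list[PPTSession]]:
    """Generate and write a full synthetic corpus: schedule, scores, audio.

    Per-recording synthesis seeds are derived deterministically from
    ``config.rng_seed``, so two builds with the same config are
    bit-identical.
    """
    if fatigue_params is None:
        fatigue_params = LatentFatigueParams()
    if drift is None:
        drift = VoiceDriftParams()
    recordings, sessions = generate_schedule(config)
    sessions = generate_ppt_scores(sessions, fatigue_params,
                                   seed=config.rng_seed,
                                   wake_time=config.wake_time,
                                   phase_spec=phase_spec)
    waveforms: dict[str, np.ndarray] = {}
    for i, rec in enumerate(sorted(recordings, key=lambda r: r.recording_id)):
        _, _, fatigue = latent_fatigue(rec.start_time, config.wake_time, phase_spec)
        waveforms[rec.recording_id] = synthesize_recording(
            rec, fatigue, drift, seed=(config.rng_seed * 100003 + i) % (2**31))
    write_corpus(out_dir, recordings, sessions, waveforms)
    recs, sess = read_corpus(out_dir)
    return recs, sess
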