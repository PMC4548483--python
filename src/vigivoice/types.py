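"""Domain types for the wakefulness-study corpus.

A study corpus consists of speech recordings and psychophysiological test
(PPT) sessions collected from a small group of subjects kept awake for
roughly 60 hours. Recordings and PPT batteries both recur at ~6 h
intervals but are offset from each other by ~3 h, so downstream analysis
must align them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

__all__ = [
    "PPT_TESTS",
    "StudyConfig",
    "ScoreEffect",
    "LatentFatigueParams",
    "VoiceDriftParams",
    "Recording",
    "PPTSession",
    "DEFAULT_STUDY_CONFIG",
]

#: Canonical order of the four psychophysiological tests. Higher scores
#: always mean worse performance.
PPT_TESTS = ("simple_rt", "planned_rt", "memory", "cognition")


@dataclass(frozen=True)
class StudyConfig:
    """Schedule and composition of a synthetic wakefulness study.

    The defaults reproduce a 7-subject, ~60 h isolation protocol with 74
    recordings in total: every subject records roughly every 6 h during
    isolation, five subjects add a baseline recording 24 h before
    isolation begins, two subjects miss the final in-isolation recording,
    and one subject records once more a few minutes after isolation ends.
    """

    n_subjects: int = 7
    isolation_start: datetime = datetime(2020, 1, 1, 10, 0)
    isolation_hours: float = 60.0
    recording_interval_hours: float = 6.0
    ppt_interval_hours: float = 6.0
    ppt_offset_hours: float = 3.0
    #: number of in-isolation recording slots per subject
    slots_per_subject: tuple[int, ...] = (9, 9, 10, 10, 10, 10, 10)
    #: 1 if the subject makes a baseline recording the day before
    baselines_per_subject: tuple[int, ...] = (1, 1, 0, 0, 1, 1, 1)
    #: 1 if the subject records again minutes after isolation ends
    post_per_subject: tuple[int, ...] = (0, 0, 0, 0, 0, 0, 1)
    #: PPT sessions per subject (at ppt_offset + k * ppt_interval)
    ppt_sessions_per_subject: tuple[int, ...] = (10,) * 7
    #: uniform jitter half-width applied to recording times, minutes
    recording_jitter_min: float = 20.0
    #: post-isolation recordings happen this many minutes after the end
    post_delay_min: float = 10.0
    duration_bounds_s: tuple[float, float] = (105.0, 495.0)
    sample_rate: int = 16_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("isolation_hours", "recording_interval_hours",
                     "ppt_interval_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("slots_per_subject", "baselines_per_subject",
                     "post_per_subject", "ppt_sessions_per_subject"):
            counts = getattr(self, name)
            if len(counts) != self.n_subjects:
                raise ValueError(
                    f"{name} has {len(counts)} entries for {self.n_subjects} subjects")
            if any(c < 0 for c in counts):
                raise ValueError(f"{name} entries must be >= 0")
        lo, hi = self.duration_bounds_s
        if not 0 < lo <= hi:
            raise ValueError(f"invalid duration bounds {self.duration_bounds_s}")

    @property
    def isolation_end(self) -> datetime:
        return self.isolation_start + timedelta(hours=self.isolation_hours)

    @property
    def wake_time(self) -> datetime:
        """Subjects are presumed continuously awake from isolation start."""
        return self.isolation_start

    def total_recordings(self) -> int:
        return (sum(self.slots_per_subject) + sum(self.baselines_per_subject)
                + sum(self.post_per_subject))

    def with_(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ScoreEffect:
    """Generating coefficients of one PPT score.

    score = intercept + b_subject + latency_slope * hours_awake
            + phase_slope * phase + noise
    """

    intercept: float
    latency_slope: float  # test units per hour awake
    phase_slope: float    # test units per unit phase
    subject_sd: float     # SD of the subject random intercept
    residual_sd: float    # SD of the session-level noise

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class LatentFatigueParams:
    """Generating model for the four PPT scores.

    Slope defaults are the fixed-effect estimates from the reference
    mixed-effects analysis of the 7-subject isolation study (latency in
    hours awake, phase the cosine covariate); intercepts and variance
    components are plausible values for trained adult subjects, chosen so
    that within-subject session-to-session noise is modest relative to
    the systematic 60 h drift.
    """

    simple_rt: ScoreEffect = ScoreEffect(320.0, 0.653, -3.10, 30.0, 25.0)
    planned_rt: ScoreEffect = ScoreEffect(40.0, 0.403, 1.22, 8.0, 8.0)
    memory: ScoreEffect = ScoreEffect(4.0, 0.0286, 0.785, 1.5, 1.5)
    cognition: ScoreEffect = ScoreEffect(240.0, -0.0256, 25.8, 35.0, 15.0)

    def effect(self, test: str) -> ScoreEffect:
        if test not in PPT_TESTS:
            raise KeyError(f"unknown PPT test {test!r}; expected one of {PPT_TESTS}")
        return getattr(self, test)


@dataclass(frozen=True)
class VoiceDriftParams:
    """How synthetic speech acoustics drift with latent fatigue F in [0, 1].

    The synthesizer is a minimal source-filter model: an impulse train at
    the voicing fundamental filtered through four formant resonators,
    alternating with silent pauses. Fatigue lengthens pauses, lowers the
    fundamental, shrinks formant variability, and tilts the spectrum down
    - the directions reported for sleep-deprived read speech.
    """

    base_f0_hz: float = 120.0
    formants_hz: tuple[float, ...] = (500.0, 1500.0, 2500.0, 3500.0)
    formant_bandwidths_hz: tuple[float, ...] = (80.0, 120.0, 160.0, 200.0)
    #: per-segment relative jitter SD of formant frequencies at F = 0
    base_formant_jitter: float = 0.12
    base_pause_fraction: float = 0.15
    voiced_segment_s: float = 0.35
    #: additional pause fraction at F = 1
    pause_gain: float = 0.30
    #: relative fundamental-frequency decline at F = 1
    f0_gain: float = 0.20
    #: relative shrinkage of formant jitter SD at F = 1
    formant_var_gain: float = 0.7
    #: spectral tilt: one-pole lowpass coefficient added at F = 1
    tilt_gain: float = 0.5
    noise_level: float = 0.02

    def __post_init__(self) -> None:
        if not 0 <= self.base_pause_fraction < 1:
            raise ValueError("base_pause_fraction must be in [0, 1)")
        if self.base_pause_fraction + max(self.pause_gain, 0.0) >= 1:
            raise ValueError("pause fraction would leave [0, 1) at F = 1")
        if len(self.formants_hz) != len(self.formant_bandwidths_hz):
            raise ValueError("formants and bandwidths must have equal length")

    @classmethod
    def null(cls) -> "VoiceDriftParams":
        """Drift gains all zero: acoustics independent of fatigue."""
        return cls(pause_gain=0.0, f0_gain=0.0, formant_var_gain=0.0,
                   tilt_gain=0.0)


@dataclass
class Recording:
    """One speech recording: who, when, how long, and (optionally) audio."""

    subject_id: str
    start_time: datetime
    duration_s: float
    is_baseline: bool = False
    wav_path: str | None = None
    sample_rate: int = 16_000

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")

    @property
    def recording_id(self) -> str:
        return f"{self.subject_id}_{self.start_time:%Y%m%dT%H%M%S}"


@dataclass
class PPTSession:
    """One psychophysiological test battery: four scores at a timestamp."""

    subject_id: str
    session_time: datetime
    simple_rt: float | None = None   # mean reaction time, ms
    planned_rt: float | None = None  # mean timing error, ms
    memory: int | None = None        # summed errors of the two memory tests
    cognition: float | None = None   # completion time, s

    def __post_init__(self) -> None:
        if self.memory is not None and self.memory < 0:
            raise ValueError("memory errors must be a non-negative count")
        for name in ("simple_rt", "planned_rt", "cognition"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def session_id(self) -> str:
        return f"{self.subject_id}_ppt_{self.session_time:%Y%m%dT%H%M%S}"

    def score(self, test: str) -> float:
        if test not in PPT_TESTS:
            raise KeyError(f"unknown PPT test {test!r}")
        v = getattr(self, test)
        if v is None:
            raise ValueError(f"session {self.session_id} has no {test} score")
        return float(v)


DEFAULT_STUDY_CONFIG = StudyConfig()
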