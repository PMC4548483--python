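"""Pairing recordings with their nearest psychophysiological test session.

Recordings and PPT batteries run on interleaved ~6 h schedules, so each
retained recording is uniquely assigned the nearest-in-time session of
the same subject. Baseline recordings (made the day before isolation)
have no corresponding session and are excluded; a recording left without
a free session — e.g. one made minutes after isolation ended — is
excluded too. Exclusions are reported, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circadian import PhaseSpec
from .synthetic_corpus import latent_fatigue
from .types import PPTSession, Recording

__all__ = ["AlignedSample", "Exclusion", "align"]


@dataclass
class AlignedSample:
    """One recording uniquely paired with one same-subject PPT session."""

    recording: Recording
    session: PPTSession
    gap_min: float      # |recording start - session time|
    latency_min: float  # minutes awake at recording start
    phase: float        # circadian covariate at recording start


@dataclass
class Exclusion:
    recording: Recording
    reason: str


def align(
    recordings: list[Recording],
    sessions: list[PPTSession],
    wake_time=None,
    phase_spec: PhaseSpec | None = None,
    method: str = "nearest",
) -> tuple[list[AlignedSample], list[Exclusion]]:
    """Uniquely assign the nearest PPT session to each recording.

    Matching is per subject. The default ``nearest`` method walks the
    recordings in chronological order and gives each the nearest
    still-unassigned session — on an interleaved every-6-h schedule this
    keeps every gap near the 3 h offset. ``greedy_gap`` instead takes
    unmatched (recording, session) pairs in ascending gap order (ties
    broken by the earlier recording); on jittered schedules this can
    cascade, stranding one recording far from its session. ``optimal``
    minimizes the total gap over all one-to-one matchings (Hungarian
    algorithm). All methods leave surplus recordings unmatched.

    ``wake_time`` (default: earliest non-baseline recording start per
    subject's study, i.e. the minimum over all recordings) anchors the
    latency covariate.
    """
    if method not in ("nearest", "greedy_gap", "optimal"):
        raise ValueError(f"unknown matching method {method!r}")
    if wake_time is None:
        candidates = [r.start_time for r in recordings if not r.is_baseline]
        wake_time = min(candidates) if candidates else None

    aligned: list[AlignedSample] = []
    excluded: list[Exclusion] = []
    subjects = sorted({r.subject_id for r in recordings})
    for sid in subjects:
        recs = [r for r in recordings if r.subject_id == sid]
        sess = [s for s in sessions if s.subject_id == sid]
        usable = []
        for r in recs:
            if r.is_baseline:
                excluded.append(Exclusion(r, "baseline recording: no equivalent PPT session"))
            else:
                usable.append(r)
        if not usable:
            continue
        usable.sort(key=lambda r: r.start_time)
        pairs = _match(usable, sess, method)
        matched_recs = {i for i, _ in pairs}
        for i, r in enumerate(usable):
            if i not in matched_recs:
                excluded.append(Exclusion(r, "no unassigned PPT session available"))
        for i, j in pairs:
            r, s = usable[i], sess[j]
            gap = abs((r.start_time - s.session_time).total_seconds()) / 60.0
            latency, phase, _ = latent_fatigue(r.start_time, wake_time, phase_spec)
            aligned.append(AlignedSample(r, s, gap, latency, phase))
    aligned.sort(key=lambda a: (a.recording.subject_id, a.recording.start_time))
    return aligned, excluded


def _match(recs: list[Recording], sess: list[PPTSession], method: str) -> list[tuple[int, int]]:
    if not recs or not sess:
        return []
    gaps = np.array([[abs((r.start_time - s.session_time).total_seconds())
                      for s in sess] for r in recs])
    if method == "optimal":
        from scipy.optimize import linear_sum_assignment
        if len(recs) <= len(sess):
            ri, sj = linear_sum_assignment(gaps)
        else:
            sj, ri = linear_sum_assignment(gaps.T)
        return list(zip(ri.tolist(), sj.tolist()))
    if method == "nearest":
        # chronological: each recording takes its nearest free session
        pairs = []
        free = set(range(len(sess)))
        for i in range(len(recs)):
            if not free:
                break
            j = min(free, key=lambda j: (gaps[i, j], j))
            free.remove(j)
            pairs.append((i, j))
        return pairs
    # greedy_gap: ascending gap, ties -> earlier recording (lower index)
    order = sorted(
        ((gaps[i, j], i, j) for i in range(len(recs)) for j in range(len(sess))),
        key=lambda t: (t[0], t[1], t[2]))
    used_r: set[int] = set()
    used_s: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in order:
        if i in used_r or j in used_s:
            continue
        used_r.add(i)
        used_s.add(j)
        pairs.append((i, j))
    return pairs
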