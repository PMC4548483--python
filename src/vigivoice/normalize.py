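"""Within-subject normalization of features and test scores.

Speech features are *gaussianized* per speaker: each feature's values
for a speaker are replaced by standard-normal quantiles of their ranks,
which removes speaker-identity cues (every speaker ends up with the same
marginal distribution) while preserving the within-speaker ordering that
carries the fatigue signal.

PPT scores are z-standardized per subject so models learn within-subject
performance change rather than which subject is which; the stored means
and SDs allow exact inversion back to original units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "gaussianize",
    "gaussianize_features",
    "SpeakerNormalizer",
    "ScoreStandardizer",
]


def gaussianize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform of one per-subject sample.

    A value with (average, for ties) rank r among n maps to
    ``Phi^-1((r - 0.5) / n)``. An all-equal sample maps to zeros. The
    transform is invariant under any strictly monotone re-expression of
    the inputs and preserves ranks by construction.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1:
        raise ValueError("gaussianize expects a 1-D sample")
    n = values.size
    if n < 2 or np.ptp(values) == 0.0:
        return np.zeros(n)
    ranks = rankdata(values, method="average")
    return norm.ppf((ranks - 0.5) / n)


def gaussianize_features(
    features: pd.DataFrame,
    subject_ids: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Gaussianize every feature column within each subject.

    ``features`` is a (recordings x features) frame; ``subject_ids``
    aligns with its rows. Returns a frame of identical shape and index.
    """
    subject_ids = np.asarray(subject_ids)
    if len(subject_ids) != len(features):
        raise ValueError("subject_ids must align with feature rows")
    out = features.copy()
    for sid in np.unique(subject_ids):
        mask = subject_ids == sid
        block = features.loc[mask].to_numpy(dtype=np.float64)
        n = block.shape[0]
        if n < 2:
            out.loc[mask] = 0.0
            continue
        ranks = np.apply_along_axis(rankdata, 0, block)
        g = norm.ppf((ranks - 0.5) / n)
        g[:, np.ptp(block, axis=0) == 0.0] = 0.0
        out.loc[mask] = g
    return out


@dataclass
class SpeakerNormalizer:
    """Enrollment-style gaussianizer: stores per (subject, feature)
    sorted reference values and maps new values by interpolated rank.

    The mapping is monotone non-decreasing; applied to its own reference
    sample it reproduces :func:`gaussianize` of that sample.
    """

    reference: dict[str, dict[str, list[float]]] = field(default_factory=dict)

    @classmethod
    def fit(cls, features: pd.DataFrame,
            subject_ids: pd.Series | np.ndarray) -> "SpeakerNormalizer":
        subject_ids = np.asarray(subject_ids)
        ref: dict[str, dict[str, list[float]]] = {}
        for sid in np.unique(subject_ids):
            block = features.loc[subject_ids == sid]
            ref[str(sid)] = {c: sorted(block[c].tolist()) for c in features.columns}
        return cls(reference=ref)

    def transform_value(self, subject_id: str, feature: str, value: float) -> float:
        try:
            sample = np.asarray(self.reference[str(subject_id)][feature])
        except KeyError as exc:
            raise KeyError(
                f"no enrollment data for subject {subject_id!r} / {feature!r}") from exc
        n = sample.size
        if n < 2 or sample[0] == sample[-1]:
            return 0.0
        # mid-rank of `value` within the reference sample
        r = np.searchsorted(sample, value, side="left") + \
            np.searchsorted(sample, value, side="right")
        rank = (r + 1) / 2.0
        p = np.clip((rank - 0.5) / n, 0.5 / n, 1 - 0.5 / n)
        return float(norm.ppf(p))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.reference))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpeakerNormalizer":
        return cls(reference=json.loads(Path(path).read_text()))


@dataclass
class ScoreStandardizer:
    """Per (subject, test) z-standardization with exact inversion.

    Uses the sample SD (divide by n - 1), the convention under which
    [400, 500, 600] maps to [-1, 0, 1]. Statistics are computed from
    the full per-subject sample; a fold-safe variant (fit on training
    rows only) is available via ``fit(..., rows=...)`` but is off by
    default because the headline analysis standardizes before
    cross-validation.
    """

    stats: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def fit(cls, scores: pd.DataFrame, subject_col: str = "subject_id",
            tests: tuple[str, ...] | None = None,
            rows: np.ndarray | None = None) -> "ScoreStandardizer":
        if tests is None:
            tests = tuple(c for c in scores.columns if c != subject_col)
        df = scores if rows is None else scores.iloc[rows]
        stats: dict[tuple[str, str], tuple[float, float]] = {}
        for sid, block in df.groupby(subject_col):
            for test in tests:
                x = block[test].to_numpy(dtype=np.float64)
                mu = float(x.mean())
                sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
                if sd == 0.0:
                    raise ValueError(
                        f"zero SD for subject {sid!r}, test {test!r}: "
                        "cannot z-standardize a constant score")
                stats[(str(sid), test)] = (mu, sd)
        return cls(stats=stats)

    def _lookup(self, subject_id: str, test: str) -> tuple[float, float]:
        try:
            return self.stats[(str(subject_id), test)]
        except KeyError as exc:
            raise KeyError(
                f"no statistics for subject {subject_id!r}, test {test!r}") from exc

    def transform(self, x: np.ndarray, subject_ids: np.ndarray, test: str) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        out = np.empty_like(x)
        for i, (v, sid) in enumerate(zip(x, subject_ids)):
            mu, sd = self._lookup(sid, test)
            out[i] = (v - mu) / sd
        return out

    def invert(self, z: np.ndarray, subject_ids: np.ndarray, test: str) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        out = np.empty_like(z)
        for i, (v, sid) in enumerate(zip(z, subject_ids)):
            mu, sd = self._lookup(sid, test)
            out[i] = v * sd + mu
        return out

    def mean(self, subject_id: str, test: str) -> float:
        return self._lookup(subject_id, test)[0]
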