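"""Shared fixtures: compact synthetic corpora built once per session.

Corpora use the default 74-recording study composition but short
recordings (12-16 s — long enough for the 0.1 Hz modulation band) so the
full pipeline stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from vigivoice.report import assemble_dataset
from vigivoice.synthetic_corpus import build_corpus
from vigivoice.types import StudyConfig, VoiceDriftParams

SHORT = dict(duration_bounds_s=(12.0, 16.0), rng_seed=5)


@pytest.fixture(scope="session")
def drift_corpus(tmp_path_factory):
    """Default-drift corpus: acoustics carry the fatigue signal."""
    d = tmp_path_factory.mktemp("drift_corpus")
    recordings, sessions = build_corpus(StudyConfig(**SHORT), d)
    return d, recordings, sessions


@pytest.fixture(scope="session")
def null_corpus(tmp_path_factory):
    """Zero-drift corpus: acoustics independent of fatigue."""
    d = tmp_path_factory.mktemp("null_corpus")
    recordings, sessions = build_corpus(StudyConfig(**SHORT), d,
                                        drift=VoiceDriftParams.null())
    return d, recordings, sessions


@pytest.fixture(scope="session")
def drift_data(drift_corpus):
    d, _, _ = drift_corpus
    return assemble_dataset(d)


@pytest.fixture(scope="session")
def null_data(null_corpus):
    d, _, _ = null_corpus
    return assemble_dataset(d)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
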