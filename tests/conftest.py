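"""Shared fixtures: synthetic clips, a contaminated corpus, a pipeline run.

Everything is generated at test time from seeds; session scope keeps the
expensive corpora to one build per run.
"""

from __future__ import annotations

import tempfile
from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from phenoacoustics.audio import AudioClip
from phenoacoustics.pipeline import PipelineConfig, run_all
from phenoacoustics.synth import (
    RecordingSchedule,
    default_activity,
    default_library,
    iter_corpus,
    truth_table,
)

SR = 22050.0


@pytest.fixture(scope="session")
def library():
    return default_library(20)


@pytest.fixture(scope="session")
def activity():
    return default_activity(20)


def tone(freq: float, duration: float = 1.0, sr: float = SR, amp: float = 0.5):
    t = np.arange(int(duration * sr)) / sr
    return AudioClip(amp * np.sin(2 * np.pi * freq * t), sr)


@pytest.fixture
def tone_clip():
    return tone(5000.0)


@pytest.fixture(scope="session")
def mixed_corpus(library, activity):
    """~200 short clips with rain and fault contamination at known rates.

    Returns (truth table, clip index table) where clips are kept in memory.
    """
    from phenoacoustics.pipeline import PipelineConfig, index_row

    schedule = RecordingSchedule(
        sites=("T1",),
        start_date=datetime(2018, 1, 1).date(),
        end_date=datetime(2018, 12, 31).date(),
        cadence_minutes=720,
        day_stride=4,
        missing_fraction=0.0,
    )
    cfg = PipelineConfig(sample_rate=SR, clip_duration=5.0)
    rows, truths = [], []
    for clip, truth in iter_corpus(
        schedule, library, activity,
        rain_rate=0.10, fault_rate=0.05, seed=77,
        duration=5.0, sample_rate=SR,
    ):
        truths.append(truth)
        rows.append(index_row(clip, cfg))
    return truth_table(truths), pd.DataFrame(rows)


@pytest.fixture(scope="session")
def e2e_config():
    """Reduced-size study configuration for the end-to-end run."""
    return PipelineConfig(
        output_dir=tempfile.mkdtemp(prefix="pheno_e2e_"),
        seed=11,
        sites=["T1", "T2"],
        start_date="2018-01-01",
        end_date="2019-12-31",
        cadence_minutes=180,
        day_stride=15,
        write_audio=False,
        clip_duration=15.0,
        sample_rate=SR,
        missing_fraction=0.05,
        rain_rate=0.08,
        fault_rate=0.02,
        cv_repeats=100,
        n_iter=1000,
    )


@pytest.fixture(scope="session")
def e2e_report(e2e_config):
    """Full pipeline run on the reduced synthetic corpus (shared)."""
    return run_all(e2e_config)
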