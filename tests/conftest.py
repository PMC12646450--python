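import numpy as np
import pytest

from canisleep.io import EEG_CHANNELS, Hypnogram
from canisleep.synthetic import gen_cohort_to_disk, trazodone_like_config


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def simple_hypnogram():
    """120 epochs: wake, drowsiness, NREM blocks then a short REM bout."""
    states = np.concatenate([
        np.zeros(40, int), np.ones(30, int), np.full(40, 2), np.full(10, 3)])
    artifact = np.zeros(120, bool)
    artifact[:8] = True
    return Hypnogram(states, artifact)


@pytest.fixture(scope="session")
def disk_cohort(tmp_path_factory):
    """Small trazodone-like cohort written to disk (EDF + TSV + manifest);
    shared across tests that exercise file-based entry points."""
    outdir = tmp_path_factory.mktemp("cohort")
    cfg = trazodone_like_config(n_subjects=3, duration_min=6, seed=11)
    manifest = gen_cohort_to_disk(cfg, outdir)
    return outdir, manifest


@pytest.fixture
def channels():
    return EEG_CHANNELS
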