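"""Data model and I/O for canine polysomnography sessions.

Recordings are exchanged as 16-bit EDF (four EEG channels F3, F4, Fz, Cz
referenced to Oz, 400 Hz); sleep scorings as TSV hypnograms in 3-second
epochs over the four behavioural states wakefulness (0), drowsiness (1),
NREM (2) and REM (3); a study manifest (TSV) pairs each subject's control
and trazodone sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

EEG_CHANNELS: tuple[str, ...] = ("F3", "F4", "Fz", "Cz")
CONDITIONS: tuple[str, ...] = ("control", "trazodone")

#: canonical state coding: wakefulness 0, drowsiness 1, NREM 2, REM 3
STATE_CODES: dict[str, int] = {"wake": 0, "drowsiness": 1, "nrem": 2, "rem": 3}
STATE_NAMES: dict[int, str] = {v: k for k, v in STATE_CODES.items()}
N_STATES = 4

# scorer-facing label aliases accepted on load (case-insensitive)
_STATE_ALIASES: dict[str, int] = {
    "w": 0, "wake": 0, "wakefulness": 0,
    "d": 1, "drow": 1, "drowsiness": 1,
    "n": 2, "nrem": 2,
    "r": 3, "rem": 3,
}


@dataclass
class Hypnogram:
    """A scored state sequence in fixed-length epochs with artifact flags."""

    states: np.ndarray                    # int codes in {0,1,2,3}
    artifact: np.ndarray                  # bool, True = noisy epoch
    epoch_length_s: float = 3.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        if self.states.size and not np.isin(self.states, list(STATE_NAMES)).all():
            raise ValueError("state codes must be in {0,1,2,3}")
        if self.artifact.shape != self.states.shape:
            raise ValueError("artifact flags must match states in length")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def duration_min(self) -> float:
        return len(self) * self.epoch_length_s / 60.0


@dataclass
class SessionRecording:
    """One subject-condition multichannel EEG recording (microvolts)."""

    subject_id: str
    condition: str
    channels: tuple[str, ...]
    sampling_rate_hz: float
    signal: np.ndarray                    # (n_channels, n_samples), µV

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        self.channels = tuple(self.channels)
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.signal.shape[0] != len(self.channels):
            raise ValueError("signal rows must match channel count")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    @property
    def n_samples(self) -> int:
        return int(self.signal.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class EpochSet:
    """Fixed-length artifact-free epochs selected for one behavioural state."""

    state: int
    data: np.ndarray                      # (n_epochs, n_channels, n_points)
    source_indices: np.ndarray            # epoch indices into the hypnogram
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (n_epochs, n_channels, n_points)")
        self.source_indices = np.asarray(self.source_indices, dtype=np.int64)
        if self.source_indices.size != self.data.shape[0]:
            raise ValueError("one source index per epoch required")

    @property
    def n_epochs(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_points_per_epoch(self) -> int:
        return int(self.data.shape[2])


@dataclass
class SegmentedEpochs:
    """All scored epochs of a recording, with state and artifact flag each."""

    data: np.ndarray                      # (n_epochs, n_channels, n_points)
    states: np.ndarray
    artifact: np.ndarray
    epoch_indices: np.ndarray

    def by_state(self) -> dict[int, "SegmentedEpochs"]:
        """Split into per-state subsets (states actually present only)."""
        out = {}
        for s in np.unique(self.states):
            m = self.states == s
            out[int(s)] = SegmentedEpochs(
                self.data[m], self.states[m], self.artifact[m], self.epoch_indices[m]
            )
        return out


@dataclass
class StudyManifest:
    """Session table pairing each subject's control and trazodone recordings."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("subject_id", "condition", "recording_path", "hypnogram_path",
               "weight_kg", "age_months")

    def __post_init__(self) -> None:
        for col in self.COLUMNS[:4]:
            if col not in self.table.columns:
                raise ValueError(f"manifest missing column {col!r}")
        dup = self.table.duplicated(subset=["subject_id", "condition"])
        if dup.any():
            raise ValueError("each subject may appear at most once per condition")

    def sessions(self):
        return self.table.itertuples(index=False)

    def subjects(self) -> list[str]:
        return sorted(self.table["subject_id"].unique())


# ---------------------------------------------------------------------------
# EDF writing (16-bit, standard header, 1-second data records)
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, signal: np.ndarray, sfreq: float,
              channels: Sequence[str], physical_max: float | None = None) -> None:
    """Write a multichannel signal (µV) as 16-bit EDF with 1-s data records.

    The recording is zero-padded to a whole number of 1-second records; the
    physical range is symmetric and chosen from the data unless given.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    n_ch, n_samp = signal.shape
    if n_ch != len(channels):
        raise ValueError("channel count mismatch")
    spr = int(round(sfreq))
    if abs(spr - sfreq) > 1e-9:
        raise ValueError("write_edf supports integer sampling rates only")
    n_rec = int(np.ceil(n_samp / spr)) if n_samp else 0
    if physical_max is None:
        peak = float(np.max(np.abs(signal))) if n_samp else 1.0
        physical_max = max(peak * 1.05, 1.0)
    # use exactly the value written in the header, so reader and writer
    # agree on the scaling to the last digit
    physical_max = float(f"{physical_max:.6g}"[:8])
    dig_max, dig_min = 32767, -32768
    gain = 2.0 * physical_max / (dig_max - dig_min)
    offset = physical_max - gain * dig_max

    header = b"".join([
        _pad("0", 8), _pad("X X X X", 80), _pad("Startdate X X X X", 80),
        _pad("01.01.01", 8), _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_ch)), 8), _pad("", 44),
        _pad(str(n_rec), 8), _pad("1", 8), _pad(str(n_ch), 4),
    ])
    fields = [
        [ _pad(f"EEG {ch}", 16) for ch in channels ],
        [ _pad("AgAgCl electrode", 80) ] * n_ch,
        [ _pad("uV", 8) ] * n_ch,
        [ _pad(f"{-physical_max:.6g}"[:8], 8) ] * n_ch,
        [ _pad(f"{physical_max:.6g}"[:8], 8) ] * n_ch,
        [ _pad(str(dig_min), 8) ] * n_ch,
        [ _pad(str(dig_max), 8) ] * n_ch,
        [ _pad("", 80) ] * n_ch,
        [ _pad(str(spr), 8) ] * n_ch,
        [ _pad("", 32) ] * n_ch,
    ]
    sig_header = b"".join(b"".join(col) for col in fields)

    padded = np.zeros((n_ch, n_rec * spr), dtype=np.float64)
    padded[:, :n_samp] = signal
    digital = np.clip(np.round((padded - offset) / gain),
                      dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# Loading operations
# ---------------------------------------------------------------------------

def load_recording(path: str | Path,
                   expected_channels: Sequence[str] = EEG_CHANNELS,
                   subject_id: str = "", condition: str = "control",
                   ) -> SessionRecording:
    """Load an EDF recording, reordering channels to the expected montage.

    Raises a ``ValueError`` naming any expected channel absent from the file.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:                      # noqa: BLE001
        raise OSError(f"could not read EDF file {path}: {exc}") from exc
    labels = [lb.removeprefix("EEG ").strip() for lb in raw.ch_names]
    sfreq = float(raw.info["sfreq"])
    signal = raw.get_data() * 1e6                 # volts -> microvolts
    missing = [ch for ch in expected_channels if ch not in labels]
    if missing:
        raise ValueError(
            f"{path}: missing channel(s) {', '.join(missing)}; found {labels}")
    order = [labels.index(ch) for ch in expected_channels]
    return SessionRecording(
        subject_id=subject_id, condition=condition,
        channels=tuple(expected_channels),
        sampling_rate_hz=sfreq, signal=signal[order],
    )


def load_hypnogram(path: str | Path, epoch_length_s: float = 3.0) -> Hypnogram:
    """Load a TSV hypnogram (columns epoch_index, state, artifact_flag)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"epoch_index", "state", "artifact_flag"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: hypnogram TSV needs columns {sorted(required)}")
    if df.empty:
        return Hypnogram(np.empty(0, dtype=int), np.empty(0, dtype=bool),
                         epoch_length_s)
    idx = df["epoch_index"].astype(int).to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        raise ValueError(f"{path}: epoch_index must be 0..n-1 without gaps")
    codes = np.empty(len(df), dtype=np.int64)
    for i, label in enumerate(df["state"]):
        key = str(label).strip().lower()
        if key not in _STATE_ALIASES:
            raise ValueError(f"{path}: unknown state label {label!r} at row {i}")
        codes[i] = _STATE_ALIASES[key]
    flags = df["artifact_flag"].str.strip().str.lower().isin(
        ("1", "true", "yes")).to_numpy()
    return Hypnogram(codes, flags, epoch_length_s)


def write_hypnogram(path: str | Path, hyp: Hypnogram) -> None:
    df = pd.DataFrame({
        "epoch_index": np.arange(len(hyp)),
        "state": [STATE_NAMES[s] for s in hyp.states],
        "artifact_flag": hyp.artifact.astype(int),
    })
    df.to_csv(path, sep="\t", index=False)


def load_manifest(path: str | Path) -> StudyManifest:
    df = pd.read_csv(path, sep="\t", comment="#")
    return StudyManifest(df)


def write_manifest(path: str | Path, manifest: StudyManifest) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Epoch segmentation
# ---------------------------------------------------------------------------

def segment_epochs(rec: SessionRecording, hyp: Hypnogram) -> SegmentedEpochs:
    """Cut the recording into scored epochs of ``hyp.epoch_length_s``.

    Epoch i covers samples [i*fs*L, (i+1)*fs*L) per channel (half-open,
    non-overlapping). A scored epoch only partially covered by samples at
    the recording tail is dropped, never padded; if the scoring exceeds the
    recording by more than one epoch, or no complete epoch remains, an
    error is raised.
    """
    n_points = int(round(rec.sampling_rate_hz * hyp.epoch_length_s))
    n_full = rec.n_samples // n_points
    if len(hyp) > n_full + 1:
        raise ValueError(
            f"hypnogram ({len(hyp)} epochs) exceeds recording "
            f"({n_full} complete epochs) by more than one epoch")
    kept = min(n_full, len(hyp))
    if kept == 0:
        raise ValueError("recording shorter than a single scored epoch")
    data = rec.signal[:, :kept * n_points].reshape(
        len(rec.channels), kept, n_points).transpose(1, 0, 2)
    return SegmentedEpochs(
        data=np.ascontiguousarray(data),
        states=hyp.states[:kept].copy(),
        artifact=hyp.artifact[:kept].copy(),
        epoch_indices=np.arange(kept),
    )
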