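"""Filtering and clean-epoch sampling.

The continuous record is band-pass filtered to [1, 70] Hz with a 60 Hz
power-line notch before epoching. All filters are zero-phase (applied
forward and backward), which matters downstream where instantaneous phase
is extracted for connectivity. Narrowband presets for the phase-based
connectivity are 2-Hz-wide bands: delta [2,4], theta [5,7], alpha [9,11],
beta [19,21] and gamma [34,36] Hz.
"""

from __future__ import annotations

import hashlib
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EpochSet, Hypnogram, SegmentedEpochs, STATE_NAMES

logger = logging.getLogger(__name__)

from dataclasses import dataclass

#: default broadband filter edges (Hz)
BANDPASS = (1.0, 70.0)
NOTCH_HZ = 60.0
#: narrow bands used for phase-based connectivity (Hz)
PLI_BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta": (5.0, 7.0),
    "alpha": (9.0, 11.0),
    "beta": (19.0, 21.0),
    "gamma": (34.0, 36.0),
}
EPOCHS_PER_STATE = 5


@dataclass
class FilterSpec:
    """A declarative filter description, applied zero-phase.

    ``kind`` selects among the broadband band-pass, the power-line notch
    and the narrow connectivity bands; edges must stay below Nyquist.
    """

    kind: str = "bandpass"                # bandpass | notch | narrowband
    low_hz: float = BANDPASS[0]
    high_hz: float = BANDPASS[1]
    notch_hz: float = NOTCH_HZ
    zero_phase: bool = True               # forward-backward; always on

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "notch", "narrowband"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind != "notch" and not self.low_hz < self.high_hz:
            raise ValueError("low edge must be below high edge")
        if not self.zero_phase:
            raise ValueError("only zero-phase application is supported")

    def apply(self, x: np.ndarray, fs: float) -> np.ndarray:
        if self.kind == "notch":
            return notch(x, fs, self.notch_hz)
        return bandpass(x, fs, self.low_hz, self.high_hz)


def _check_edges(fs: float, *edges: float) -> None:
    nyq = fs / 2.0
    for e in edges:
        if not 0 < e < nyq:
            raise ValueError(f"filter edge {e} Hz outside (0, Nyquist={nyq}) Hz")


def bandpass(x: np.ndarray, fs: float, low: float = BANDPASS[0],
             high: float = BANDPASS[1], order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    A 4th-order design applied forward-backward (8th-order effective
    magnitude, zero net phase).
    """
    _check_edges(fs, low, high)
    if low >= high:
        raise ValueError("low edge must be below high edge")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


def notch(x: np.ndarray, fs: float, freq: float = NOTCH_HZ,
          quality: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch (quality factor 30) along the last axis."""
    _check_edges(fs, freq)
    b, a = sps.iirnotch(freq, quality, fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=np.float64), axis=-1)


def narrowband(x: np.ndarray, fs: float, band: tuple[float, float],
               order: int = 4) -> np.ndarray:
    """Zero-phase narrowband filter (same engine as :func:`bandpass`)."""
    return bandpass(x, fs, band[0], band[1], order=order)


def derive_seed(master_seed: int, *keys) -> int:
    """Deterministic per-stream seed from a master seed and string keys."""
    digest = hashlib.sha256(
        ("|".join([str(master_seed), *map(str, keys)])).encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def sample_clean_epochs(by_state: Mapping[int, SegmentedEpochs],
                        n: int = EPOCHS_PER_STATE,
                        seed: int = 0) -> dict[int, EpochSet]:
    """Sample ``n`` artifact-free epochs per state, uniformly without
    replacement, with a seeded generator.

    States with fewer than ``n`` clean epochs contribute all they have (the
    shortfall is logged); states with no clean epoch are absent from the
    result, so downstream group comparisons degrade to unpaired.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    out: dict[int, EpochSet] = {}
    for state in sorted(by_state):
        seg = by_state[state]
        clean = np.flatnonzero(~seg.artifact)
        if clean.size == 0:
            logger.warning("state %s: no artifact-free epochs; state absent",
                           STATE_NAMES.get(state, state))
            continue
        rng = np.random.default_rng(derive_seed(seed, "epoch-sample", state))
        take = min(n, clean.size)
        if take < n:
            logger.warning("state %s: only %d clean epochs available (< %d)",
                           STATE_NAMES.get(state, state), clean.size, n)
        chosen = np.sort(rng.choice(clean, size=take, replace=False))
        out[state] = EpochSet(
            state=state,
            data=seg.data[chosen],
            source_indices=seg.epoch_indices[chosen],
            seed=seed,
        )
    return out


def epoch_quality_summary(hyp: Hypnogram) -> pd.DataFrame:
    """Per-state counts of clean/noisy epochs and the percent clean.

    States never scored in the hypnogram are absent from the table.
    """
    rows = []
    for state in np.unique(hyp.states):
        m = hyp.states == state
        noisy = int(hyp.artifact[m].sum())
        total = int(m.sum())
        rows.append({
            "state": STATE_NAMES[int(state)],
            "n_clean": total - noisy,
            "n_noisy": noisy,
            "percent_clean": 100.0 * (total - noisy) / total,
        })
    return pd.DataFrame(rows, columns=["state", "n_clean", "n_noisy",
                                       "percent_clean"])
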