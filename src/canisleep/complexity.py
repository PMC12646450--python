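"""Nonlinear EEG metrics: binarized Lempel-Ziv complexity and permutation
entropy, on low- and high-frequency signal components.

The EEG is binarized at its median (strictly above the median maps to 1,
ties to 0) and the Kaspar-Schuster production complexity of the binary
string is computed; by default the count is normalized as
``c(n) * log2(n) / n`` so equal-length epochs are comparable on a [0, ~1]
scale. Permutation entropy follows Bandt and Pompe: each window of D
samples at lag tau is reduced to its ordinal (rank-order) pattern, and the
Shannon entropy (bits) of the pattern distribution is normalized by
log2(D!). Defaults D = 4, tau = 1.

Both metrics are computed separately on a low [1, 16] Hz and a high
[17, 50] Hz component of each epoch and averaged over epochs and the four
channels, giving one value per session, state, band and metric. (A
[16, 45] Hz high-band preset also ships; the [17, 50] Hz split is the
default.)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .hypnogram import lzc_sequence
from .io import EpochSet, STATE_NAMES
from .preprocess import bandpass
from .stats import kruskal_dunn

logger = logging.getLogger(__name__)

LOW_BAND = (1.0, 16.0)
HIGH_BAND = (17.0, 50.0)
#: alternative high band matching the figure-style convention
HIGH_BAND_ALT = (16.0, 45.0)


@dataclass
class PEConfig:
    """Ordinal-pattern parameters for permutation entropy."""

    embedding_dimension: int = 4
    delay: int = 1
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.embedding_dimension < 2:
            raise ValueError("embedding dimension must be >= 2")
        if self.delay < 1:
            raise ValueError("delay must be >= 1")


def binarize_median(x: np.ndarray) -> np.ndarray:
    """Binary sequence: 1 where the sample exceeds the signal median,
    0 otherwise (ties map to 0, so a constant signal is all zeros)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return (x > np.median(x)).astype(np.int8)


def lzc_signal(x: np.ndarray, normalized: bool = True) -> float:
    """Median-binarize then Kaspar-Schuster complexity.

    With ``normalized`` the count is scaled by log2(n)/n (binary alphabet),
    approaching ~1 for white noise and small values for regular signals.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    c = lzc_sequence(binarize_median(x))
    if not normalized:
        return float(c)
    n = x.size
    return c * math.log2(n) / n


def _ordinal_counts(x: np.ndarray, d: int, tau: int) -> np.ndarray:
    n_windows = x.size - (d - 1) * tau
    windows = np.lib.stride_tricks.sliding_window_view(x, (d - 1) * tau + 1
                                                       )[:, ::tau]
    assert windows.shape == (n_windows, d)
    # stable argsort: ties broken by order of occurrence
    patterns = np.argsort(windows, axis=1, kind="stable")
    codes = (patterns * (d ** np.arange(d))).sum(axis=1)
    return np.bincount(codes)


def permutation_entropy(x: np.ndarray, cfg: PEConfig | None = None) -> float:
    """Permutation entropy of a series (bits; normalized by log2(D!) when
    ``cfg.normalized``). Rank ties are broken by order of occurrence."""
    cfg = cfg or PEConfig()
    x = np.asarray(x, dtype=float)
    d, tau = cfg.embedding_dimension, cfg.delay
    if x.size < (d - 1) * tau + 1:
        raise ValueError("series shorter than one embedding window")
    counts = _ordinal_counts(x, d, tau)
    p = counts[counts > 0] / counts.sum()
    h = float(-(p * np.log2(p)).sum()) + 0.0   # avoid -0.0 for 1 pattern
    if cfg.normalized:
        h /= math.log2(math.factorial(d))
    return h


@dataclass
class BandSplit:
    """Low/high frequency split for the nonlinear metrics."""

    low: tuple[float, float] = LOW_BAND
    high: tuple[float, float] = HIGH_BAND

    def __post_init__(self) -> None:
        if self.low[1] > self.high[0]:
            raise ValueError("low and high bands must not overlap")


def band_metrics(epochs: EpochSet, fs: float,
                 split: BandSplit | None = None,
                 cfg: PEConfig | None = None,
                 normalized_lzc: bool = True) -> pd.DataFrame:
    """LZC and PE per band for one state's epoch set.

    Each epoch is filtered into the low and high band, both metrics are
    computed per epoch per channel, and the mean over the selected epochs
    and the four channels gives one value per (band, metric). Per-channel
    means are also returned (column ``channel_mean`` False).
    """
    split = split or BandSplit()
    cfg = cfg or PEConfig()
    rows = []
    for band_name, band in (("low", split.low), ("high", split.high)):
        filt = bandpass(epochs.data, fs, band[0], band[1])
        lzc_vals = np.array([[lzc_signal(filt[e, c], normalized_lzc)
                              for c in range(filt.shape[1])]
                             for e in range(filt.shape[0])])
        pe_vals = np.array([[permutation_entropy(filt[e, c], cfg)
                             for c in range(filt.shape[1])]
                            for e in range(filt.shape[0])])
        rows.append((band_name, "lzc", float(lzc_vals.mean())))
        rows.append((band_name, "pe", float(pe_vals.mean())))
    return pd.DataFrame(rows, columns=["band", "metric", "value"])


def cohort_band_metrics(epoch_sets: Mapping[int, EpochSet], fs: float,
                        split: BandSplit | None = None,
                        cfg: PEConfig | None = None) -> pd.DataFrame:
    """Band metrics for every state present in a session (absent states are
    skipped with a log entry, never zero-filled)."""
    frames = []
    for state in range(4):
        if state not in epoch_sets:
            logger.info("state %s absent; nonlinear metrics skipped",
                        STATE_NAMES[state])
            continue
        df = band_metrics(epoch_sets[state], fs, split, cfg)
        df.insert(0, "state", STATE_NAMES[state])
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["state", "band", "metric", "value"])
    return pd.concat(frames, ignore_index=True)


def state_comparison(values: pd.DataFrame, metric: str, band: str,
                     condition: str | None = None,
                     p_adjust: str = "holm") -> tuple[object, pd.DataFrame]:
    """Across-state comparison of a nonlinear metric within one condition.

    ``values`` is a tidy table with columns subject_id, condition, state,
    band, metric, value. Runs the Kruskal-Wallis omnibus test across the
    states present, then Dunn's pairwise post-hoc z-tests with the chosen
    adjustment; returns (omnibus TestResult, pairwise adjusted-p matrix).
    """
    df = values[(values["metric"] == metric) & (values["band"] == band)]
    if condition is not None:
        df = df[df["condition"] == condition]
    groups = {state: sub["value"].to_numpy()
              for state, sub in df.groupby("state") if len(sub) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 states with >= 2 subjects each")
    return kruskal_dunn(groups, p_adjust=p_adjust)
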