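"""Relative power spectral density and channel-pair coherence.

Spectra are estimated by Welch's method with an 800-ms Hann window at 50%
overlap (1.25 Hz resolution on the 3-s analysis epochs; the same engine
serves power and coherence). The rPSD divides the epoch-averaged power at
each frequency by the total power over the [1, 50] Hz normalization band,
removing between-subject amplitude scale (skull thickness, electrode
contact) so comparisons reflect spectral shape only.

Group comparisons are per frequency bin: paired Wilcoxon where both
conditions are available for every subject (wakefulness, drowsiness),
Mann-Whitney otherwise (NREM, REM), with the study's significance levels
(0.01 for rPSD, 0.05 for coherence) and no correction across bins by
default; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EpochSet
from .stats import mann_whitney, paired_wilcoxon

NORM_BAND = (1.0, 50.0)
WINDOW_MS = 800.0
OVERLAP = 0.5


def _welch_params(fs: float) -> tuple[int, int]:
    nperseg = int(round(WINDOW_MS * 1e-3 * fs))
    return nperseg, int(nperseg * OVERLAP)


@dataclass
class RelativePSD:
    """Per-channel relative PSD on the [1, 50] Hz grid (bins sum to 1)."""

    freqs_hz: np.ndarray
    rpsd: np.ndarray                      # (n_channels, n_freqs)
    norm_band: tuple[float, float] = NORM_BAND

    def channel_mean(self) -> np.ndarray:
        return self.rpsd.mean(axis=0)


@dataclass
class CoherenceSpectrum:
    """Magnitude-squared coherence per channel pair on [1, 50] Hz."""

    freqs_hz: np.ndarray
    coh: dict[tuple[str, str], np.ndarray]
    window_ms: float = WINDOW_MS
    overlap: float = OVERLAP


def _epoch_data(epochs: EpochSet | np.ndarray) -> np.ndarray:
    data = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs)
    if data.ndim != 3:
        raise ValueError("expected (n_epochs, n_channels, n_points)")
    if data.shape[0] == 0:
        raise ValueError("empty epoch set")
    return data


def rpsd(epochs: EpochSet | np.ndarray, fs: float,
         norm_band: tuple[float, float] = NORM_BAND) -> RelativePSD:
    """Welch rPSD per channel, averaged over the state's epochs then
    normalized to unit total power inside ``norm_band``."""
    data = _epoch_data(epochs)
    nperseg, noverlap = _welch_params(fs)
    if data.shape[-1] < nperseg:
        raise ValueError("epoch shorter than the Welch window")
    freqs, pxx = sps.welch(data, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=noverlap, axis=-1)
    mean_pxx = pxx.mean(axis=0)           # (n_channels, n_freqs)
    band = (freqs >= norm_band[0]) & (freqs <= norm_band[1])
    out = mean_pxx[:, band]
    total = out.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero power inside the normalization band")
    return RelativePSD(freqs_hz=freqs[band], rpsd=out / total,
                       norm_band=norm_band)


def welch_total_power(x: np.ndarray, fs: float) -> float:
    """Unnormalized Welch total power (integral over frequency); should be
    close to the signal variance for stationary noise."""
    nperseg, noverlap = _welch_params(fs)
    freqs, pxx = sps.welch(np.asarray(x, dtype=float), fs=fs, window="hann",
                           nperseg=nperseg, noverlap=noverlap, axis=-1)
    return float(np.trapezoid(pxx, freqs, axis=-1))


def coherence_pair(epochs: EpochSet | np.ndarray, fs: float,
                   pair: tuple[int, int],
                   band: tuple[float, float] = NORM_BAND,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence of one channel pair, epoch-averaged.

    Each epoch's coherence comes from Welch cross-spectra (800-ms Hann
    segments, 50% overlap); epochs are then averaged. Returns
    ``(freqs, coh)`` restricted to ``band``.
    """
    data = _epoch_data(epochs)
    nperseg, noverlap = _welch_params(fs)
    if data.shape[-1] < nperseg:
        raise ValueError("epoch shorter than the coherence window")
    i, j = pair
    freqs, coh = sps.coherence(data[:, i], data[:, j], fs=fs, window="hann",
                               nperseg=nperseg, noverlap=noverlap, axis=-1)
    mean_coh = coh.mean(axis=0)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    return freqs[keep], mean_coh[keep]


def coherence_all_pairs(epochs: EpochSet | np.ndarray, fs: float,
                        channels: Sequence[str],
                        band: tuple[float, float] = NORM_BAND,
                        ) -> CoherenceSpectrum:
    out: dict[tuple[str, str], np.ndarray] = {}
    freqs = None
    for i, j in combinations(range(len(channels)), 2):
        freqs, coh = coherence_pair(epochs, fs, (i, j), band)
        out[(channels[i], channels[j])] = coh
    return CoherenceSpectrum(freqs_hz=freqs, coh=out)


def compare_bins(group_a: np.ndarray, group_b: np.ndarray,
                 freqs: np.ndarray, paired: bool, alpha: float,
                 fdr: bool = False) -> pd.DataFrame:
    """Per-frequency-bin two-sided test between two groups of spectra.

    ``group_a``/``group_b`` are (n_subjects, n_freqs). Paired mode uses the
    Wilcoxon signed-rank test (rows aligned by subject); unpaired mode the
    Mann-Whitney U test and tolerates unequal group sizes. Raw p-values
    are thresholded at ``alpha`` (the study shades raw p); ``fdr=True``
    applies Benjamini-Hochberg instead.
    """
    group_a = np.atleast_2d(np.asarray(group_a, dtype=float))
    group_b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if group_a.shape[1] != freqs.size or group_b.shape[1] != freqs.size:
        raise ValueError("frequency grids differ between groups")
    if group_a.shape[0] < 2 or group_b.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if paired and group_a.shape[0] != group_b.shape[0]:
        raise ValueError("paired comparison needs aligned groups")
    pvals = np.empty(freqs.size)
    for k in range(freqs.size):
        if paired:
            pvals[k] = paired_wilcoxon(group_a[:, k], group_b[:, k]).p_value
        else:
            pvals[k] = mann_whitney(group_a[:, k], group_b[:, k]).p_value
    if fdr:
        from statsmodels.stats.multitest import multipletests
        sig = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        sig = pvals < alpha
    return pd.DataFrame({"freq_hz": freqs, "p_value": pvals,
                         "significant": sig})


def significant_bands(result: pd.DataFrame) -> list[tuple[float, float]]:
    """Contiguous runs of significant bins as (low, high) Hz intervals."""
    sig = result["significant"].to_numpy()
    freqs = result["freq_hz"].to_numpy()
    bands = []
    start = None
    for k, flag in enumerate(sig):
        if flag and start is None:
            start = freqs[k]
        elif not flag and start is not None:
            bands.append((start, freqs[k - 1]))
            start = None
    if start is not None:
        bands.append((start, freqs[-1]))
    return bands


def compare_rpsd(group_a: Sequence[RelativePSD] | np.ndarray,
                 group_b: Sequence[RelativePSD] | np.ndarray,
                 freqs: np.ndarray | None = None,
                 paired: bool = True, alpha: float = 0.01,
                 fdr: bool = False) -> pd.DataFrame:
    """Per-bin comparison of channel-averaged rPSD between conditions."""
    a, fa = _stack_spectra(group_a, freqs)
    b, fb = _stack_spectra(group_b, freqs)
    if not np.array_equal(fa, fb):
        raise ValueError("frequency grids differ between groups")
    return compare_bins(a, b, fa, paired=paired, alpha=alpha, fdr=fdr)


def compare_coherence(group_a: np.ndarray, group_b: np.ndarray,
                      freqs: np.ndarray, paired: bool = True,
                      alpha: float = 0.05, fdr: bool = False) -> pd.DataFrame:
    """Per-bin comparison of one channel pair's coherence spectra."""
    return compare_bins(group_a, group_b, freqs, paired=paired, alpha=alpha,
                        fdr=fdr)


def _stack_spectra(group, freqs):
    if isinstance(group, np.ndarray) and group.ndim == 2:
        if freqs is None:
            raise ValueError("freqs required with a raw array")
        return group, np.asarray(freqs)
    spectra = list(group)
    f0 = spectra[0].freqs_hz
    for sp in spectra[1:]:
        if not np.array_equal(sp.freqs_hz, f0):
            raise ValueError("frequency grids differ between subjects")
    return np.vstack([sp.channel_mean() for sp in spectra]), f0
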