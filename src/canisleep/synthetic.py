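"""Study-shaped synthetic data: Markov hypnograms and state-dependent,
optionally phase-coupled multichannel EEG for paired cohorts.

The generator emulates the study design (12 dogs, two sessions each —
control and trazodone — of 2 h at 400 Hz on four channels) so that every
pipeline stage can be exercised without the non-deposited recordings.

Hypnograms are first-order Markov chains over wakefulness / drowsiness /
NREM / REM in 3-s epochs. EEG is a sum of Gaussian band-limited noise
components (delta [1,4], theta [4,8], alpha [8,13], beta [13,30], gamma
[30,48] Hz) whose per-state amplitude weights follow the classic sleep
profiles (delta-dominant NREM, broadband wake/REM), over a 1/f pink
background. Component amplitudes follow the scored state of each 3-s
epoch with 0.25-s crossfades, so epochs are internally stationary.
Between-subject variability enters as a lognormal jitter on the band
weights, shared by a subject's two sessions. Cross-channel coupling is
injected by letting a channel pair share a fraction of a band's amplitude
through a common drive, one copy phase-shifted by a fixed lag — the
construction the phase-lag-index stage is designed to detect. (The share
is linear in amplitude: a fraction f leaves private noise at relative
amplitude 1-f, i.e. a variance ratio (f/(1-f))^2, which keeps the drive
dominant through its envelope fades.) Artifact
epochs are flagged (not corrupted) at per-state rates taken from the
study's reported retention percentages.

The trazodone-like preset applies the drug signature reported by the
study: stickier states (higher self-transition probabilities, hence lower
hypnogram complexity), strongly reduced NREM-to-REM entry (so most
sessions never reach REM), reduced low-frequency power in wakefulness and
drowsiness, a 1.5x power increase above 13 Hz in drowsiness and NREM, and
extra alpha-band Cz-Fz coupling in NREM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .connectivity import _band_response
from .io import (EEG_CHANNELS, Hypnogram, SessionRecording, StudyManifest,
                 write_edf, write_hypnogram, write_manifest)
from .preprocess import derive_seed

#: generator band edges (Hz) — classic broad bands, distinct from the
#: narrow 2-Hz analysis bands used by the PLI stage
GEN_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 48.0),
}
CROSSFADE_S = 0.25


@dataclass
class StateSpectralProfile:
    """Relative band-amplitude weights plus pink background for one state."""

    weights: dict[str, float]
    pink_weight: float = 0.15
    pink_exponent: float = 1.0
    amplitude_uv: float = 30.0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("band weights must be nonnegative")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one band weight must be positive")


@dataclass
class CouplingSpec:
    """Shared band-limited drive between two channels with a phase lag."""

    pair: tuple[str, str]
    band: str
    phase_lag: float = np.pi / 4
    coupling_fraction: float = 0.8        # amplitude share of the shared drive
    state: int | None = None              # active state; None = all states

    def __post_init__(self) -> None:
        if not -np.pi < self.phase_lag <= np.pi:
            raise ValueError("phase lag must lie in (-pi, pi]")
        if not 0.0 <= self.coupling_fraction <= 1.0:
            raise ValueError("coupling fraction must lie in [0, 1]")
        if self.band not in GEN_BANDS:
            raise ValueError(f"unknown band {self.band!r}")


@dataclass
class ConditionSpec:
    """Per-condition generative parameters."""

    transitions: np.ndarray               # row-stochastic 4x4
    profiles: dict[int, StateSpectralProfile]
    couplings: list[CouplingSpec] = field(default_factory=list)
    artifact_rate: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        _check_stochastic(self.transitions)


@dataclass
class CohortConfig:
    """Paired-cohort generation parameters (defaults mirror the study:
    12 subjects, 120-min sessions, 400 Hz, 3-s epochs)."""

    conditions: dict[str, ConditionSpec]
    n_subjects: int = 12
    duration_min: float = 120.0
    fs: float = 400.0
    epoch_length_s: float = 3.0
    subject_weight_jitter: float = 0.05   # lognormal sigma on band weights
    initial_state: int = 0
    seed: int = 0

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_min * 60.0 / self.epoch_length_s))


def _check_stochastic(mat: np.ndarray) -> None:
    if mat.shape != (4, 4) or np.any(mat < 0) or \
            not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix must be 4x4 row-stochastic")


# ---------------------------------------------------------------------------
# Hypnogram generation
# ---------------------------------------------------------------------------

def gen_hypnogram(transitions: np.ndarray, n_epochs: int,
                  initial_state: int = 0,
                  rng: np.random.Generator | int = 0) -> np.ndarray:
    """Realize a first-order Markov state sequence (codes 0-3)."""
    transitions = np.asarray(transitions, dtype=float)
    _check_stochastic(transitions)
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    states = np.empty(n_epochs, dtype=np.int64)
    cum = transitions.cumsum(axis=1)
    u = rng.random(n_epochs)
    s = initial_state
    for t in range(n_epochs):
        states[t] = s
        s = int(np.searchsorted(cum[s], u[t], side="right"))
    return states


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _band_noise_spectrum(n: int, fs: float, band: tuple[float, float],
                         rng: np.random.Generator,
                         shape: tuple[int, ...] = ()) -> np.ndarray:
    """Unit-RMS Gaussian band noise via spectral shaping (rFFT domain).

    Random coefficients are drawn only where the band response is
    non-negligible; elsewhere the spectrum is exactly zero.
    """
    from scipy import fft as sfft

    nf = n // 2 + 1
    resp = np.sqrt(_band_response(band, fs, n)).astype(np.float32)
    support = np.flatnonzero(resp > 1e-8)
    spec = np.zeros(shape + (nf,), dtype=np.complex64)
    spec[..., support] = resp[support] * (
        rng.standard_normal(shape + (support.size,), dtype=np.float32) +
        1j * rng.standard_normal(shape + (support.size,), dtype=np.float32))
    x = sfft.irfft(spec, n=n, axis=-1).astype(np.float64)
    return x / x.std(axis=-1, keepdims=True)


def _pink_noise(n: int, fs: float, exponent: float,
                rng: np.random.Generator, shape: tuple[int, ...] = ()
                ) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.zeros_like(freqs)
    valid = (freqs >= 0.5) & (freqs <= 70.0)
    gain[valid] = freqs[valid] ** (-exponent / 2.0)
    spec = (rng.standard_normal(shape + (freqs.size,), dtype=np.float32) +
            1j * rng.standard_normal(shape + (freqs.size,), dtype=np.float32)
            ) * gain.astype(np.float32)
    from scipy import fft as sfft
    x = sfft.irfft(spec, n=n, axis=-1).astype(np.float64)
    return x / x.std(axis=-1, keepdims=True)


def _phase_shifted(spectrum_signal: np.ndarray, lag: float) -> np.ndarray:
    """Copy of a (narrowband) signal with every positive-frequency
    component delayed in phase by ``lag`` radians."""
    n = spectrum_signal.shape[-1]
    spec = np.fft.rfft(spectrum_signal, axis=-1)
    spec[..., 1:] *= np.exp(-1j * lag)
    return np.fft.irfft(spec, n=n, axis=-1)


def _state_envelopes(states: np.ndarray, samples_per_epoch: int,
                     fs: float) -> np.ndarray:
    """(4, n_samples) smooth state-indicator envelopes (0.25-s crossfade,
    summing to 1 at every sample)."""
    fade = max(int(round(CROSSFADE_S * fs)) | 1, 3)    # odd width
    env = np.empty((4, states.size * samples_per_epoch))
    for s in range(4):
        ind = np.repeat((states == s).astype(float), samples_per_epoch)
        env[s] = uniform_filter1d(uniform_filter1d(ind, fade), fade)
    return env / env.sum(axis=0, keepdims=True)


def gen_state_eeg(profile: StateSpectralProfile,
                  couplings: list[CouplingSpec] | None = None,
                  n_channels: int = 4, duration_s: float = 30.0,
                  fs: float = 400.0,
                  rng: np.random.Generator | int = 0,
                  channels: tuple[str, ...] = EEG_CHANNELS) -> np.ndarray:
    """Single-state multichannel EEG segment (µV); couplings active
    throughout. Returns (n_channels, n_samples)."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    n = int(round(duration_s * fs))
    couplings = couplings or []
    for c in couplings:
        for ch in c.pair:
            if ch not in channels[:n_channels]:
                raise ValueError(f"coupling channel {ch!r} not in montage")
    out = np.zeros((n_channels, n))
    for name, band in GEN_BANDS.items():
        comp = _band_noise_spectrum(n, fs, band, rng, (n_channels,))
        for c in couplings:
            if c.band != name:
                continue
            i = channels.index(c.pair[0])
            j = channels.index(c.pair[1])
            drive = _band_noise_spectrum(n, fs, band, rng)
            f = c.coupling_fraction
            norm = np.sqrt((1 - f) ** 2 + f ** 2)
            comp[i] = ((1 - f) * comp[i] + f * drive) / norm
            comp[j] = ((1 - f) * comp[j] +
                       f * _phase_shifted(drive, c.phase_lag)) / norm
        out += profile.weights[name] * comp
    out += profile.pink_weight * _pink_noise(n, fs, profile.pink_exponent,
                                             rng, (n_channels,))
    return profile.amplitude_uv * out


def gen_session(cond: ConditionSpec, cfg: CohortConfig,
                subject_jitter: dict[str, float],
                rng: np.random.Generator) -> tuple[np.ndarray, Hypnogram]:
    """One session: (signal (4, n_samples) µV, hypnogram).

    Band amplitudes follow the scored state of each epoch through smooth
    envelopes; couplings are blended in only during their active state.
    """
    n_epochs = cfg.n_epochs
    spe = int(round(cfg.fs * cfg.epoch_length_s))
    n = n_epochs * spe
    states = gen_hypnogram(cond.transitions, n_epochs, cfg.initial_state, rng)
    artifact = np.zeros(n_epochs, dtype=bool)
    for s, rate in cond.artifact_rate.items():
        m = states == s
        artifact[m] = rng.random(m.sum()) < rate
    env = _state_envelopes(states, spe, cfg.fs)

    n_ch = len(EEG_CHANNELS)
    signal = np.zeros((n_ch, n))
    for name, band in GEN_BANDS.items():
        comp = _band_noise_spectrum(n, cfg.fs, band, rng, (n_ch,))
        # per-sample amplitude for this band: state profile x subject trait
        amp = np.zeros(n)
        for s in range(4):
            prof = cond.profiles[s]
            amp += env[s] * prof.amplitude_uv * prof.weights[name] * \
                subject_jitter[name]
        contrib = comp * amp
        for c in cond.couplings:
            if c.band != name:
                continue
            i = EEG_CHANNELS.index(c.pair[0])
            j = EEG_CHANNELS.index(c.pair[1])
            drive = _band_noise_spectrum(n, cfg.fs, band, rng)
            f = c.coupling_fraction
            norm = np.sqrt((1 - f) ** 2 + f ** 2)
            mixed_i = ((1 - f) * comp[i] + f * drive) / norm
            mixed_j = ((1 - f) * comp[j] +
                       f * _phase_shifted(drive, c.phase_lag)) / norm
            gate = env[c.state] if c.state is not None else 1.0
            contrib[i] += amp * gate * (mixed_i - comp[i])
            contrib[j] += amp * gate * (mixed_j - comp[j])
        signal += contrib
    pink_amp = np.zeros(n)
    for s in range(4):
        prof = cond.profiles[s]
        pink_amp += env[s] * prof.amplitude_uv * prof.pink_weight
    signal += pink_amp * _pink_noise(n, cfg.fs, 1.0, rng, (n_ch,))
    return signal, Hypnogram(states, artifact, cfg.epoch_length_s)


def gen_cohort(cfg: CohortConfig
               ) -> dict[tuple[str, str], tuple[SessionRecording, Hypnogram]]:
    """Generate the full paired cohort in memory.

    Returns a mapping (subject_id, condition) -> (recording, hypnogram);
    fully deterministic in ``cfg.seed``. Subject band-weight jitter is a
    subject trait shared by both of a subject's sessions.
    """
    out = {}
    for k in range(cfg.n_subjects):
        subject = f"dog{k + 1:02d}"
        jit_rng = np.random.default_rng(derive_seed(cfg.seed, "jitter", subject))
        jitter = {b: float(jit_rng.lognormal(0.0, cfg.subject_weight_jitter))
                  for b in GEN_BANDS}
        for cond_name, cond in cfg.conditions.items():
            rng = np.random.default_rng(
                derive_seed(cfg.seed, "session", subject, cond_name))
            signal, hyp = gen_session(cond, cfg, jitter, rng)
            rec = SessionRecording(subject_id=subject, condition=cond_name,
                                   channels=EEG_CHANNELS,
                                   sampling_rate_hz=cfg.fs, signal=signal)
            out[(subject, cond_name)] = (rec, hyp)
    return out


def gen_cohort_to_disk(cfg: CohortConfig, outdir: str | Path) -> StudyManifest:
    """Generate the cohort and write EDF recordings, TSV hypnograms and the
    study manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sessions = gen_cohort(cfg)
    meta_rng = np.random.default_rng(derive_seed(cfg.seed, "demographics"))
    rows = []
    weights = {}
    ages = {}
    for (subject, cond), (rec, hyp) in sessions.items():
        rec_path = outdir / f"{subject}_{cond}.edf"
        hyp_path = outdir / f"{subject}_{cond}_hypnogram.tsv"
        write_edf(rec_path, rec.signal, rec.sampling_rate_hz, rec.channels)
        write_hypnogram(hyp_path, hyp)
        if subject not in weights:       # study-like dog demographics
            weights[subject] = round(float(meta_rng.uniform(5.0, 32.0)), 1)
            ages[subject] = round(float(meta_rng.uniform(15.0, 155.0)), 1)
        rows.append({
            "subject_id": subject, "condition": cond,
            "recording_path": rec_path.name, "hypnogram_path": hyp_path.name,
            "weight_kg": weights[subject], "age_months": ages[subject],
        })
    manifest = StudyManifest(pd.DataFrame(rows))
    write_manifest(outdir / "manifest.tsv", manifest)
    return manifest


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: per-state band-amplitude weights (relative µV): broadband wake/REM,
#: delta-dominant NREM
_BASE_WEIGHTS: dict[int, dict[str, float]] = {
    0: {"delta": 0.30, "theta": 0.60, "alpha": 0.80, "beta": 0.70,
        "gamma": 0.40},
    1: {"delta": 0.60, "theta": 0.80, "alpha": 0.60, "beta": 0.40,
        "gamma": 0.20},
    2: {"delta": 1.50, "theta": 0.50, "alpha": 0.30, "beta": 0.15,
        "gamma": 0.08},
    3: {"delta": 0.35, "theta": 0.70, "alpha": 0.60, "beta": 0.50,
        "gamma": 0.30},
}

#: clean-epoch retention by state matching the study's reported averages
_ARTIFACT_CONTROL = {0: 1 - 0.077, 1: 1 - 0.411, 2: 0.0, 3: 1 - 0.335}
_ARTIFACT_TRAZODONE = {0: 1 - 0.177, 1: 1 - 0.589, 2: 0.0, 3: 1 - 0.531}

_TRANSITIONS_CONTROL = np.array([
    [0.880, 0.100, 0.020, 0.000],
    [0.060, 0.800, 0.140, 0.000],
    [0.015, 0.045, 0.930, 0.010],
    [0.050, 0.000, 0.100, 0.850],
])
#: trazodone: stickier states, strongly suppressed NREM->REM entry
_TRANSITIONS_TRAZODONE = np.array([
    [0.930, 0.060, 0.010, 0.000],
    [0.025, 0.910, 0.065, 0.000],
    [0.008, 0.032, 0.9595, 0.0005],
    [0.050, 0.000, 0.100, 0.850],
])

#: spectral drug signature: power x0.8 below 13 Hz in wake/drowsiness,
#: power x1.5 above 13 Hz in drowsiness/NREM (amplitudes scale by sqrt)
_LOW_GEN = ("delta", "theta", "alpha")
_HIGH_GEN = ("beta", "gamma")
HIGH_POWER_FACTOR = 1.5
LOW_POWER_FACTOR = 0.8


def control_condition() -> ConditionSpec:
    return ConditionSpec(
        transitions=_TRANSITIONS_CONTROL.copy(),
        profiles={s: StateSpectralProfile(dict(w))
                  for s, w in _BASE_WEIGHTS.items()},
        couplings=[],
        artifact_rate=dict(_ARTIFACT_CONTROL),
    )


def trazodone_like_condition() -> ConditionSpec:
    profiles = {}
    for s, w in _BASE_WEIGHTS.items():
        w = dict(w)
        if s in (0, 1):
            for b in _LOW_GEN:
                w[b] *= np.sqrt(LOW_POWER_FACTOR)
        if s in (1, 2):
            for b in _HIGH_GEN:
                w[b] *= np.sqrt(HIGH_POWER_FACTOR)
        profiles[s] = StateSpectralProfile(w)
    return ConditionSpec(
        transitions=_TRANSITIONS_TRAZODONE.copy(),
        profiles=profiles,
        couplings=[CouplingSpec(pair=("Fz", "Cz"), band="alpha",
                                phase_lag=np.pi / 4, coupling_fraction=0.8,
                                state=2)],
        artifact_rate=dict(_ARTIFACT_TRAZODONE),
    )


def trazodone_like_config(n_subjects: int = 12, duration_min: float = 120.0,
                          seed: int = 0) -> CohortConfig:
    """The paired study preset: control vs the trazodone-like signature."""
    return CohortConfig(
        conditions={"control": control_condition(),
                    "trazodone": trazodone_like_condition()},
        n_subjects=n_subjects, duration_min=duration_min, seed=seed,
    )


def null_config(n_subjects: int = 12, duration_min: float = 120.0,
                seed: int = 0) -> CohortConfig:
    """Matched null preset: both conditions generated identically (for
    empirical type-I-error checks)."""
    return CohortConfig(
        conditions={"control": control_condition(),
                    "trazodone": control_condition()},
        n_subjects=n_subjects, duration_min=duration_min, seed=seed,
    )


PRESETS = {"trazodone-like": trazodone_like_config, "null": null_config}
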