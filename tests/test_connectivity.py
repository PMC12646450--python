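"""Phase extraction, PLI, surrogate construction and the
surrogate-thresholded condition difference."""

import numpy as np
import pytest

from canisleep.connectivity import (delta_pli, instantaneous_phase,
                                    narrowband_analytic, pli_pair,
                                    pli_state_matrix, surrogate_signals)
from canisleep.preprocess import PLI_BANDS, bandpass
from oracles import pli_loop

FS = 400.0


def _tone(freq, seconds=3.0, phase=0.0):
    t = np.arange(int(seconds * FS)) / FS
    return np.sin(2 * np.pi * freq * t + phase)


class TestInstantaneousPhase:
    def test_phase_advances_at_carrier_rate(self):
        ph = instantaneous_phase(_tone(10.0))
        rate = np.median(np.diff(np.unwrap(ph))) * FS / (2 * np.pi)
        assert rate == pytest.approx(10.0, rel=0.01)

    def test_quadrature_pair_offset_by_half_pi(self):
        t = np.arange(1200) / FS
        ph_sin = instantaneous_phase(np.sin(2 * np.pi * 10 * t))
        ph_cos = instantaneous_phase(np.cos(2 * np.pi * 10 * t))
        diff = np.angle(np.exp(1j * (ph_cos - ph_sin)))
        assert abs(np.median(diff) - np.pi / 2) < 0.05

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros(1000))


class TestPLIPair:
    def test_constant_lag_gives_unit_pli(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 5000)
        assert pli_pair(ph, ph - np.pi / 2) == pytest.approx(1.0)

    def test_zero_lag_gives_zero_pli(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 5000)
        assert pli_pair(ph, ph.copy()) == 0.0

    def test_independent_phases_near_zero(self, rng):
        a = rng.uniform(-np.pi, np.pi, 10_000)
        b = rng.uniform(-np.pi, np.pi, 10_000)
        assert pli_pair(a, b) < 0.05

    def test_matches_explicit_loop(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 200))
            a = rng.uniform(-8, 8, n)
            b = rng.uniform(-8, 8, n)
            assert pli_pair(a, b) == pytest.approx(pli_loop(a, b),
                                                   abs=1e-12)

    def test_symmetric_under_swap(self, rng):
        a = rng.uniform(-np.pi, np.pi, 500)
        b = rng.uniform(-np.pi, np.pi, 500)
        assert pli_pair(a, b) == pytest.approx(pli_pair(b, a), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pli_pair(np.zeros(5), np.zeros(4))


class TestNarrowbandAnalytic:
    def test_agrees_with_filtfilt_hilbert_inside_epoch(self, rng):
        from scipy import signal as sps
        x = rng.normal(0, 1, 1200)
        z = narrowband_analytic(x, FS, PLI_BANDS["alpha"])
        sos = sps.butter(4, PLI_BANDS["alpha"], btype="bandpass", fs=FS,
                         output="sos")
        ref = sps.hilbert(sps.sosfiltfilt(sos, x))
        mid = slice(120, 1080)
        err = np.abs(np.angle(z[mid] / ref[mid]))
        assert np.median(err) < 0.15


class TestPLIMatrix:
    def test_common_zero_lag_drive_scores_zero(self):
        tone = _tone(10.0)
        data = np.tile(tone, (1, 4, 1)).astype(float)
        mats = pli_state_matrix(data, FS, {"alpha": PLI_BANDS["alpha"]})
        assert np.allclose(mats["alpha"], 0.0, atol=1e-9)

    def test_lagged_pair_stands_out(self, rng):
        from canisleep.synthetic import CouplingSpec, gen_state_eeg
        from canisleep.synthetic import control_condition
        cpl = CouplingSpec(pair=("F3", "F4"), band="alpha",
                           phase_lag=np.pi / 4, coupling_fraction=0.9,
                           state=None)
        x = gen_state_eeg(control_condition().profiles[0], [cpl],
                          duration_s=60, rng=rng)
        epochs = x.reshape(4, -1, 12_000).transpose(1, 0, 2)
        mat = pli_state_matrix(epochs, FS)["alpha"]
        assert mat[0, 1] > 0.8
        others = [mat[i, j] for i in range(4) for j in range(i + 1, 4)
                  if (i, j) != (0, 1)]
        assert max(others) < 0.2

    def test_symmetry_zero_diagonal_bounds(self, rng):
        data = rng.normal(0, 1, (3, 4, 1200))
        for mat in pli_state_matrix(data, FS).values():
            assert np.allclose(mat, mat.T)
            assert np.allclose(np.diag(mat), 0.0)
            assert (mat >= 0).all() and (mat <= 1).all()


class TestSurrogates:
    def test_amplitude_spectrum_preserved(self, rng):
        epoch = bandpass(rng.normal(0, 1, (4, 1200)), FS, 1, 70)
        surr = surrogate_signals(epoch, np.random.default_rng(3))
        orig = np.abs(np.fft.rfft(epoch, axis=-1))
        new = np.abs(np.fft.rfft(surr, axis=-1))
        band = slice(3, 210)            # [1, 70] Hz on the 1200-point grid
        ratio = new[:, band].sum(axis=1) / orig[:, band].sum(axis=1)
        assert np.allclose(ratio, 1.0, atol=0.01)

    def test_coupling_destroyed(self, rng):
        from canisleep.synthetic import CouplingSpec, control_condition, \
            gen_state_eeg
        cpl = CouplingSpec(pair=("F3", "F4"), band="alpha",
                           phase_lag=np.pi / 3, coupling_fraction=0.9,
                           state=None)
        x = gen_state_eeg(control_condition().profiles[0], [cpl],
                          duration_s=180, rng=rng)
        epochs = x.reshape(4, -1, 24_000).transpose(1, 0, 2)
        real = pli_state_matrix(epochs, FS)["alpha"][0, 1]
        surr_vals = []
        for k in range(20):
            s = np.stack([surrogate_signals(e, np.random.default_rng(k))
                          for e in epochs])
            surr_vals.append(pli_state_matrix(s, FS)["alpha"][0, 1])
        assert real > 0.8
        assert np.mean(surr_vals) < 0.1

    def test_deterministic_given_seed(self, rng):
        epoch = rng.normal(0, 1, (4, 1200))
        a = surrogate_signals(epoch, np.random.default_rng(5))
        b = surrogate_signals(epoch, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestDeltaPLI:
    def _epochs(self, rng, coupled=False):
        from canisleep.synthetic import CouplingSpec, control_condition, \
            gen_state_eeg
        couplings = []
        if coupled:
            couplings = [CouplingSpec(pair=("Fz", "Cz"), band="alpha",
                                      phase_lag=np.pi / 4,
                                      coupling_fraction=0.8, state=None)]
        x = gen_state_eeg(control_condition().profiles[2], couplings,
                          duration_s=15, rng=rng)
        return x.reshape(4, -1, 1200).transpose(1, 0, 2)

    def test_single_surrogate_rejected(self, rng):
        ctrl = {f"d{k}": self._epochs(rng) for k in range(2)}
        with pytest.raises(ValueError, match="n_surrogates"):
            delta_pli(ctrl, ctrl, FS, n_surrogates=1)

    def test_single_common_subject_rejected(self, rng):
        ctrl = {"a": self._epochs(rng), "b": self._epochs(rng)}
        traz = {"a": self._epochs(rng)}
        with pytest.raises(ValueError, match="subjects"):
            delta_pli(ctrl, traz, FS, n_surrogates=4)

    def test_injected_coupling_flagged_with_direction(self, rng):
        bands = {"alpha": PLI_BANDS["alpha"], "delta": PLI_BANDS["delta"]}
        ctrl = {f"d{k}": self._epochs(rng) for k in range(6)}
        traz = {f"d{k}": self._epochs(rng, coupled=True) for k in range(6)}
        res = delta_pli(ctrl, traz, FS, bands, n_surrogates=50, seed=4)
        flags = res["alpha"].flags.set_index("edge")
        assert flags.loc["Fz-Cz", "flagged"]
        assert flags.loc["Fz-Cz", "direction"] == "trazodone-increase"
        assert not res["delta"].flags["flagged"].any()

    def test_threshold_scopes_ordered_by_strictness(self, rng):
        """The pooled scope thresholds at single-dog noise scale, well
        above the ensemble scope's standard-error scale."""
        from canisleep.connectivity import SurrogateEnsemble
        diffs = [rng.normal(0, 0.1, (30, 4, 4)) for _ in range(8)]
        ens = SurrogateEnsemble(band="alpha", n_surrogates=30, seed=0,
                                diffs=diffs)
        _, sd_pooled = ens.threshold("pooled")
        _, sd_ensemble = ens.threshold("ensemble")
        assert np.median(sd_pooled / sd_ensemble) > 2.0
        with pytest.raises(ValueError):
            ens.threshold("bogus")

    def test_flags_reproducible_given_seed(self, rng):
        ctrl = {f"d{k}": self._epochs(rng) for k in range(3)}
        traz = {f"d{k}": self._epochs(rng) for k in range(3)}
        bands = {"alpha": PLI_BANDS["alpha"]}
        a = delta_pli(ctrl, traz, FS, bands, n_surrogates=20, seed=9)
        b = delta_pli(ctrl, traz, FS, bands, n_surrogates=20, seed=9)
        assert np.array_equal(a["alpha"].threshold, b["alpha"].threshold)
        assert a["alpha"].flags.equals(b["alpha"].flags)
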