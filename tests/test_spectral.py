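"""Relative PSD and coherence: concentration, normalization, scale
invariance, and per-bin group comparisons."""

import numpy as np
import pytest

from canisleep.spectral import (coherence_all_pairs, coherence_pair,
                                compare_bins, compare_rpsd, rpsd,
                                significant_bands, welch_total_power)

FS = 400.0


def _sine_epochs(freq, n_epochs=5, n_ch=4, n=1200, amp=1.0, noise=0.0,
                 rng=None):
    rng = rng or np.random.default_rng(0)
    t = np.arange(n) / FS
    phases = rng.uniform(0, 2 * np.pi, (n_epochs, n_ch, 1))
    out = amp * np.sin(2 * np.pi * freq * t + phases)
    if noise:
        out = out + rng.normal(0, noise, out.shape)
    return out


class TestRPSD:
    def test_pure_tone_concentrates_power(self):
        sp = rpsd(_sine_epochs(10.0), FS)
        mask = np.abs(sp.freqs_hz - 10.0) <= 1.5   # +/- one 1.25-Hz bin
        assert sp.rpsd[:, mask].sum(axis=1).min() >= 0.8

    def test_normalization_band_sums_to_one(self, rng):
        sp = rpsd(rng.normal(0, 1, (3, 4, 1200)), FS)
        assert np.allclose(sp.rpsd.sum(axis=1), 1.0, atol=1e-9)
        assert (sp.rpsd >= 0).all()
        assert sp.freqs_hz.min() >= 1.0 and sp.freqs_hz.max() <= 50.0

    def test_white_noise_spectrum_flat_after_averaging(self, rng):
        sp = rpsd(rng.normal(0, 1, (100, 1, 1200)), FS)
        mid = sp.rpsd[0, (sp.freqs_hz >= 5) & (sp.freqs_hz <= 45)]
        assert mid.max() / mid.min() < 3.0

    def test_amplitude_scale_invariance(self, rng):
        x = rng.normal(0, 1, (4, 4, 1200))
        a = rpsd(x, FS)
        b = rpsd(1000.0 * x, FS)
        assert np.allclose(a.rpsd, b.rpsd, atol=1e-12)

    def test_empty_epochs_rejected(self):
        with pytest.raises(ValueError):
            rpsd(np.empty((0, 4, 1200)), FS)

    def test_parseval_total_power_near_variance(self, rng):
        x = rng.normal(0, 2.0, 40_000)
        assert welch_total_power(x, FS) == pytest.approx(4.0, rel=0.1)


class TestCoherence:
    def test_identical_signals_fully_coherent(self, rng):
        x = rng.normal(0, 1, (5, 1, 1200))
        data = np.concatenate([x, x], axis=1)
        _, coh = coherence_pair(data, FS, (0, 1))
        assert np.allclose(coh, 1.0, atol=1e-9)

    def test_independent_noise_incoherent_when_averaged(self, rng):
        data = rng.normal(0, 1, (1, 2, 80_000))
        _, coh = coherence_pair(data, FS, (0, 1))
        assert coh.mean() < 0.2

    def test_shared_tone_peaks_at_its_frequency(self, rng):
        t = np.arange(40_000) / FS
        tone = np.sin(2 * np.pi * 10 * t)
        data = np.stack([tone + rng.normal(0, 1, t.size),
                         tone + rng.normal(0, 1, t.size)])[None]
        freqs, coh = coherence_pair(data, FS, (0, 1))
        at_tone = coh[np.abs(freqs - 10.0).argmin()]
        elsewhere = coh[(freqs >= 20) & (freqs <= 45)].mean()
        assert at_tone > elsewhere

    def test_epoch_shorter_than_window_rejected(self, rng):
        with pytest.raises(ValueError):
            coherence_pair(rng.normal(0, 1, (2, 2, 200)), FS, (0, 1))

    def test_all_pairs_symmetric_bounded(self, rng, channels):
        cs = coherence_all_pairs(rng.normal(0, 1, (3, 4, 1200)), FS, channels)
        assert len(cs.coh) == 6
        for vals in cs.coh.values():
            assert (vals >= 0).all() and (vals <= 1.0 + 1e-12).all()


class TestCompare:
    def _spectra(self, rng, n_subjects, boost_high=1.0):
        """Channel-averaged rPSD rows for a small cohort of noise EEG."""
        rows = []
        t = np.arange(1200) / FS
        for _ in range(n_subjects):
            jit = rng.lognormal(0, 0.1, 4)
            epochs = []
            for _ in range(5):
                low = jit[0] * np.sin(2 * np.pi * 4 * t +
                                      rng.uniform(0, 2 * np.pi))
                high = boost_high * jit[1] * 0.4 * np.sin(
                    2 * np.pi * 25 * t + rng.uniform(0, 2 * np.pi))
                noise = 0.3 * rng.normal(0, 1, (4, 1200))
                epochs.append(low + high + noise)
            sp = rpsd(np.stack(epochs), FS)
            rows.append(sp.channel_mean())
        return np.vstack(rows), sp.freqs_hz

    def test_identical_groups_nothing_significant(self, rng):
        a, freqs = self._spectra(rng, 6)
        res = compare_bins(a, a, freqs, paired=True, alpha=0.01)
        assert not res["significant"].any()

    def test_high_band_boost_detected_only_at_high_frequencies(self):
        rng = np.random.default_rng(77)
        a, freqs = self._spectra(rng, 10)
        b, _ = self._spectra(rng, 10, boost_high=1.6)
        res = compare_bins(a, b, freqs, paired=False, alpha=0.01)
        hit = res[(res["freq_hz"] > 20) & (res["freq_hz"] < 30)]
        miss = res[(res["freq_hz"] > 6) & (res["freq_hz"] < 15)]
        # the boosted band must light up; away from it only the mild
        # renormalization counter-shift may occasionally reach threshold
        assert hit["significant"].mean() > 0.4
        assert miss["significant"].mean() <= 0.35

    def test_single_subject_rejected(self, rng):
        a, freqs = self._spectra(rng, 1)
        with pytest.raises(ValueError):
            compare_bins(a, a, freqs, paired=False, alpha=0.05)

    def test_mismatched_grids_rejected(self, rng):
        a, freqs = self._spectra(rng, 3)
        with pytest.raises(ValueError):
            compare_bins(a, a[:, :-1], freqs[:-1], paired=True, alpha=0.05)

    def test_unpaired_mode_tolerates_unequal_groups(self, rng):
        a, freqs = self._spectra(rng, 12)
        b, _ = self._spectra(rng, 5)
        res = compare_bins(a, b, freqs, paired=False, alpha=0.05)
        assert len(res) == freqs.size

    def test_contiguous_bins_reported_as_bands(self, rng):
        import pandas as pd
        res = pd.DataFrame({"freq_hz": [1.25, 2.5, 3.75, 5.0, 6.25],
                            "p_value": 0.5,
                            "significant": [True, True, False, True, True]})
        assert significant_bands(res) == [(1.25, 2.5), (5.0, 6.25)]

    def test_shared_drive_raises_coherence_at_its_frequency_only(self):
        """A condition that adds a shared 20 Hz drive to one channel pair
        must be flagged near 20 Hz by the coherence comparison."""
        from canisleep.spectral import compare_coherence

        rng = np.random.default_rng(88)
        t = np.arange(2400) / FS

        def subject(shared):
            epochs = []
            for _ in range(5):
                noise = rng.normal(0, 1, (2, 2400))
                if shared:
                    drive = np.sin(2 * np.pi * 20 * t +
                                   rng.uniform(0, 2 * np.pi))
                    noise += 1.2 * drive
                epochs.append(noise)
            freqs, coh = coherence_pair(np.stack(epochs), FS, (0, 1))
            return freqs, coh

        freqs, _ = subject(False)
        a = np.vstack([subject(False)[1] for _ in range(8)])
        b = np.vstack([subject(True)[1] for _ in range(8)])
        res = compare_coherence(a, b, freqs, paired=False, alpha=0.05)
        near = res[np.abs(res["freq_hz"] - 20.0) <= 2.0]
        far = res[(res["freq_hz"] >= 30) & (res["freq_hz"] <= 45)]
        assert near["significant"].any()
        assert far["significant"].mean() < 0.3

    def test_rpsd_objects_accepted(self, rng):
        spectra = [rpsd(rng.normal(0, 1, (3, 4, 1200)), FS)
                   for _ in range(4)]
        res = compare_rpsd(spectra, spectra, paired=True)
        assert not res["significant"].any()
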