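"""Shared end-to-end cohort analysis used by the acceptance suite: run
the full method chain (filter -> epoch -> sample -> analyze) in memory on
generated cohorts and summarize what each stage detected."""

from __future__ import annotations

import numpy as np

from canisleep.connectivity import delta_pli
from canisleep.hypnogram import latency, lzc_sequence
from canisleep.io import segment_epochs
from canisleep.preprocess import (PLI_BANDS, bandpass, notch,
                                  sample_clean_epochs)
from canisleep.spectral import compare_bins, rpsd
from canisleep.stats import mann_whitney, paired_wilcoxon
from canisleep.complexity import PEConfig, permutation_entropy
from canisleep.synthetic import gen_cohort

FS = 400.0
NREM = 2
REM = 3


def prepare_epochs(sessions, seed):
    """Filter each session ([1,70] Hz band-pass + 60 Hz notch), segment
    into scored 3-s epochs and sample 5 clean epochs per state."""
    out = {}
    for (subj, cond), (rec, hyp) in sessions.items():
        rec.signal = notch(bandpass(rec.signal, rec.sampling_rate_hz),
                           rec.sampling_rate_hz)
        seg = segment_epochs(rec, hyp)
        out[(subj, cond)] = sample_clean_epochs(seg.by_state(), 5, seed=seed)
    return out


def _state_sets(epochs, cond, state):
    return {s: sets[state] for (s, c), sets in epochs.items()
            if c == cond and state in sets}


def nrem_rpsd_comparison(epochs, alpha=0.01):
    """Per-bin unpaired comparison of channel-averaged NREM rPSD."""
    spectra = {"control": [], "trazodone": []}
    freqs = None
    for (subj, cond), sets in epochs.items():
        if NREM in sets:
            sp = rpsd(sets[NREM], FS)
            freqs = sp.freqs_hz
            spectra[cond].append(sp.channel_mean())
    return compare_bins(np.vstack(spectra["control"]),
                        np.vstack(spectra["trazodone"]),
                        freqs, paired=False, alpha=alpha)


def hypnogram_stats(sessions):
    """REM censoring counts and the paired hypnogram-LZC comparison."""
    absent = {"control": 0, "trazodone": 0}
    censored_at_total = True
    lzc = {"control": {}, "trazodone": {}}
    for (subj, cond), (_, hyp) in sessions.items():
        lat, cen = latency(hyp, REM)
        absent[cond] += cen
        if cen and lat != hyp.duration_min:
            censored_at_total = False
        lzc[cond][subj] = lzc_sequence(hyp.states)
    subjects = sorted(lzc["control"])
    c = np.array([lzc["control"][s] for s in subjects], float)
    t = np.array([lzc["trazodone"][s] for s in subjects], float)
    res = paired_wilcoxon(c, t)
    return {
        "rem_absent": absent,
        "censored_at_total": censored_at_total,
        "lzc_p": res.p_value,
        "lzc_lower_in_trazodone": float(np.median(c - t)) > 0,
    }


def effect_replicate(cfg_effect, seed):
    """Full drug-signature analysis of one effect cohort."""
    sessions = gen_cohort(cfg_effect)
    n_sessions = cfg_effect.n_subjects
    hyp = hypnogram_stats(sessions)
    epochs = prepare_epochs(sessions, seed)

    res = nrem_rpsd_comparison(epochs, alpha=0.01)
    high = res[(res["freq_hz"] >= 15) & (res["freq_hz"] <= 40)]
    low = res[(res["freq_hz"] >= 3) & (res["freq_hz"] <= 8)]

    bands = {k: PLI_BANDS[k] for k in ("alpha", "delta")}
    dp = delta_pli(_state_sets(epochs, "control", NREM),
                   _state_sets(epochs, "trazodone", NREM),
                   FS, bands, n_surrogates=100, seed=seed)
    alpha_flags = dp["alpha"].flags.set_index("edge")
    return {
        **hyp,
        "rem_absent_frac_trazodone": hyp["rem_absent"]["trazodone"]
        / n_sessions,
        "rem_absent_frac_control": hyp["rem_absent"]["control"] / n_sessions,
        "high_band_flag_frac": float(high["significant"].mean()),
        "low_band_flags": int(low["significant"].sum()),
        "alpha_edge_flagged": bool(alpha_flags.loc["Fz-Cz", "flagged"]),
        "alpha_edge_direction": alpha_flags.loc["Fz-Cz", "direction"],
        "delta_band_flags": int(dp["delta"].flags["flagged"].sum()),
    }


def null_replicate(cfg_null, seed):
    """Type-I / false-positive analysis of one matched null cohort."""
    sessions = gen_cohort(cfg_null)
    hyp = hypnogram_stats(sessions)
    epochs = prepare_epochs(sessions, seed)

    res = nrem_rpsd_comparison(epochs, alpha=0.05)
    pe_cfg = PEConfig(4, 1)
    pe = {"control": [], "trazodone": []}
    for (subj, cond), sets in epochs.items():
        if NREM in sets:
            filt = bandpass(sets[NREM].data, FS, 1.0, 16.0)
            pe[cond].append(float(np.mean(
                [[permutation_entropy(filt[e, c], pe_cfg)
                  for c in range(filt.shape[1])]
                 for e in range(filt.shape[0])])))
    pe_p = mann_whitney(pe["control"], pe["trazodone"]).p_value

    dp = delta_pli(_state_sets(epochs, "control", NREM),
                   _state_sets(epochs, "trazodone", NREM),
                   FS, PLI_BANDS, n_surrogates=100, seed=seed)
    false_edges = sum(int(v.flags["flagged"].sum()) for v in dp.values())
    return {
        "lzc_p": hyp["lzc_p"],
        "pe_p": pe_p,
        "spectral_flag_frac": float(res["significant"].mean()),
        "false_edges_per_30": false_edges,
    }
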