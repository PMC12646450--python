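"""End-to-end study analysis: orchestrates io -> preprocess -> hypnogram ->
spectral -> complexity -> connectivity over a session manifest, writing
plain TSV tables (plus a JSON run summary) to an output directory.

Stage contract: ``run_all`` executes every stage in order; ``run_stage``
runs one stage, erroring with the name of any missing upstream stage.
Given identical inputs, configuration and seed, every output is
byte-identical across reruns. Within-subject comparisons are paired
(Wilcoxon) for wakefulness and drowsiness; NREM and REM comparisons are
unpaired (Mann-Whitney) because sessions may lack those states — a
session missing a state is dropped from that state's comparisons and the
degradation is logged, mirroring how the study handled dogs that never
reached REM under trazodone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .complexity import BandSplit, PEConfig, cohort_band_metrics, state_comparison
from .connectivity import delta_pli, pli_state_matrix
from .hypnogram import (architecture_table, compare_architecture,
                        summarize_architecture, transition_table)
from .io import (EEG_CHANNELS, EpochSet, N_STATES, STATE_NAMES, load_hypnogram,
                 load_manifest, load_recording, segment_epochs)
from .preprocess import (PLI_BANDS, bandpass, epoch_quality_summary, notch,
                         sample_clean_epochs)
from .spectral import (coherence_all_pairs, compare_bins, rpsd)
from .stats import mann_whitney, paired_wilcoxon

logger = logging.getLogger(__name__)

#: paired test usable per state (False -> Mann-Whitney fallback)
STATE_PAIRED = {0: True, 1: True, 2: False, 3: False}

STAGES = ("preprocess", "hypnogram", "spectral", "complexity", "connectivity")


@dataclass
class PipelineConfig:
    manifest_path: Path
    output_dir: Path
    seed: int = 0
    bandpass_hz: tuple[float, float] = (1.0, 70.0)
    notch_hz: float = 60.0
    epochs_per_state: int = 5
    pe_dimension: int = 4
    pe_delay: int = 1
    band_split: tuple[tuple[float, float], tuple[float, float]] = \
        ((1.0, 16.0), (17.0, 50.0))
    n_surrogates: int = 100
    alpha_rpsd: float = 0.01
    alpha_coherence: float = 0.05
    alpha: float = 0.05
    threshold_scope: str = "pooled"
    make_plots: bool = False

    def __post_init__(self) -> None:
        self.manifest_path = Path(self.manifest_path)
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {f.name: str(getattr(self, f.name))
                   for f in dataclasses.fields(self)}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _metadata_line(cfg: PipelineConfig) -> str:
    return (f"# canisleep {__version__} seed={cfg.seed} "
            f"config={cfg.config_hash()}")


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_line(cfg) + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n",
                  float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline output table, skipping the metadata header."""
    return pd.read_csv(path, sep="\t", comment="#")


def _epochs_dir(cfg: PipelineConfig) -> Path:
    return cfg.output_dir / "epochs"


def _require(cfg: PipelineConfig, path: Path, upstream: str) -> None:
    if not path.exists():
        raise FileNotFoundError(
            f"missing output {path.name}: run the '{upstream}' stage first")


def _sessions(cfg: PipelineConfig):
    manifest = load_manifest(cfg.manifest_path)
    base = cfg.manifest_path.parent
    for row in manifest.sessions():
        yield (row.subject_id, row.condition,
               base / row.recording_path, base / row.hypnogram_path)


# ---------------------------------------------------------------------------
# Stage: preprocess — filter, epoch, sample clean epochs per state
# ---------------------------------------------------------------------------

def stage_preprocess(cfg: PipelineConfig) -> None:
    out = _epochs_dir(cfg)
    out.mkdir(parents=True, exist_ok=True)
    quality_rows = []
    for subject, cond, rec_path, hyp_path in _sessions(cfg):
        rec = load_recording(rec_path, EEG_CHANNELS, subject, cond)
        hyp = load_hypnogram(hyp_path)
        filt = notch(bandpass(rec.signal, rec.sampling_rate_hz,
                              *cfg.bandpass_hz),
                     rec.sampling_rate_hz, cfg.notch_hz)
        rec.signal = filt
        seg = segment_epochs(rec, hyp)
        selected = sample_clean_epochs(
            seg.by_state(), cfg.epochs_per_state,
            seed=int(hashlib.sha256(
                f"{cfg.seed}|{subject}|{cond}".encode()).digest()[0:4].hex(), 16))
        arrays = {"fs": np.array(rec.sampling_rate_hz)}
        for state, es in selected.items():
            arrays[f"state_{state}"] = es.data
            arrays[f"indices_{state}"] = es.source_indices
        np.savez(out / f"{subject}_{cond}.npz", **arrays)
        q = epoch_quality_summary(hyp)
        q.insert(0, "condition", cond)
        q.insert(0, "subject_id", subject)
        quality_rows.append(q)
    _write_tsv(pd.concat(quality_rows, ignore_index=True),
               cfg.output_dir / "epoch_quality.tsv", cfg)


def _load_epochs(cfg: PipelineConfig
                 ) -> dict[tuple[str, str], dict[int, EpochSet]]:
    out = {}
    fs = None
    for subject, cond, _, _ in _sessions(cfg):
        path = _epochs_dir(cfg) / f"{subject}_{cond}.npz"
        _require(cfg, path, "preprocess")
        with np.load(path) as npz:
            fs = float(npz["fs"])
            sets = {}
            for state in range(N_STATES):
                key = f"state_{state}"
                if key in npz:
                    sets[state] = EpochSet(state=state, data=npz[key],
                                           source_indices=npz[f"indices_{state}"])
        out[(subject, cond)] = sets
    out["fs"] = fs
    return out


# ---------------------------------------------------------------------------
# Stage: hypnogram — architecture metrics and paired tests (EEG-free)
# ---------------------------------------------------------------------------

def stage_hypnogram(cfg: PipelineConfig) -> None:
    summaries: dict[str, dict] = {}
    for subject, cond, _, hyp_path in _sessions(cfg):
        hyp = load_hypnogram(hyp_path)
        summaries.setdefault(cond, {})[subject] = summarize_architecture(hyp)
    _write_tsv(architecture_table(summaries),
               cfg.output_dir / "architecture_summary.tsv", cfg)
    _write_tsv(transition_table(summaries),
               cfg.output_dir / "transition_matrices.tsv", cfg)
    if {"control", "trazodone"} <= set(summaries):
        tests = compare_architecture(summaries["control"],
                                     summaries["trazodone"])
        _write_tsv(tests, cfg.output_dir / "architecture_tests.tsv", cfg)


# ---------------------------------------------------------------------------
# Stage: spectral — rPSD and coherence with per-bin group tests
# ---------------------------------------------------------------------------

def _per_state_groups(values: dict, state: int):
    """Split per-(subject, condition) values into aligned/unaligned groups
    for one state; returns (control, trazodone, paired, subjects)."""
    ctrl, traz = {}, {}
    for (subject, cond), v in values.items():
        if v is None:
            continue
        (ctrl if cond == "control" else traz)[subject] = v
    paired = STATE_PAIRED[state]
    if paired:
        common = sorted(set(ctrl) & set(traz))
        dropped = sorted((set(ctrl) | set(traz)) - set(common))
        if dropped:
            logger.warning("state %s: subjects %s incomplete; dropped from "
                           "paired comparison", STATE_NAMES[state], dropped)
        a = [ctrl[s] for s in common]
        b = [traz[s] for s in common]
    else:
        a = [ctrl[s] for s in sorted(ctrl)]
        b = [traz[s] for s in sorted(traz)]
    return a, b, paired


def stage_spectral(cfg: PipelineConfig) -> None:
    epochs = _load_epochs(cfg)
    fs = epochs.pop("fs")
    rpsd_rows, coh_rows = [], []
    rpsd_by_state: dict[int, dict] = {s: {} for s in range(N_STATES)}
    coh_by_state: dict[int, dict] = {s: {} for s in range(N_STATES)}
    freqs = None
    coh_freqs = None
    for (subject, cond), sets in epochs.items():
        for state in range(N_STATES):
            if state not in sets:
                rpsd_by_state[state][(subject, cond)] = None
                coh_by_state[state][(subject, cond)] = None
                continue
            sp = rpsd(sets[state], fs)
            freqs = sp.freqs_hz
            rpsd_by_state[state][(subject, cond)] = sp.channel_mean()
            for ch, row in zip(EEG_CHANNELS, sp.rpsd):
                for f, v in zip(sp.freqs_hz, row):
                    rpsd_rows.append((subject, cond, STATE_NAMES[state],
                                      ch, f, v))
            cs = coherence_all_pairs(sets[state], fs, EEG_CHANNELS)
            coh_freqs = cs.freqs_hz
            coh_by_state[state][(subject, cond)] = cs.coh
            for (ci, cj), vals in cs.coh.items():
                for f, v in zip(cs.freqs_hz, vals):
                    coh_rows.append((subject, cond, STATE_NAMES[state],
                                     f"{ci}-{cj}", f, v))
    _write_tsv(pd.DataFrame(rpsd_rows, columns=[
        "subject_id", "condition", "state", "channel", "freq_hz", "rpsd"]),
        cfg.output_dir / "rpsd.tsv", cfg)
    _write_tsv(pd.DataFrame(coh_rows, columns=[
        "subject_id", "condition", "state", "pair", "freq_hz", "coherence"]),
        cfg.output_dir / "coherence.tsv", cfg)

    test_rows, coh_test_rows = [], []
    for state in range(N_STATES):
        a, b, paired = _per_state_groups(rpsd_by_state[state], state)
        if len(a) >= 2 and len(b) >= 2 and freqs is not None:
            res = compare_bins(np.vstack(a), np.vstack(b), freqs,
                               paired=paired, alpha=cfg.alpha_rpsd)
            res.insert(0, "state", STATE_NAMES[state])
            res["paired"] = paired
            test_rows.append(res)
        ca, cb, cpaired = _per_state_groups(coh_by_state[state], state)
        if len(ca) >= 2 and len(cb) >= 2 and coh_freqs is not None:
            for pair in ca[0]:
                pa = np.vstack([d[pair] for d in ca])
                pb = np.vstack([d[pair] for d in cb])
                res = compare_bins(pa, pb, coh_freqs, paired=cpaired,
                                   alpha=cfg.alpha_coherence)
                res.insert(0, "pair", f"{pair[0]}-{pair[1]}")
                res.insert(0, "state", STATE_NAMES[state])
                res["paired"] = cpaired
                coh_test_rows.append(res)
    if test_rows:
        _write_tsv(pd.concat(test_rows, ignore_index=True),
                   cfg.output_dir / "spectral_tests.tsv", cfg)
    if coh_test_rows:
        _write_tsv(pd.concat(coh_test_rows, ignore_index=True),
                   cfg.output_dir / "coherence_tests.tsv", cfg)


# ---------------------------------------------------------------------------
# Stage: complexity — nonlinear metrics, condition and state comparisons
# ---------------------------------------------------------------------------

def stage_complexity(cfg: PipelineConfig) -> None:
    epochs = _load_epochs(cfg)
    fs = epochs.pop("fs")
    split = BandSplit(*cfg.band_split)
    pe_cfg = PEConfig(cfg.pe_dimension, cfg.pe_delay)
    frames = []
    for (subject, cond), sets in epochs.items():
        df = cohort_band_metrics(sets, fs, split, pe_cfg)
        df.insert(0, "condition", cond)
        df.insert(0, "subject_id", subject)
        frames.append(df)
    metrics = pd.concat(frames, ignore_index=True)
    _write_tsv(metrics, cfg.output_dir / "nonlinear_metrics.tsv", cfg)

    test_rows = []
    for (state, band, metric), sub in metrics.groupby(["state", "band",
                                                       "metric"]):
        state_code = {v: k for k, v in STATE_NAMES.items()}[state]
        pivot = sub.pivot_table(index="subject_id", columns="condition",
                                values="value")
        if "control" not in pivot or "trazodone" not in pivot:
            continue
        if STATE_PAIRED[state_code]:
            both = pivot.dropna()
            if len(both) < 2:
                continue
            res = paired_wilcoxon(both["control"], both["trazodone"])
        else:
            x = pivot["control"].dropna()
            y = pivot["trazodone"].dropna()
            if len(x) < 2 or len(y) < 2:
                continue
            res = mann_whitney(x, y)
        test_rows.append((state, band, metric, res.method, res.statistic,
                          res.p_value, res.n_used, res.paired))
    _write_tsv(pd.DataFrame(test_rows, columns=[
        "state", "band", "metric", "method", "statistic", "p_value",
        "n_used", "paired"]),
        cfg.output_dir / "nonlinear_tests.tsv", cfg)

    cmp_rows = []
    for cond in sorted(metrics["condition"].unique()):
        for band in ("low", "high"):
            for metric in ("lzc", "pe"):
                try:
                    omnibus, mat = state_comparison(metrics, metric, band, cond)
                except ValueError:
                    continue
                for s1 in mat.index:
                    for s2 in mat.columns:
                        if s1 < s2:
                            cmp_rows.append((cond, band, metric,
                                             f"{s1}-{s2}",
                                             omnibus.p_value,
                                             mat.loc[s1, s2]))
    _write_tsv(pd.DataFrame(cmp_rows, columns=[
        "condition", "band", "metric", "state_pair", "omnibus_p",
        "adjusted_p"]),
        cfg.output_dir / "state_comparisons.tsv", cfg)


# ---------------------------------------------------------------------------
# Stage: connectivity — PLI matrices and surrogate-thresholded differences
# ---------------------------------------------------------------------------

def stage_connectivity(cfg: PipelineConfig) -> None:
    epochs = _load_epochs(cfg)
    fs = epochs.pop("fs")
    pli_rows = []
    by_state: dict[int, dict[str, dict]] = {
        s: {"control": {}, "trazodone": {}} for s in range(N_STATES)}
    for (subject, cond), sets in epochs.items():
        for state, es in sets.items():
            mats = pli_state_matrix(es, fs)
            by_state[state][cond][subject] = es
            for band, mat in mats.items():
                for i in range(len(EEG_CHANNELS)):
                    for j in range(i + 1, len(EEG_CHANNELS)):
                        pli_rows.append((subject, cond, STATE_NAMES[state],
                                         band,
                                         EEG_CHANNELS[i], EEG_CHANNELS[j],
                                         mat[i, j]))
    _write_tsv(pd.DataFrame(pli_rows, columns=[
        "subject_id", "condition", "state", "band", "ch_i", "ch_j", "pli"]),
        cfg.output_dir / "pli_matrices.tsv", cfg)

    delta_rows = []
    for state in range(N_STATES):
        ctrl = by_state[state]["control"]
        traz = by_state[state]["trazodone"]
        if len(set(ctrl) & set(traz)) < 2:
            logger.warning("state %s: fewer than 2 complete pairs; "
                           "delta-PLI skipped", STATE_NAMES[state])
            continue
        results = delta_pli(ctrl, traz, fs, PLI_BANDS, EEG_CHANNELS,
                            n_surrogates=cfg.n_surrogates, seed=cfg.seed,
                            threshold_scope=cfg.threshold_scope)
        for band, res in results.items():
            flags = res.flags.copy()
            flags.insert(0, "band", band)
            flags.insert(0, "state", STATE_NAMES[state])
            flags["n_subjects"] = res.n_subjects
            delta_rows.append(flags)
    if delta_rows:
        _write_tsv(pd.concat(delta_rows, ignore_index=True),
                   cfg.output_dir / "delta_pli.tsv", cfg)


_STAGE_FUNCS = {
    "preprocess": stage_preprocess,
    "hypnogram": stage_hypnogram,
    "spectral": stage_spectral,
    "complexity": stage_complexity,
    "connectivity": stage_connectivity,
}


def run_stage(name: str, cfg: PipelineConfig) -> None:
    """Run a single pipeline stage (idempotent; errors name any missing
    upstream stage)."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    logger.info("running stage %s", name)
    _STAGE_FUNCS[name](cfg)


def run_all(cfg: PipelineConfig) -> None:
    """Run the full analysis; writes all tables plus run_info.json."""
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    for name in STAGES:
        try:
            run_stage(name, cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    info = {"version": __version__, "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "stages": list(STAGES)}
    with open(cfg.output_dir / "run_info.json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if cfg.make_plots:
        from .plots import make_summary_plots
        make_summary_plots(cfg)
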