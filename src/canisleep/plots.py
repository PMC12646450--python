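"""Optional summary figures (hypnogram raster, rPSD overlays with
significance shading, delta-PLI edge maps). Purely cosmetic: no analysis
result depends on these."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .io import STATE_NAMES, load_hypnogram, load_manifest  # noqa: E402
from .pipeline import PipelineConfig, read_table  # noqa: E402


def plot_hypnograms(cfg: PipelineConfig, outdir: Path) -> None:
    manifest = load_manifest(cfg.manifest_path)
    base = cfg.manifest_path.parent
    for row in manifest.sessions():
        hyp = load_hypnogram(base / row.hypnogram_path)
        t = np.arange(len(hyp)) * hyp.epoch_length_s / 60.0
        fig, ax = plt.subplots(figsize=(8, 2))
        ax.step(t, hyp.states, where="post", lw=0.8)
        ax.set_yticks(range(4), [STATE_NAMES[s] for s in range(4)])
        ax.set_xlabel("time (min)")
        ax.set_title(f"{row.subject_id} / {row.condition}")
        ax.invert_yaxis()
        fig.tight_layout()
        fig.savefig(outdir / f"hypnogram_{row.subject_id}_{row.condition}.png",
                    dpi=100)
        plt.close(fig)


def plot_rpsd(cfg: PipelineConfig, outdir: Path) -> None:
    rpsd_path = cfg.output_dir / "rpsd.tsv"
    tests_path = cfg.output_dir / "spectral_tests.tsv"
    if not rpsd_path.exists():
        return
    df = read_table(rpsd_path)
    tests = read_table(tests_path) if tests_path.exists() else None
    for state, sub in df.groupby("state"):
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for cond, csub in sub.groupby("condition"):
            mean = csub.groupby("freq_hz")["rpsd"].mean()
            ax.plot(mean.index, mean.values, label=cond)
        if tests is not None:
            sig = tests[(tests["state"] == state) & tests["significant"]]
            for f in sig["freq_hz"]:
                ax.axvspan(f - 0.6, f + 0.6, color="0.85", zorder=0)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("rPSD")
        ax.set_title(f"rPSD - {state}")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / f"rpsd_{state}.png", dpi=100)
        plt.close(fig)


def plot_delta_pli(cfg: PipelineConfig, outdir: Path) -> None:
    path = cfg.output_dir / "delta_pli.tsv"
    if not path.exists():
        return
    df = read_table(path)
    for (state, band), sub in df.groupby(["state", "band"]):
        fig, ax = plt.subplots(figsize=(3.5, 3))
        colors = ["tab:green" if f else "0.85" for f in sub["flagged"]]
        ax.barh(sub["edge"], sub["delta"].abs(), color=colors)
        for y, th in enumerate(sub["threshold"]):
            ax.plot([th, th], [y - 0.4, y + 0.4], "k--", lw=0.8)
        ax.set_xlabel("|dPLI| (dashed: threshold)")
        ax.set_title(f"{state} / {band}")
        fig.tight_layout()
        fig.savefig(outdir / f"delta_pli_{state}_{band}.png", dpi=100)
        plt.close(fig)


def make_summary_plots(cfg: PipelineConfig) -> None:
    outdir = cfg.output_dir / "plots"
    outdir.mkdir(parents=True, exist_ok=True)
    plot_hypnograms(cfg, outdir)
    plot_rpsd(cfg, outdir)
    plot_delta_pli(cfg, outdir)
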