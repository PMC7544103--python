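"""Standard figures: r histograms, slope fans, subject panels, Bland-Altman."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def r_histograms(result, path: Path) -> None:
    fits = [f for s in result.subjects for f in s.fits]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, pred, label in zip(
        axes, ("ptt_ra_av", "hr_av"), ("SBP_AV vs PTT-RA_AV", "SBP_AV vs HR_AV")
    ):
        r = [f.pearson_r for f in fits if f.predictor == pred and not f.degenerate]
        ax.hist(r, bins=np.linspace(-1, 1, 21), color="0.3")
        ax.set_xlabel("Pearson r")
        ax.set_title(label, fontsize=9)
    axes[0].set_ylabel("subjects")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def slope_lines(result, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for s in result.subjects:
        for f in s.fits:
            if f.predictor != "ptt_ra_av" or f.degenerate:
                continue
            x = np.array([-20.0, 20.0])
            ax.plot(x, f.slope * x, color="k", alpha=0.25, lw=0.8)
    ax.set_xlabel("PTT-RA_AV change (ms)")
    ax.set_ylabel("fitted SBP_AV change (mmHg)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def subject_panel(result, path: Path) -> None:
    """Time series + regression panels for the subject nearest the median r."""
    cands = [
        (s, f)
        for s in result.subjects
        for f in s.fits
        if f.predictor == "ptt_ra_av" and not f.degenerate
    ]
    if not cands:
        return
    med = np.median([f.pearson_r for _, f in cands])
    s, f = min(cands, key=lambda sf: abs(sf[1].pearson_r - med))
    seg = s.primary
    av = s.averaged
    span = av[(av["beat_index"] >= seg.start_beat) & (av["beat_index"] <= seg.end_beat)]
    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    axes[0, 0].plot(span["time_s"], span["sbp_av"], "k", lw=0.9)
    axes[0, 0].set_ylabel("SBP_AV (mmHg)")
    axes[0, 1].plot(span["time_s"], span["ptt_ra_av"], "k", lw=0.9)
    axes[0, 1].set_ylabel("PTT-RA_AV (ms)")
    axes[1, 0].scatter(span["ptt_ra_av"], span["sbp_av"], s=4, color="0.2")
    xs = np.array([span["ptt_ra_av"].min(), span["ptt_ra_av"].max()])
    axes[1, 0].plot(xs, f.slope * xs + f.intercept, "r", lw=1)
    axes[1, 0].set_xlabel("PTT-RA_AV (ms)")
    axes[1, 0].set_ylabel("SBP_AV (mmHg)")
    axes[1, 1].plot(span["time_s"], span["hr_av"], "k", lw=0.9)
    axes[1, 1].set_ylabel("HR_AV (bpm)")
    for ax in axes.flat:
        ax.tick_params(labelsize=8)
    fig.suptitle(f"subject {s.subject_id} (r={f.pearson_r:.2f})", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def bland_altman_plot(result, path: Path) -> None:
    pairs = [
        (s.fits[0].slope, s.secondary_fit.slope)
        for s in result.subjects
        if s.secondary_fit is not None and s.fits and not s.fits[0].degenerate
    ]
    if len(pairs) < 2 or result.bland_altman is None:
        return
    arr = np.asarray(pairs)
    mean = arr.mean(axis=1)
    diff = arr[:, 0] - arr[:, 1]
    ba = result.bland_altman
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=8, color="0.2")
    for y, style in ((ba["mean_bias"], "-"), (ba["loa_low"], "--"), (ba["loa_high"], "--")):
        ax.axhline(y, color="r", ls=style, lw=0.9)
    ax.set_xlabel("mean slope of the two events (mmHg/ms)")
    ax.set_ylabel("slope difference, primary - secondary (mmHg/ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def make_all_figures(result, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    r_histograms(result, out_dir / "fig_r_histograms.png")
    slope_lines(result, out_dir / "fig_slopes.png")
    subject_panel(result, out_dir / "fig_subject_panel.png")
    bland_altman_plot(result, out_dir / "fig_bland_altman.png")
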