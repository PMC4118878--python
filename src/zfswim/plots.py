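"""Diagnostic figures: curvature heatmaps, tail-offset traces, spectra."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_group_profiles(summaries: dict, outdir: str | Path) -> list[Path]:
    """One curvature heatmap per group plus an overlaid tail-offset figure.

    The heatmap mirrors the standard presentation: body location on the
    vertical axis (head at the top), normalized cycle frame on the
    horizontal, warmer colors = stronger bending.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    vmax = max(float(s.mean_profile.max()) for s in summaries.values()) or 1.0
    for group, s in summaries.items():
        fig, ax = plt.subplots(figsize=(5, 3.2))
        im = ax.imshow(s.mean_profile, aspect="auto", cmap="jet", vmin=0, vmax=vmax)
        ax.set_xlabel("normalized cycle frame")
        ax.set_ylabel("body location (head = 0)")
        ax.set_title(f"mean body curvature: {group} (n={s.n_cycles} cycles)")
        fig.colorbar(im, ax=ax, label="curvature (deg)")
        p = outdir / f"curvature_profile_{group}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for group, s in summaries.items():
        ax.plot(s.mean_offset_profile, label=group)
    ax.set_xlabel("normalized cycle frame")
    ax.set_ylabel("tail offset T/L")
    ax.set_title("mean tail-offset profile per group")
    ax.legend()
    p = outdir / "tail_offset_profiles.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)
    return written


def plot_spectrum(series: np.ndarray, out: str | Path, label: str = "series") -> Path:
    """Fourier magnitude of a kinematic series, for cutoff inspection.

    This is the figure one looks at to choose the low-pass cutoffs: the
    signal band should sit left of the cutoff, broadband noise right.
    """
    series = np.asarray(series, float)
    mag = np.abs(np.fft.rfft(series - series.mean()))
    freq = np.fft.rfftfreq(len(series))  # cycles/sample; Nyquist = 0.5
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(freq, mag)
    ax.set_xlabel("normalized frequency (cycles/sample)")
    ax.set_ylabel("|FFT|")
    ax.set_title(f"magnitude spectrum: {label}")
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out
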