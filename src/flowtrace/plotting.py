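"""Diagnostic figures: TAC waterfalls and delay-versus-distance plots."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_SEG_COLORS = {"proximal": "tab:red", "thrombus": "tab:green",
               "mother": "tab:blue"}


def _seg_color(seg_id):
    if seg_id in _SEG_COLORS:
        return _SEG_COLORS[seg_id]
    palette = ["tab:cyan", "tab:purple", "tab:orange", "tab:pink",
               "tab:olive"]
    if seg_id.startswith("daughter"):
        try:
            return palette[(int(seg_id[8:]) - 1) % len(palette)]
        except ValueError:
            pass
    return "tab:gray"


def plot_tac_waterfall(tacs_df, path_id, ax=None, offset_hu=None):
    """Stacked conditioned TACs of one path, ordered by arc-length.

    Each curve is vertically offset in proportion to its position along
    the path, so the bolus front is visible as a diagonal ridge.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    sub = tacs_df[tacs_df.path_id == path_id]
    if sub.empty:
        raise ValueError(f"no TACs for path {path_id!r}")
    if offset_hu is None:
        offset_hu = 0.15 * sub.value_hu.max()
    arcs = sorted(sub.arclength_mm.unique())
    for n, arc in enumerate(arcs):
        one = sub[sub.arclength_mm == arc]
        ax.plot(one.time_s, one.value_hu + n * offset_hu,
                color=_seg_color(one.segment_id.iloc[0]), lw=0.8)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("attenuation + offset [HU]")
    ax.set_title(f"{path_id}: TACs along the centerline")
    return ax


def plot_delay_profile(delays_df, segments, ax=None):
    """Delay vs distance with the fitted per-segment regression lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    valid = delays_df[delays_df.valid.astype(bool)]
    for seg_id, sub in valid.groupby("segment_id"):
        ax.plot(sub.arclength_mm, sub.delay_s, ".",
                color=_seg_color(seg_id), label=seg_id)
        flow = segments.get(seg_id)
        if flow and flow.get("slope_s_per_mm") is not None:
            x = sub.arclength_mm
            slope = flow["slope_s_per_mm"]
            y0 = sub.delay_s.mean() - slope * x.mean()
            ax.plot([x.min(), x.max()],
                    [y0 + slope * x.min(), y0 + slope * x.max()],
                    color=_seg_color(seg_id), lw=1.5)
    ax.set_xlabel("distance from proximal marker [mm]")
    ax.set_ylabel("time delay [s]")
    ax.legend(fontsize=8)
    return ax


def plot_results(results_dir, out_dir=None):
    """Render the standard figures for a pipeline result bundle."""
    import json

    import pandas as pd

    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir else results_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    delays = pd.read_csv(results_dir / "delays.csv")
    tacs = pd.read_csv(results_dir / "tacs.csv")
    with open(results_dir / "segments.json") as fh:
        segments = json.load(fh)
    written = []
    for path_id in sorted(delays.path_id.unique()):
        fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
        plot_tac_waterfall(tacs, path_id, ax=axes[0])
        plot_delay_profile(delays[delays.path_id == path_id], segments,
                           ax=axes[1])
        fig.tight_layout()
        out = out_dir / f"{path_id}.png"
        fig.savefig(out, dpi=110)
        plt.close(fig)
        written.append(out)
    return written
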