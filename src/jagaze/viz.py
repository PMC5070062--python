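"""Minimal plotting: a grouped bar summary of fixation-duration percentages."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_fd_summary(fd_summary: pd.DataFrame, ax=None):
    """Bar chart of FD% group means per task and AOI (face, target,
    non-target), with SD whiskers.  Returns the matplotlib Axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    aois = ["fd_face", "fd_target", "fd_nontarget"]
    tasks = list(dict.fromkeys(fd_summary["task"]))
    width = 0.35
    centers, labels = [], []
    pos = 0.0
    for task in tasks:
        for aoi in aois:
            for k, group in enumerate(("ASD", "TD")):
                row = fd_summary[
                    (fd_summary["task"] == task) & (fd_summary["group"] == group)
                ]
                if row.empty:
                    continue
                mean = float(row[f"{aoi}_mean"].iloc[0])
                sd = float(row[f"{aoi}_sd"].iloc[0])
                ax.bar(
                    pos + k * width, mean, width,
                    yerr=sd if np.isfinite(sd) else None,
                    color="#c44" if group == "ASD" else "#46a",
                    label=group if (task == tasks[0] and aoi == aois[0]) else None,
                )
            centers.append(pos + width / 2)
            labels.append(f"{task}\n{aoi.removeprefix('fd_')}")
            pos += 1.0
        pos += 0.5
    ax.set_xticks(centers)
    ax.set_xticklabels(labels, fontsize=8)
    ax.set_ylabel("fixation duration (% of on-trial FD)")
    ax.legend(frameon=False)
    return ax
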