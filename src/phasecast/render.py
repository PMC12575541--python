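"""Anticipation-timeline rendering.

Draws the two-axis view used to inspect anticipation models online: the
x-axis is the current elapsed time of the procedure, the y-axis the future
horizon in minutes; each column shows the phase sequence the model
predicts from that moment.  Phases are coloured categorically, the
end-of-surgery class is grey, and the ground-truth phase band is drawn
underneath for reference.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .timelines import PhaseTimeline, PhaseVocabulary

__all__ = ["phase_colormap", "render_anticipation_timeline"]

_PALETTE = ["#e6742c", "#4ba352", "#3b7bb8", "#c94078", "#8a62c9",
            "#b8a431", "#45b5b0", "#d05a5a", "#6b8e23", "#9467bd"]


def phase_colormap(vocabulary: PhaseVocabulary) -> ListedColormap:
    """Categorical colours per phase; EOS (last index) is grey."""
    colors = [_PALETTE[i % len(_PALETTE)]
              for i in range(vocabulary.eos_index)] + ["#9e9e9e"]
    return ListedColormap(colors)


def render_anticipation_timeline(pred_grid: np.ndarray,
                                 probe_times: Sequence[int],
                                 timeline: PhaseTimeline,
                                 out_path: str | Path,
                                 title: str | None = None) -> Path:
    """Save the anticipation timeline figure (SVG or PNG by extension).

    ``pred_grid[k]`` is the length-N predicted label sequence issued at
    ``probe_times[k]`` seconds; column k of the image therefore shows what
    the model expected the next N minutes to look like at that moment.
    """
    pred_grid = np.asarray(pred_grid)
    probe_times = np.asarray(probe_times)
    if pred_grid.ndim != 2 or pred_grid.shape[0] != probe_times.size:
        raise ValueError("need one predicted sequence per probe time")
    voc = timeline.vocabulary
    cmap = phase_colormap(voc)
    n = pred_grid.shape[1]
    fig, (ax_pred, ax_gt) = plt.subplots(
        2, 1, figsize=(9, 4.2), height_ratios=[5, 1], sharex=True,
        constrained_layout=True)
    ax_pred.imshow(pred_grid.T, aspect="auto", origin="lower",
                   interpolation="nearest", cmap=cmap,
                   vmin=-0.5, vmax=voc.size - 0.5,
                   extent=(probe_times[0] / 60.0, probe_times[-1] / 60.0,
                           0.5, n + 0.5))
    ax_pred.set_ylabel("anticipated minutes ahead")
    ax_pred.set_title(title or f"anticipation timeline: {timeline.video_id}")
    ax_gt.imshow(timeline.labels[None, :], aspect="auto",
                 interpolation="nearest", cmap=cmap,
                 vmin=-0.5, vmax=voc.size - 0.5,
                 extent=(0.0, len(timeline) / 60.0, 0, 1))
    ax_gt.set_yticks([])
    ax_gt.set_ylabel("truth", rotation=0, ha="right", va="center")
    ax_gt.set_xlabel("elapsed time (min)")
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
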