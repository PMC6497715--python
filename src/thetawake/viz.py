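"""Diagnostic plots (optional; requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .events import DetectionParams, compute_threshold, theta_filter
from .types import EventRecord, Montage, Recording


def plot_detection(
    rec: Recording,
    area: tuple[str, ...],
    events: list[EventRecord],
    p: DetectionParams = DetectionParams(),
    t_range: tuple[float, float] | None = None,
    ax=None,
):
    """Reference trace with the detection threshold and marked troughs."""
    import matplotlib.pyplot as plt

    idx = [rec.labels.index(l) for l in area]
    refsig = theta_filter(rec.data[idx].mean(axis=0), rec.fs, p)
    thr = compute_threshold(refsig, p, mask=rec.artifact_mask)
    t = rec.times
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    sel = slice(None)
    if t_range is not None:
        sel = slice(int(t_range[0] * rec.fs), int(t_range[1] * rec.fs))
    ax.plot(t[sel], refsig[sel], lw=0.7, color="k")
    ax.axhline(thr, color="r", lw=1, label=f"threshold {thr:.2f}")
    ev_t = [e.t_neg for e in events if t_range is None or t_range[0] <= e.t_neg < t_range[1]]
    ax.plot(ev_t, np.interp(ev_t, t, refsig), "o", ms=4, mfc="none", mec="r")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("reference (z)")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_topography(values, montage: Montage, ax=None, cmap="RdBu_r", mask=None):
    """Simple 2-D scalp scatter of per-channel values."""
    import matplotlib.pyplot as plt

    xy = np.stack([montage.pos2d[l] for l in montage.labels])
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=values, s=120, cmap=cmap, edgecolors="k")
    if mask is not None:
        ax.scatter(xy[mask, 0], xy[mask, 1], c="white", s=12, zorder=3)
    ax.set_aspect("equal")
    ax.axis("off")
    plt.colorbar(sc, ax=ax, shrink=0.7)
    return ax
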