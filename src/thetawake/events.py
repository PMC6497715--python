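"""Detection of local sleep-like events during wakefulness.

Pipeline per scalp area (frontal / central / parietal):

1. average the area's channels and band-pass the mean in the theta band
   (5-7 Hz, 2nd-order Butterworth, zero-phase) -> the *reference signal*;
2. set a robust threshold at ``median - 2 x median absolute deviation``
   of the reference signal (negative, one-sided: the detector targets
   negative troughs);
3. find candidate troughs: the interior minimum between two consecutive
   local maxima whose separation lies in the theta period range, kept
   when it undershoots the threshold;
4. mark *involved* channels by the maximum lagged Pearson correlation
   (lags up to +-50 ms, the plausible theta travel delay) between the
   reference's trough segment and each channel's theta-filtered trace,
   at r > 0.95; prune involved channels with no involved neighbor
   (isolated channels are likely artifacts);
5. measure the trough-to-following-peak amplitude at the involved
   channel with the median slope, and the event's globality as the
   percentage of analyzed channels involved.

Density is reported as events per minute of usable signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .types import EventRecord, Montage, Recording

__all__ = [
    "AreaSet",
    "DetectionParams",
    "DEFAULT_AREAS",
    "theta_filter",
    "area_reference",
    "compute_threshold",
    "detect_negative_peaks",
    "event_involvement",
    "event_amplitude",
    "detect_all",
]

logger = logging.getLogger(__name__)

#: Anterior-posterior detection areas (published electrode lists).  The
#: central list shares CPz/CP2 with the parietal list as printed; see
#: ``AreaSet.default``.
DEFAULT_AREAS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "AF3", "AFz", "AF4", "F1", "Fz", "F2"),
    "central": ("FC1", "FCz", "FC2", "C1", "CPz", "CP2"),
    "parietal": ("CP1", "CPz", "CP2", "P1", "Pz", "P2", "PO3", "POz", "PO4"),
}


@dataclass(frozen=True)
class AreaSet:
    """Named, ordered channel lists defining the detection areas."""

    areas: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, labs in self.areas.items():
            if not labs:
                raise ValueError(f"area {name!r} has no channels")

    @classmethod
    def default(cls, fix_central_overlap: bool = False) -> "AreaSet":
        """The standard three areas.

        The printed central list shares CPz/CP2 with the parietal list
        even though the areas are described as non-overlapping; the
        default keeps the lists exactly as printed and warns.  With
        ``fix_central_overlap`` the suspected typo is repaired by
        substituting Cz/C2.
        """
        areas = {k: tuple(v) for k, v in DEFAULT_AREAS.items()}
        if fix_central_overlap:
            areas["central"] = ("FC1", "FCz", "FC2", "C1", "Cz", "C2")
        else:
            warnings.warn(
                "central and parietal area lists overlap on CPz/CP2 "
                "(as printed); pass fix_central_overlap=True to substitute Cz/C2",
                stacklevel=2,
            )
        return cls(areas=areas)

    def validate_against(self, labels: list[str]) -> None:
        have = set(labels)
        for name, labs in self.areas.items():
            missing = [l for l in labs if l not in have]
            if missing:
                raise ValueError(f"area {name!r} channels missing: {missing}")


@dataclass(frozen=True)
class DetectionParams:
    band: tuple[float, float] = (5.0, 7.0)
    butter_order: int = 2
    thresh_factor: float = 2.0
    corr_cut: float = 0.95
    lag_win_ms: float = 50.0
    min_involved_neighbors: int = 1
    period_tol: float = 0.2
    mad_kind: str = "mad"  # or "mean_abs": mean absolute deviation from median
    corr_mode: str = "lag"  # or "window": fixed 50 ms segment, zero lag

    def __post_init__(self) -> None:
        if not 0 < self.corr_cut < 1:
            raise ValueError("corr_cut must lie in (0, 1)")
        if not self.lag_win_ms > 0:
            raise ValueError("lag_win_ms must be positive")
        if self.mad_kind not in ("mad", "mean_abs"):
            raise ValueError(f"unknown mad_kind {self.mad_kind!r}")
        if self.corr_mode not in ("lag", "window"):
            raise ValueError(f"unknown corr_mode {self.corr_mode!r}")

    @property
    def period_range(self) -> tuple[float, float]:
        """Allowed separation (s) of flanking maxima: theta period +- tol."""
        lo, hi = self.band
        return (1.0 / hi) * (1.0 - self.period_tol), (1.0 / lo) * (1.0 + self.period_tol)


def theta_filter(data: np.ndarray, fs: float, p: DetectionParams = DetectionParams()) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass in the theta band."""
    sos = signal.butter(p.butter_order, p.band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def area_reference(
    rec: Recording, area: tuple[str, ...] | list[str], p: DetectionParams = DetectionParams()
) -> np.ndarray:
    """Theta-filtered mean of the area's channels (the reference signal)."""
    if rec.unit_state != "zscored" or rec.reference != "average":
        raise ValueError("detection expects a z-scored, average-referenced recording")
    missing = [l for l in area if l not in rec.labels]
    if missing:
        raise ValueError(f"area channels missing from recording: {missing}")
    idx = [rec.labels.index(l) for l in area]
    return theta_filter(rec.data[idx].mean(axis=0), rec.fs, p)


def compute_threshold(
    refsig: np.ndarray,
    p: DetectionParams = DetectionParams(),
    mask: np.ndarray | None = None,
) -> float:
    """Robust negative trough threshold of a reference signal.

    ``median - thresh_factor x median(|x - median|)`` over usable
    samples (or the mean absolute deviation from the median when
    ``mad_kind='mean_abs'``).  One-sided: only negative troughs are
    detected against it.
    """
    x = refsig if mask is None else refsig[np.asarray(mask, bool)]
    med = float(np.median(x))
    dev = np.abs(x - med)
    scale = float(np.median(dev)) if p.mad_kind == "mad" else float(np.mean(dev))
    return med - p.thresh_factor * scale


def detect_negative_peaks(
    refsig: np.ndarray,
    fs: float,
    thr: float,
    p: DetectionParams = DetectionParams(),
    mask: np.ndarray | None = None,
) -> list[tuple[float, float, float]]:
    """Candidate troughs between theta-spaced local maxima.

    For each pair of *consecutive* strict local maxima whose separation
    lies in the theta period range, the interior minimum is a candidate
    iff its value is strictly below ``thr`` and every sample between the
    maxima (inclusive) is usable.  Returns ``(t_pos_prev, t_neg,
    t_pos_next)`` triples in seconds, sorted by ``t_neg``.
    """
    x = np.asarray(refsig, dtype=float)
    med = np.median(x if mask is None else x[np.asarray(mask, bool)])
    if thr == med:  # degenerate flat signal (zero spread): nothing to detect
        return []
    if thr > med:
        raise ValueError("threshold must lie below the signal median")
    interior = x[1:-1]
    maxima = np.flatnonzero((interior > x[:-2]) & (interior > x[2:])) + 1
    if len(maxima) < 2:
        return []
    lo, hi = p.period_range
    sep = np.diff(maxima) / fs
    ok_pairs = np.flatnonzero((sep >= lo) & (sep <= hi))
    bad_cum = None
    if mask is not None:
        bad_cum = np.r_[0, np.cumsum(~np.asarray(mask, bool))]
    out: list[tuple[float, float, float]] = []
    seen: set[int] = set()
    for k in ok_pairs:
        m1, m2 = int(maxima[k]), int(maxima[k + 1])
        seg = x[m1 + 1 : m2]
        imin = m1 + 1 + int(np.argmin(seg))  # first occurrence breaks ties
        if not x[imin] < thr:
            continue
        if bad_cum is not None and bad_cum[m2 + 1] - bad_cum[m1] > 0:
            continue
        if imin in seen:
            continue
        seen.add(imin)
        out.append((m1 / fs, imin / fs, m2 / fs))
    return out


def _max_lagged_corr(ref: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Max Pearson r of ``ref`` against each lagged window.

    ``windows`` has shape (n_channels, n_lags, len(ref)).
    """
    r = ref - ref.mean()
    rn = np.linalg.norm(r)
    w = windows - windows.mean(axis=2, keepdims=True)
    wn = np.linalg.norm(w, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.einsum("clt,t->cl", w, r) / (wn * rn)
    corr = np.nan_to_num(corr, nan=-1.0)
    return corr.max(axis=1)


def event_involvement(
    cand: tuple[float, float, float],
    rec_theta: np.ndarray,
    fs: float,
    refsig: np.ndarray,
    montage: Montage,
    labels: list[str],
    p: DetectionParams = DetectionParams(),
) -> frozenset[str] | None:
    """Channels involved in one candidate event, after cluster pruning.

    The reference's segment between the flanking maxima (``corr_mode
    'lag'``, default) is correlated with every channel's theta trace at
    integer-sample lags up to +-``lag_win_ms``; a channel is involved
    when its maximum correlation strictly exceeds ``corr_cut``.  With
    ``corr_mode 'window'`` a fixed 50 ms segment centered on the trough
    is compared at zero lag only.  Involved channels with fewer than
    ``min_involved_neighbors`` involved neighbors in the montage graph
    are unmarked (single pass).

    Returns None (with a log entry) when the lagged segment would cross
    the recording edge.
    """
    t_prev, t_neg, t_next = cand
    n = rec_theta.shape[1]
    if p.corr_mode == "lag":
        i0, i1 = int(round(t_prev * fs)), int(round(t_next * fs)) + 1
        lag = int(round(p.lag_win_ms * fs / 1000.0))
    else:
        half = int(round(p.lag_win_ms * fs / 1000.0 / 2))
        c = int(round(t_neg * fs))
        i0, i1 = c - half, c + half + 1
        lag = 0
    if i0 - lag < 0 or i1 + lag > n:
        logger.info("candidate at t=%.3f s too close to the edge; dropped", t_neg)
        return None
    ref = refsig[i0:i1]
    block = rec_theta[:, i0 - lag : i1 + lag]
    windows = sliding_window_view(block, len(ref), axis=1)  # ch x lags x seg
    best = _max_lagged_corr(ref, windows)
    involved = {lab for lab, r in zip(labels, best) if r > p.corr_cut}
    # cluster pruning: unmark channels isolated within the involved set
    kept = {
        lab
        for lab in involved
        if len(montage.neighbor_map.get(lab, set()) & involved)
        >= p.min_involved_neighbors
    }
    return frozenset(kept)


def event_amplitude(
    cand: tuple[float, float, float],
    involved: frozenset[str],
    rec_theta: np.ndarray,
    fs: float,
    labels: list[str],
) -> float:
    """Trough-to-following-peak amplitude at the median-slope channel.

    Per involved channel the slope is the rise from the trough sample to
    the next-maximum sample of the reference timing, divided by the
    elapsed time; the channel with the median slope (lower median for
    even counts) supplies the amplitude.
    """
    if not involved:
        raise ValueError("amplitude needs a nonempty involved set")
    _, t_neg, t_next = cand
    i_neg, i_next = int(round(t_neg * fs)), int(round(t_next * fs))
    idx = [labels.index(l) for l in sorted(involved)]
    vals_neg = rec_theta[idx, i_neg]
    vals_next = rec_theta[idx, i_next]
    slopes = (vals_next - vals_neg) / ((i_next - i_neg) / fs)
    order = np.argsort(slopes, kind="stable")
    pick = order[(len(idx) - 1) // 2]  # lower median
    return float(vals_next[pick] - vals_neg[pick])


def detect_all(
    rec: Recording,
    areas: AreaSet,
    montage: Montage,
    p: DetectionParams = DetectionParams(),
) -> tuple[list[EventRecord], dict[str, float]]:
    """Full detection chain over all areas.

    Returns the event list (sorted by area then time) and the per-area
    density in events per minute of usable signal.  Candidates whose
    involved set empties after pruning are discarded and logged.
    Globality uses the analyzed (non-bad) channel count as denominator.
    """
    areas.validate_against(rec.labels)
    analyzed = [l for l in rec.labels if l not in rec.bad_channels]
    n_analyzed = len(analyzed)
    rec_theta = theta_filter(rec.data, rec.fs, p)
    usable_min = rec.usable_seconds / 60.0
    events: list[EventRecord] = []
    density: dict[str, float] = {}
    for name, area in areas.areas.items():
        idx = [rec.labels.index(l) for l in area]
        refsig = theta_filter(rec.data[idx].mean(axis=0), rec.fs, p)
        thr = compute_threshold(refsig, p, mask=rec.artifact_mask)
        cands = detect_negative_peaks(refsig, rec.fs, thr, p, mask=rec.artifact_mask)
        kept = 0
        for cand in cands:
            involved = event_involvement(
                cand, rec_theta, rec.fs, refsig, montage, rec.labels, p
            )
            if involved is None:
                continue
            if not involved:
                logger.debug(
                    "event at t=%.3f s (%s) pruned to empty; discarded", cand[1], name
                )
                continue
            amp = event_amplitude(cand, involved, rec_theta, rec.fs, rec.labels)
            events.append(
                EventRecord(
                    area=name,
                    t_neg=cand[1],
                    t_pos_prev=cand[0],
                    t_pos_next=cand[2],
                    amplitude_z=amp,
                    involved=involved,
                    globality_pct=100.0 * len(involved) / n_analyzed,
                )
            )
            kept += 1
        density[name] = kept / usable_min if usable_min > 0 else 0.0
    events.sort(key=lambda e: (e.area, e.t_neg))
    return events, density
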