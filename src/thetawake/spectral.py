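"""Power spectra, PRSA, normalized band topography, global-increase rule.

PSDs use Welch's averaged periodograms with a 4-s Hamming window; each
segment is zero-padded to reach a 0.125 Hz bin spacing (the only
self-consistent reading of a 4-s window with 0.125 Hz resolution).
Band power per channel is divided by the scalp-average band power, so
every topography has mean 1 by construction.

PRSA (phase-rectified signal averaging) reinforces quasi-periodic
components before the PSD: windows centered on "anchor" samples — by
default every sample smaller than its predecessor — are averaged, which
aligns oscillatory phases and cancels incoherent noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import welch_masked
from .types import BandTopography, Recording

__all__ = [
    "SpectralParams",
    "prsa",
    "band_topography",
    "global_increase",
]


@dataclass(frozen=True)
class SpectralParams:
    welch_win: float = 4.0
    freq_res: float = 0.125
    theta_band: tuple[float, float] = (5.0, 7.0)
    prsa_halfwin: float = 2.0
    prsa_anchor: str = "decreasing"
    min_anchors: int = 100

    def __post_init__(self) -> None:
        if self.freq_res > 1.0 / self.welch_win + 1e-12:
            raise ValueError(
                "freq_res finer than the window only via zero padding; "
                "it may not be coarser than 1/welch_win"
            )
        if self.prsa_anchor not in ("decreasing", "increasing"):
            raise ValueError(f"unknown anchor rule {self.prsa_anchor!r}")


def prsa(
    x: np.ndarray,
    fs: float,
    p: SpectralParams = SpectralParams(),
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Phase-rectified signal average of a single-channel trace.

    Anchors are samples that decrease relative to their predecessor
    (or increase, per ``prsa_anchor``); the returned curve is the mean
    over anchor-centered windows of length ``2 * prsa_halfwin``.
    Windows that would cross the signal edge, or contain unusable
    samples, are dropped.  Returns ``(curve, n_anchors)``.

    Raises if fewer than ``min_anchors`` usable anchors are found.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("prsa expects a single-channel trace")
    half = int(round(p.prsa_halfwin * fs))
    if len(x) < 10 * half:
        raise ValueError("signal too short for the PRSA half-window")
    dec = x[1:] < x[:-1]
    if p.prsa_anchor == "increasing":
        dec = x[1:] > x[:-1]
    anchors = np.flatnonzero(dec) + 1
    anchors = anchors[(anchors >= half) & (anchors < len(x) - half)]
    if mask is not None:
        bad_cum = np.r_[0, np.cumsum(~np.asarray(mask, bool))]
        ok = (bad_cum[anchors + half] - bad_cum[anchors - half]) == 0
        anchors = anchors[ok]
    if len(anchors) < p.min_anchors:
        raise ValueError(
            f"only {len(anchors)} PRSA anchors found; need >= {p.min_anchors}"
        )
    offsets = np.arange(-half, half)
    curve = np.zeros(2 * half)
    for i in range(0, len(anchors), 4096):  # chunked to bound memory
        idx = anchors[i : i + 4096, None] + offsets[None, :]
        curve += x[idx].sum(axis=0)
    return curve / len(anchors), int(len(anchors))


def _band_power(
    data: np.ndarray, fs: float, mask: np.ndarray, p: SpectralParams
) -> np.ndarray:
    nperseg = int(round(p.welch_win * fs))
    nfft = int(round(fs / p.freq_res))
    f, pxx = welch_masked(data, fs, mask, nperseg, nfft=nfft)
    lo, hi = p.theta_band
    band = (f >= lo) & (f < hi)  # closed-open band convention
    return pxx[:, band].mean(axis=1)


def band_topography(
    rec: Recording, p: SpectralParams = SpectralParams(), use_prsa: bool = False
) -> BandTopography:
    """Normalized band-power topography of a preprocessed recording.

    Per channel: optionally PRSA, then Welch PSD (4-s Hamming segments,
    50% overlap, zero-padded to ``freq_res`` spacing); band power is the
    mean over bins in ``[lo, hi)``; finally each channel is divided by
    the cross-channel mean so the scalp average is exactly 1.
    """
    if rec.unit_state != "zscored" or rec.reference != "average":
        raise ValueError("topography expects a z-scored, average-referenced recording")
    if rec.usable_seconds < 2 * p.welch_win:
        raise ValueError("need at least two Welch windows of usable signal")
    if use_prsa:
        curves = []
        for ch in rec.data:
            curve, _ = prsa(ch, rec.fs, p, mask=rec.artifact_mask)
            curves.append(curve)
        source = np.stack(curves)
        src_mask = np.ones(source.shape[1], dtype=bool)
        nperseg = min(int(round(p.welch_win * rec.fs)), source.shape[1])
        nfft = int(round(rec.fs / p.freq_res))
        f, pxx = welch_masked(source, rec.fs, src_mask, nperseg, nfft=nfft)
        band = (f >= p.theta_band[0]) & (f < p.theta_band[1])
        power = pxx[:, band].mean(axis=1)
    else:
        power = _band_power(rec.data, rec.fs, rec.artifact_mask, p)
    with np.errstate(invalid="ignore"):
        values = power / power.mean()
    return BandTopography(labels=list(rec.labels), values=values, band=p.theta_band)


def global_increase(
    topo_a: BandTopography, topo_b: BandTopography
) -> tuple[float, bool]:
    """Fraction of channels with a strict increase from A to B.

    The increase is *global* when strictly more than 50% of the
    electrodes increase.
    """
    if topo_a.labels != topo_b.labels:
        raise ValueError("topographies cover different channel sets")
    frac = float(np.mean(topo_b.values > topo_a.values))
    return frac, frac > 0.5
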