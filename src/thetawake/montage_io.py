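"""Electrode geometry, neighbor graphs, and file I/O.

Electrode positions follow the idealized spherical 10-20/10-10 scheme:
the scalp is a unit sphere, midline and ear-to-ear electrodes sit at
their nominal arc fractions (10% of the nasion-inion or preauricular
arc per step), the outer ring lies 72 degrees from the vertex, and
intermediate rows are spaced proportionally along the circle through
their ring anchors and midline electrode.  Distances between labels
therefore match nominal published 10-20 geometry exactly.

Recordings are exchanged as EDF (16-bit), behavioral trials and event
tables as CSV.  The default cap is a symmetric 58-electrode 10-10
layout containing the frontal/central/parietal detection electrodes;
the analysis set drops the P5 and P6 derivations, leaving 56 channels.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import warnings
from pathlib import Path

import numpy as np

from .types import EventRecord, Montage, Recording, TrialRecord

__all__ = [
    "CAP_58",
    "ANALYSIS_56",
    "standard_montage",
    "build_neighbors",
    "read_edf",
    "write_edf",
    "read_trials",
    "write_trials",
    "read_events",
    "write_events",
    "montage_to_json",
    "read_mask",
    "write_mask",
]

#: Symmetric 58-channel 10-10 cap (superset of the three detection areas).
CAP_58: tuple[str, ...] = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO3", "POz", "PO4",
    "O1", "Oz", "O2",
)

#: Analysis set: the 58-channel cap minus the excluded P5/P6 derivations.
ANALYSIS_56: tuple[str, ...] = tuple(l for l in CAP_58 if l not in ("P5", "P6"))

_STANDARD_POSITIONS: dict[str, np.ndarray] | None = None


def _sph(polar_deg: float, az_deg: float) -> np.ndarray:
    """Unit vector at a polar angle from the vertex and azimuth from nasion.

    Azimuth is measured from +y (nasion) toward +x (right ear).
    """
    th = np.radians(polar_deg)
    az = np.radians(az_deg)
    return np.array([np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


def _circumcenter(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Center of the (generally non-great) circle through three 3-D points."""
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    denom = 2.0 * float(n @ n)
    return a + (
        float(ac @ ac) * np.cross(np.cross(ab, ac), ab)
        + float(ab @ ab) * np.cross(ac, np.cross(ab, ac))
    ) / denom


def _row_circle(left: np.ndarray, mid: np.ndarray, right: np.ndarray, n: int):
    """``n`` points proportionally spaced on the circle left->mid->right."""
    o = _circumcenter(left, mid, right)
    u = left - o
    radius = np.linalg.norm(u)
    u = u / radius
    normal = np.cross(left - o, right - o)
    w = np.cross(normal / np.linalg.norm(normal), u)
    if (mid - o) @ w < 0:
        w = -w
    theta_right = np.arctan2((right - o) @ w, (right - o) @ u) % (2 * np.pi)
    ts = np.linspace(0.0, 1.0, n)
    return [o + radius * (np.cos(t * theta_right) * u + np.sin(t * theta_right) * w)
            for t in ts]


def _build_ideal_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    # Sagittal midline: 10% of the nasion-inion arc per step.
    midline = ["Nz", "Fpz", "AFz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz", "Iz"]
    for i, lab in enumerate(midline):
        pos[lab] = _sph(abs(5 - i) * 18.0, 0.0 if i <= 5 else 180.0)
    # Coronal ear-to-ear line.
    coronal = ["T9", "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8", "T10"]
    for i, lab in enumerate(coronal):
        pos[lab] = _sph(abs(5 - i) * 18.0, -90.0 if i < 5 else 90.0)
    # Outer ring, 72 degrees from the vertex, 18-degree azimuth steps.
    ring_right = ["Fpz", "Fp2", "AF8", "F8", "FT8", "T8", "TP8", "P8", "PO8", "O2", "Oz"]
    ring_left = ["Fpz", "Fp1", "AF7", "F7", "FT7", "T7", "TP7", "P7", "PO7", "O1", "Oz"]
    for i, (lr, ll) in enumerate(zip(ring_right, ring_left)):
        pos.setdefault(lr, _sph(72.0, 18.0 * i))
        pos.setdefault(ll, _sph(72.0, -18.0 * i))
    # Intermediate rows: proportional arcs along the circle through the
    # left ring anchor, the midline electrode, and the right ring anchor.
    rows = {
        "AF": ("AF7", "AFz", "AF8", ["AF7", "AF5", "AF3", "AF1", "AFz", "AF2", "AF4", "AF6", "AF8"]),
        "F": ("F7", "Fz", "F8", ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"]),
        "FC": ("FT7", "FCz", "FT8", ["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"]),
        "CP": ("TP7", "CPz", "TP8", ["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"]),
        "P": ("P7", "Pz", "P8", ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"]),
        "PO": ("PO7", "POz", "PO8", ["PO7", "PO5", "PO3", "PO1", "POz", "PO2", "PO4", "PO6", "PO8"]),
    }
    for left, mid, right, labels in rows.values():
        pts = _row_circle(pos[left], pos[mid], pos[right], len(labels))
        for lab, p in zip(labels, pts):
            pos.setdefault(lab, p / np.linalg.norm(p))
    return {k: v / np.linalg.norm(v) for k, v in pos.items()}


def _standard_positions() -> dict[str, np.ndarray]:
    """Idealized spherical 10-10 electrode positions (cached)."""
    global _STANDARD_POSITIONS
    if _STANDARD_POSITIONS is None:
        _STANDARD_POSITIONS = _build_ideal_positions()
    return _STANDARD_POSITIONS


def _azimuthal_projection(v: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant 2-D projection, vertex at origin, nose up."""
    rho = np.arccos(np.clip(v[2], -1.0, 1.0))  # polar angle from vertex
    az = np.arctan2(v[0], v[1])  # 0 at nasion, positive to the right
    return np.array([rho * np.sin(az), rho * np.cos(az)])


def standard_montage(labels: list[str] | tuple[str, ...] = ANALYSIS_56) -> Montage:
    """Build a :class:`Montage` from standard 10-20/10-10 positions.

    Parameters
    ----------
    labels
        Channel names; every name must be a recognized 10-20/10-10 label.

    Raises
    ------
    ValueError
        If a label is not a standard electrode name.
    """
    std = _standard_positions()
    # standard montage files use e.g. "FPz" vs "Fpz" consistently with ours;
    # resolve case-insensitively but keep the caller's spelling.
    by_lower = {k.lower(): k for k in std}
    pos3d: dict[str, np.ndarray] = {}
    pos2d: dict[str, np.ndarray] = {}
    for lab in labels:
        key = by_lower.get(lab.lower())
        if key is None:
            raise ValueError(f"unknown 10-20/10-10 electrode label: {lab!r}")
        v = std[key]
        pos3d[lab] = v
        pos2d[lab] = _azimuthal_projection(v)
    return Montage(labels=list(labels), pos3d=pos3d, pos2d=pos2d)


def build_neighbors(montage: Montage, max_angle: float = 25.0) -> Montage:
    """Populate the neighbor map by great-circle angular distance.

    Two electrodes are neighbors when their angular separation on the unit
    sphere is at most ``max_angle`` degrees.  The default of 25 degrees
    yields roughly 4-8 neighbors per channel on a 56-channel cap.  The
    relation is symmetric and irreflexive by construction.  Channels left
    without any neighbor trigger a warning, not an error.
    """
    if not max_angle > 0:
        raise ValueError("max_angle must be positive")
    labels = montage.labels
    mat = np.stack([montage.pos3d[lab] for lab in labels])
    cos = np.clip(mat @ mat.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    np.fill_diagonal(ang, np.inf)
    adj = ang <= max_angle
    nmap = {
        lab: {labels[j] for j in np.flatnonzero(adj[i])}
        for i, lab in enumerate(labels)
    }
    isolated = [lab for lab, nbrs in nmap.items() if not nbrs]
    if isolated:
        warnings.warn(
            f"channels with no neighbors at {max_angle} deg: {isolated}",
            stacklevel=2,
        )
    out = Montage(
        labels=list(labels),
        pos3d=dict(montage.pos3d),
        pos2d=dict(montage.pos2d),
        neighbor_map=nmap,
    )
    out.validate_neighbors()
    return out


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------
# Minimal EDF (16-bit European Data Format) reader/writer.  One data record
# per second; every channel must share one integer sampling rate.  No EDF
# writer ships in this package's dependency set, so the writer is
# implemented directly against the published header layout; the reader is
# cross-checked against mne.io.read_raw_edf in the test suite.


def _fmt8(v: float) -> str:
    """Shortest decimal representation of ``v`` fitting 8 ASCII chars."""
    for digits in range(8, 0, -1):
        s = f"{v:.{digits}g}"
        if len(s) <= 8:
            return s
    return f"{v:.0e}"[:8]


def _phys_bounds(rec: Recording) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel physical min/max as they will appear in the header.

    Padded slightly, then rounded to the 8-character header precision
    and re-expanded until the data range is guaranteed to fit, so the
    writer's digitization gain matches what a reader will parse.
    """
    lo = rec.data.min(axis=1)
    hi = rec.data.max(axis=1)
    span = np.where(hi - lo <= 0, np.maximum(np.abs(lo), 1.0), hi - lo)
    pmin = np.empty_like(lo)
    pmax = np.empty_like(hi)
    for i in range(len(lo)):
        pad = 1e-3 * span[i]
        a, b = lo[i] - pad, hi[i] + pad
        for _ in range(20):
            a_r = float(_fmt8(a))
            b_r = float(_fmt8(b))
            if a_r <= lo[i] and b_r >= hi[i] and b_r > a_r:
                break
            pad *= 4.0
            a, b = lo[i] - pad, hi[i] + pad
        pmin[i], pmax[i] = a_r, b_r
    return pmin, pmax


def edf_quantization_step(rec: Recording) -> np.ndarray:
    """Per-channel quantization step the 16-bit EDF roundtrip incurs."""
    pmin, pmax = _phys_bounds(rec)
    return (pmax - pmin) / 65535.0


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF.

    The recording duration must be an integer number of seconds and ``fs``
    an integer, so that 1-second data records tile the signal exactly.
    The artifact mask and bad-channel set are not part of EDF; use
    :func:`write_mask` for the mask sidecar.
    """
    path = Path(path)
    if rec.n_channels == 0:
        raise ValueError("cannot write an EDF with no channels")
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise ValueError(
            "EDF writer requires a whole number of seconds "
            f"({rec.n_samples} samples at {fs} Hz); trim the recording"
        )
    n_records = rec.n_samples // fs
    ns = rec.n_channels

    dig_min, dig_max = -32768, 32767
    phys_min, phys_max = _phys_bounds(rec)

    unit = "uV" if rec.unit_state == "volts" else "zU"
    now = _dt.datetime(2000, 1, 1)

    def f(s: str, n: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > n:
            raise ValueError(f"EDF header field too long: {s!r}")
        return b.ljust(n)

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),  # local patient id
            f(f"Startdate 01-JAN-2000 X X thetawake ref={rec.reference}", 80),
            f(now.strftime("%d.%m.%y"), 8),
            f(now.strftime("%H.%M.%S"), 8),
            f(str(256 * (1 + ns)), 8),
            f("", 44),
            f(str(n_records), 8),
            f("1", 8),  # record duration, seconds
            f(str(ns), 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(f(lab, 16) for lab in rec.labels),
            b"".join(f("EEG", 80) for _ in range(ns)),
            b"".join(f(unit, 8) for _ in range(ns)),
            b"".join(f(_fmt8(phys_min[i]), 8) for i in range(ns)),
            b"".join(f(_fmt8(phys_max[i]), 8) for i in range(ns)),
            b"".join(f(str(dig_min), 8) for _ in range(ns)),
            b"".join(f(str(dig_max), 8) for _ in range(ns)),
            b"".join(f("", 80) for _ in range(ns)),
            b"".join(f(str(fs), 8) for _ in range(ns)),
            b"".join(f("", 32) for _ in range(ns)),
        ]
    )

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round(
        (rec.data - phys_min[:, None]) / gain[:, None] + dig_min
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())  # channel-major within each record


def read_edf(path: str | Path) -> Recording:
    """Read a 16-bit EDF file written by :func:`write_edf` (or compatible).

    All channels must share one sampling rate; annotation channels are not
    supported.  Returns a recording with an all-usable artifact mask.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            header_bytes = int(head[184:192].decode("ascii").strip())
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ValueError(f"{path}: malformed EDF header: {exc}") from exc
        recording_info = head[88:168].decode("ascii", "replace")
        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise ValueError(f"{path}: truncated EDF signal headers")

        def field(block_off: int, width: int, i: int) -> str:
            start = block_off * ns + i * width
            return sig[start : start + width].decode("ascii").strip()

        labels = [field(0, 16, i) for i in range(ns)]
        units = [field(96, 8, i) for i in range(ns)]
        phys_min = np.array([float(field(104, 8, i)) for i in range(ns)])
        phys_max = np.array([float(field(112, 8, i)) for i in range(ns)])
        dig_min = np.array([float(field(120, 8, i)) for i in range(ns)])
        dig_max = np.array([float(field(128, 8, i)) for i in range(ns)])
        nsamp = [int(field(216, 8, i)) for i in range(ns)]
        if len(set(nsamp)) != 1:
            raise ValueError(
                f"{path}: mixed per-record sample counts {sorted(set(nsamp))}; "
                "channels must share one sampling rate"
            )
        spr = nsamp[0]
        fs = spr / record_dur
        fh.seek(header_bytes)
        raw = np.frombuffer(fh.read(2 * spr * ns * n_records), dtype="<i2")
    if raw.size != spr * ns * n_records:
        raise ValueError(f"{path}: EDF data section shorter than header declares")
    digital = raw.reshape(n_records, ns, spr).transpose(1, 0, 2).reshape(ns, -1)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * gain[:, None] + phys_min[:, None]

    reference = "earlobe"
    if "ref=average" in recording_info:
        reference = "average"
    unit_state = "zscored" if units and units[0] == "zU" else "volts"
    return Recording(
        data=data, fs=fs, labels=labels, reference=reference, unit_state=unit_state
    )


# ---------------------------------------------------------------------------
# Mask sidecar (bad-segment intervals, seconds, half-open)
# ---------------------------------------------------------------------------


def write_mask(mask: np.ndarray, fs: float, path: str | Path) -> None:
    """Write unusable segments as a two-column CSV (bad_start_s, bad_end_s)."""
    bad = ~np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.r_[False, bad, False]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bad_start_s", "bad_end_s"])
        for start, end in zip(edges[::2], edges[1::2]):
            w.writerow([start / fs, end / fs])


def read_mask(path: str | Path, n_samples: int, fs: float) -> np.ndarray:
    """Read a bad-segment CSV into a per-sample usability mask."""
    mask = np.ones(n_samples, dtype=bool)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "bad_start_s" not in reader.fieldnames:
            raise ValueError(f"{path}: missing required column 'bad_start_s'")
        for row in reader:
            i0 = int(np.floor(float(row["bad_start_s"]) * fs))
            i1 = int(np.ceil(float(row["bad_end_s"]) * fs))
            mask[max(i0, 0) : min(i1, n_samples)] = False
    return mask


# ---------------------------------------------------------------------------
# Trial and event tables
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = ("trial_id", "stim_time_s", "rt_ms", "outcome")
_EVENT_COLUMNS = (
    "event_id",
    "area",
    "t_neg_s",
    "t_pos_prev_s",
    "t_pos_next_s",
    "amplitude_z",
    "globality_pct",
    "involved_channels",
)


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a behavioral trial table (CSV: trial_id, stim_time_s, rt_ms, outcome)."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        names = reader.fieldnames or []
        for col in _TRIAL_COLUMNS:
            if col not in names:
                raise ValueError(f"{path}: missing required column {col!r}")
        trials = []
        for i, row in enumerate(reader):
            try:
                rt = float(row["rt_ms"])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric rt_ms in data row {i}: {row['rt_ms']!r}"
                ) from exc
            trials.append(
                TrialRecord(
                    trial_id=int(row["trial_id"]),
                    stim_time=float(row["stim_time_s"]),
                    rt=rt,
                    outcome=row["outcome"].strip(),
                )
            )
    return trials


def write_trials(trials: list[TrialRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_TRIAL_COLUMNS)
        for t in trials:
            w.writerow([t.trial_id, repr(t.stim_time), repr(t.rt), t.outcome])


def write_events(events: list[EventRecord], path: str | Path) -> None:
    """Write detected events as CSV; involved channels are ';'-joined."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_EVENT_COLUMNS)
        for i, e in enumerate(events):
            w.writerow(
                [
                    i,
                    e.area,
                    repr(e.t_neg),
                    repr(e.t_pos_prev),
                    repr(e.t_pos_next),
                    repr(e.amplitude_z),
                    repr(e.globality_pct),
                    ";".join(sorted(e.involved)),
                ]
            )


def read_events(path: str | Path) -> list[EventRecord]:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        names = reader.fieldnames or []
        for col in _EVENT_COLUMNS:
            if col not in names:
                raise ValueError(f"{path}: missing required column {col!r}")
        events = []
        for row in reader:
            involved = frozenset(
                c for c in row["involved_channels"].split(";") if c
            )
            events.append(
                EventRecord(
                    area=row["area"],
                    t_neg=float(row["t_neg_s"]),
                    t_pos_prev=float(row["t_pos_prev_s"]),
                    t_pos_next=float(row["t_pos_next_s"]),
                    amplitude_z=float(row["amplitude_z"]),
                    involved=involved,
                    globality_pct=float(row["globality_pct"]),
                )
            )
    return events


def montage_to_json(montage: Montage, path: str | Path) -> None:
    obj = {
        "labels": montage.labels,
        "pos3d": {k: v.tolist() for k, v in montage.pos3d.items()},
        "pos2d": {k: v.tolist() for k, v in montage.pos2d.items()},
        "neighbor_map": {k: sorted(v) for k, v in montage.neighbor_map.items()},
    }
    Path(path).write_text(json.dumps(obj, indent=1))
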