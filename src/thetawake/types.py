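"""Core domain containers shared across the package.

All times are seconds from recording start, all sample indexing is 0-based,
and intervals are half-open ``[start, end)`` unless a docstring says
otherwise.  Voltages are microvolts before standardization and unitless
z-scores after.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "Recording",
    "EventRecord",
    "TrialRecord",
    "BandTopography",
]


@dataclass
class Montage:
    """Electrode geometry and sensor adjacency.

    Parameters
    ----------
    labels
        Ordered channel names (10-20 / 10-10 nomenclature).
    pos3d
        label -> unit-sphere coordinates ``(x, y, z)`` with +x toward the
        right ear, +y toward the nasion and +z toward the vertex.
    pos2d
        label -> azimuthal-equidistant projection ``(x, y)`` of ``pos3d``
        (vertex at the origin, nose up).
    neighbor_map
        label -> set of neighboring labels.  Symmetric and irreflexive;
        empty until :func:`~thetawake.montage_io.build_neighbors` runs.
    """

    labels: list[str]
    pos3d: dict[str, np.ndarray]
    pos2d: dict[str, np.ndarray]
    neighbor_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab not in self.pos3d or lab not in self.pos2d:
                raise ValueError(f"label {lab!r} has no position")

    def angle_deg(self, a: str, b: str) -> float:
        """Great-circle angular distance between two electrodes in degrees."""
        cosang = float(np.clip(np.dot(self.pos3d[a], self.pos3d[b]), -1.0, 1.0))
        return float(np.degrees(np.arccos(cosang)))

    def angles_from(self, center: str, labels: list[str] | None = None) -> np.ndarray:
        """Angular distances (degrees) from ``center`` to each label."""
        labels = self.labels if labels is None else labels
        ref = self.pos3d[center]
        mat = np.stack([self.pos3d[lab] for lab in labels])
        return np.degrees(np.arccos(np.clip(mat @ ref, -1.0, 1.0)))

    def subset(self, labels: list[str]) -> "Montage":
        keep = set(labels)
        nmap = {
            lab: {n for n in self.neighbor_map.get(lab, set()) if n in keep}
            for lab in labels
        }
        return Montage(
            labels=list(labels),
            pos3d={lab: self.pos3d[lab] for lab in labels},
            pos2d={lab: self.pos2d[lab] for lab in labels},
            neighbor_map=nmap,
        )

    def validate_neighbors(self) -> None:
        for a, nbrs in self.neighbor_map.items():
            if a in nbrs:
                raise ValueError(f"neighbor relation is reflexive at {a!r}")
            for b in nbrs:
                if a not in self.neighbor_map.get(b, set()):
                    raise ValueError(f"neighbor relation not symmetric: {a!r}/{b!r}")


@dataclass
class Recording:
    """Multichannel EEG segment.

    ``data`` is channels x samples; ``artifact_mask`` marks usable samples
    (True = usable).  ``reference`` is ``"earlobe"`` (as recorded) or
    ``"average"`` (after re-referencing); ``unit_state`` is ``"volts"``
    (microvolts) or ``"zscored"``.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    reference: str = "earlobe"
    artifact_mask: np.ndarray | None = None
    bad_channels: set[str] = field(default_factory=set)
    unit_state: str = "volts"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.artifact_mask is None:
            self.artifact_mask = np.ones(self.data.shape[1], dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != (self.data.shape[1],):
            raise ValueError("artifact_mask length must equal sample count")
        if not set(self.bad_channels) <= set(self.labels):
            raise ValueError("bad_channels must be a subset of labels")
        if self.reference not in ("earlobe", "average"):
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.unit_state not in ("volts", "zscored"):
            raise ValueError(f"unknown unit_state {self.unit_state!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def usable_seconds(self) -> float:
        return float(self.artifact_mask.sum()) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            fs=self.fs,
            labels=list(self.labels),
            reference=self.reference,
            artifact_mask=self.artifact_mask.copy(),
            bad_channels=set(self.bad_channels),
            unit_state=self.unit_state,
        )


@dataclass
class EventRecord:
    """One detected local sleep-like event.

    ``t_pos_prev`` / ``t_pos_next`` are the flanking positive peaks of the
    area reference signal, ``t_neg`` the negative trough between them.
    ``amplitude_z`` is the trough-to-following-peak excursion measured at
    the median-slope involved channel.  ``globality_pct`` is
    ``100 * len(involved) / n_analyzed`` channels.
    """

    area: str
    t_neg: float
    t_pos_prev: float
    t_pos_next: float
    amplitude_z: float
    involved: frozenset[str]
    globality_pct: float

    def validate(self) -> None:
        if not self.t_pos_prev < self.t_neg < self.t_pos_next:
            raise ValueError("event peaks out of order")
        if not self.amplitude_z > 0:
            raise ValueError("amplitude must be positive")
        if not 0 < self.globality_pct <= 100:
            raise ValueError("globality_pct out of range")


@dataclass
class TrialRecord:
    """One visuomotor trial: stimulus time (s), reaction time (ms), outcome."""

    trial_id: int
    stim_time: float
    rt: float
    outcome: str
    valid: bool | None = None

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError("reaction time must be non-negative")
        if self.outcome not in ("S", "F"):
            raise ValueError(f"outcome must be 'S' or 'F', got {self.outcome!r}")


@dataclass
class BandTopography:
    """Per-channel band power normalized by the scalp average (mean = 1)."""

    labels: list[str]
    values: np.ndarray
    band: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise ValueError("one value per label required")
        if not np.all(self.values > 0):  # also rejects NaN
            raise ValueError("band powers must be positive and finite")
        if abs(self.values.mean() - 1.0) > 1e-9:
            raise ValueError("topography must be normalized to scalp mean 1")

    @property
    def n_channels(self) -> int:
        return len(self.labels)
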