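"""Synthetic wake-EEG sessions with ground truth.

The generator emulates the statistical structure the analysis assumes:

* a spatially correlated 1/f ("pink") background with an alpha peak near
  9 Hz, mimicking relaxed wakefulness;
* transient theta (5-7 Hz) wavelets — local sleep-like events — injected
  at known times with a controllable spatial extent across channels
  (cosine amplitude taper from a center electrode out to a cutoff
  radius), giving every event a known ground-truth involved-channel set;
* visuomotor trials whose reaction times are linearly coupled to the
  globality of events falling in a peristimulus window, plus Gaussian
  noise;
* paired Earth/space-style condition sets with per-subject random
  offsets (random-intercept structure).

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal.windows import hann

from .montage_io import ANALYSIS_56, build_neighbors, standard_montage
from .types import Montage, Recording, TrialRecord

__all__ = [
    "BackgroundSpec",
    "EventSpec",
    "TrialGenSpec",
    "SessionSpec",
    "gen_background",
    "inject_events",
    "gen_trials",
    "gen_session",
    "gen_condition_pair",
    "event_truth_globality",
    "radius_for_globality",
]

logger = logging.getLogger(__name__)

#: reaction-time truncation bounds (ms); chosen so both behavioral
#: exclusion rules (false starts < 100 ms, outliers > 500 ms) see traffic.
RT_BOUNDS_MS = (50.0, 800.0)


@dataclass(frozen=True)
class BackgroundSpec:
    """Parameters of the ongoing background EEG.

    ``psd_slope`` is the 1/f exponent of the power spectrum,
    ``alpha_power_ratio`` the height of the alpha peak relative to the
    1/f trend at ``alpha_freq``.  ``amplitude_sd`` sets each channel's
    standard deviation, in microvolts when ``unit`` is ``"volts"`` and
    in z-units when ``"zscored"``.  ``spatial_lambda`` (degrees) is the
    decay constant of cross-channel correlation.
    """

    n_channels: int = 56
    fs: float = 512.0
    duration: float = 3600.0
    psd_slope: float = 1.0
    alpha_freq: float = 9.0
    alpha_power_ratio: float = 2.0
    amplitude_sd: float = 20.0
    unit: str = "volts"
    spatial_lambda: float = 40.0
    n_sources: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.fs >= 128:
            raise ValueError("fs must be at least 128 Hz")
        if self.psd_slope < 0:
            raise ValueError("psd_slope must be non-negative")
        if self.unit not in ("volts", "zscored"):
            raise ValueError(f"unknown unit {self.unit!r}")


@dataclass(frozen=True)
class EventSpec:
    """Ground truth for one injected local sleep-like event.

    The event is a Hann-windowed theta wavelet whose negative trough
    falls at ``t_neg`` on ``center_channel``.  Across channels the
    amplitude follows a cosine-tapered plateau of angular distance
    ``d``: full amplitude out to ``plateau * spatial_radius``, a
    quarter-cosine falloff to zero at ``spatial_radius``, zero beyond.
    The plateau keeps the involved-channel count a sharp, monotone
    function of the radius.

    Ground-truth *involvement* counts the channels that actually carry
    the event at a meaningful level — taper weight >= ``min_weight``
    (channels on the falloff tail receive next to nothing and no
    detector could, or should, mark them).
    """

    t_neg: float
    center_channel: str
    spatial_radius: float
    amplitude: float
    freq: float = 6.0
    n_cycles: float = 1.5
    plateau: float = 0.8
    min_weight: float = 0.3

    def __post_init__(self) -> None:
        if not 5.0 <= self.freq <= 7.0:
            raise ValueError("event frequency must lie in the theta band [5, 7] Hz")
        if not self.amplitude >= 0:
            raise ValueError("amplitude must be non-negative")
        if not 0.0 <= self.plateau < 1.0:
            raise ValueError("plateau fraction must lie in [0, 1)")

    @property
    def half_duration(self) -> float:
        return 0.5 * self.n_cycles / self.freq

    def taper(self, d: np.ndarray) -> np.ndarray:
        """Spatial amplitude profile at angular distances ``d`` (degrees)."""
        r = max(self.spatial_radius, 1e-9)
        edge = self.plateau * r
        ramp = np.cos(0.5 * np.pi * (d - edge) / max(r - edge, 1e-9))
        w = np.where(d <= edge, 1.0, np.where(d <= r, ramp, 0.0))
        return np.asarray(w, dtype=float)

    def involved_labels(self, montage: Montage, labels: list[str] | None = None) -> frozenset[str]:
        """Ground-truth involved set: channels with taper >= ``min_weight``."""
        labels = montage.labels if labels is None else labels
        d = montage.angles_from(self.center_channel, labels)
        w = self.taper(d)
        return frozenset(lab for lab, ww in zip(labels, w) if ww >= self.min_weight)


@dataclass(frozen=True)
class TrialGenSpec:
    """Reaction-time generator: RT = base + beta * window-globality + noise."""

    n_trials: int = 100
    base_rt: float = 244.0
    beta: float = 2.0
    noise_sd: float = 40.0
    iti: float = 6.0
    jitter_frac: float = 0.25
    p_success: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def event_truth_globality(
    spec: EventSpec, montage: Montage, n_analyzed: int | None = None
) -> float:
    """Ground-truth globality (%) of one event on a given montage."""
    n = len(montage.labels) if n_analyzed is None else n_analyzed
    return 100.0 * len(spec.involved_labels(montage)) / n


def _source_spectrum(freqs: np.ndarray, spec: BackgroundSpec) -> np.ndarray:
    """Target amplitude spectrum: 1/f^slope with a Gaussian alpha bump."""
    f = np.maximum(freqs, 0.5)  # flatten below 0.5 Hz to keep power finite
    power = f ** (-spec.psd_slope)
    power = power * (
        1.0
        + spec.alpha_power_ratio
        * np.exp(-0.5 * ((freqs - spec.alpha_freq) / 1.0) ** 2)
    )
    power[freqs == 0] = 0.0
    return np.sqrt(power)


def _colored_noise(rng: np.random.Generator, n: int, amp: np.ndarray) -> np.ndarray:
    """Gaussian noise with the given rFFT amplitude profile, unit variance."""
    spec = (rng.standard_normal(len(amp)) + 1j * rng.standard_normal(len(amp))) * amp
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def gen_background(spec: BackgroundSpec, montage: Montage) -> Recording:
    """Generate spatially correlated 1/f background EEG.

    Channels are mixtures of shared cortical "sources" (placed at a
    subset of electrode sites, mixed with distance-decaying weights) and
    a private noise stream, all with identical spectral shape — so the
    normalized band topography of the pure background is flat in
    expectation.  Deterministic per seed.
    """
    labels = montage.labels[: spec.n_channels]
    if len(labels) < spec.n_channels:
        raise ValueError("montage has fewer positions than requested channels")
    n = int(round(spec.duration * spec.fs))
    if n * spec.n_channels > 2**31:
        raise ValueError("requested recording too large")
    rng = np.random.default_rng(spec.seed)
    freqs = np.fft.rfftfreq(n, 1.0 / spec.fs)
    amp = _source_spectrum(freqs, spec)

    k = min(spec.n_sources, len(labels))
    source_sites = labels[:: max(1, len(labels) // k)][:k]
    sources = np.stack([_colored_noise(rng, n, amp) for _ in range(k)])
    private = np.stack([_colored_noise(rng, n, amp) for _ in labels])

    pos = np.stack([montage.pos3d[lab] for lab in labels])
    src_pos = np.stack([montage.pos3d[lab] for lab in source_sites])
    ang = np.degrees(np.arccos(np.clip(pos @ src_pos.T, -1, 1)))  # ch x src
    w = np.exp(-ang / spec.spatial_lambda)

    data = w @ sources + 0.7 * private
    data *= spec.amplitude_sd / data.std(axis=1, keepdims=True)
    return Recording(
        data=data,
        fs=spec.fs,
        labels=list(labels),
        reference="earlobe",
        unit_state=spec.unit,
    )


def _wavelet(spec: EventSpec, fs: float) -> tuple[np.ndarray, int]:
    """Hann-windowed cosine trough; returns (waveform, trough offset)."""
    half = int(round(spec.half_duration * fs))
    t = np.arange(-half, half + 1) / fs
    win = hann(2 * half + 1, sym=True)
    return -spec.amplitude * win * np.cos(2 * np.pi * spec.freq * t), half


def inject_events(
    rec: Recording, specs: list[EventSpec]
) -> tuple[Recording, list[EventSpec]]:
    """Add theta wavelets to a recording; returns (new recording, truth).

    The trough of each wavelet lands exactly on the sample nearest
    ``t_neg`` of the center channel; other channels get the same
    waveform scaled by a cosine taper of angular distance, zero beyond
    ``spatial_radius``.  Overlapping events are allowed (logged).
    """
    out = rec.copy()
    montage = standard_montage(rec.labels)
    last_end = -np.inf
    for spec in sorted(specs, key=lambda s: s.t_neg):
        if not 0.0 <= spec.t_neg < rec.duration:
            raise ValueError(f"event t_neg {spec.t_neg} outside recording")
        if spec.center_channel not in rec.labels:
            raise ValueError(f"unknown center channel {spec.center_channel!r}")
        if spec.t_neg - spec.half_duration < last_end:
            logger.info("overlapping injected events near t=%.3f s", spec.t_neg)
        last_end = spec.t_neg + spec.half_duration

        wave, half = _wavelet(spec, rec.fs)
        center = int(round(spec.t_neg * rec.fs))
        i0, i1 = center - half, center + half + 1
        w0 = max(0, -i0)
        w1 = len(wave) - max(0, i1 - rec.n_samples)
        i0, i1 = max(i0, 0), min(i1, rec.n_samples)

        d = montage.angles_from(spec.center_channel, rec.labels)
        taper = spec.taper(d)
        out.data[:, i0:i1] += taper[:, None] * wave[w0:w1]
    return out, list(specs)


def expected_event_amplitude(
    spec: EventSpec,
    labels: list[str],
    fs: float,
    detection_params=None,
) -> float:
    """Noise-free forward model of the detector's amplitude measure.

    Renders the event alone on a zero background, average-references and
    theta-filters it exactly as the detector does, and measures the
    trough-to-following-peak amplitude at the median-slope channel of
    the ground-truth involved set.  This defines what the injected
    ``amplitude`` parameter should come out as downstream, including the
    average-reference leakage and filter attenuation.
    """
    from .events import DetectionParams, event_amplitude, theta_filter
    from .preprocess import average_reference

    p = DetectionParams() if detection_params is None else detection_params
    montage = standard_montage(labels)
    dur = 4.0 * spec.half_duration + 1.0
    centered = replace(spec, t_neg=dur / 2)
    silent = Recording(
        data=np.zeros((len(labels), int(round(dur * fs)))),
        fs=fs,
        labels=list(labels),
        unit_state="zscored",
    )
    rec, _ = inject_events(silent, [centered])
    rec = average_reference(rec)
    theta = theta_filter(rec.data, fs, p)
    involved = sorted(centered.involved_labels(montage))
    ref = theta[[labels.index(l) for l in involved]].mean(axis=0)
    i_neg = int(np.argmin(ref))
    # next local maximum of the reference after the trough
    after = ref[i_neg:]
    rel = np.flatnonzero((after[1:-1] > after[:-2]) & (after[1:-1] > after[2:]))
    i_next = i_neg + 1 + int(rel[0])
    cand = (0.0, i_neg / fs, i_next / fs)
    return event_amplitude(cand, frozenset(involved), theta, fs, list(labels))


def gen_trials(
    truth: list[EventSpec],
    spec: TrialGenSpec,
    session_dur: float,
    montage: Montage,
    n_analyzed: int | None = None,
) -> list[TrialRecord]:
    """Generate a visuomotor trial stream coupled to event globality.

    Stimuli sit on a regular ``iti`` grid with uniform jitter of up to a
    quarter ITI.  RT (ms) = base_rt + beta * (max ground-truth globality
    of events with t_neg in [stim - 0.25 s, stim + 0.5 s), else 0) +
    Gaussian noise, truncated to 50-800 ms.  Outcomes are success/fail
    draws independent of events.
    """
    if spec.iti * spec.n_trials > session_dur:
        raise ValueError("session too short for n_trials at this ITI")
    rng = np.random.default_rng(spec.seed)
    stim = (np.arange(spec.n_trials) + 0.5) * spec.iti
    jit = spec.jitter_frac * spec.iti
    stim = stim + rng.uniform(-jit, jit, size=spec.n_trials)

    ev_times = np.array([e.t_neg for e in truth])
    ev_glob = np.array(
        [event_truth_globality(e, montage, n_analyzed) for e in truth]
    )
    trials = []
    for i, s in enumerate(stim):
        in_win = (ev_times >= s - 0.25) & (ev_times < s + 0.5) if len(truth) else np.array([], bool)
        g = float(ev_glob[in_win].max()) if in_win.any() else 0.0
        rt = spec.base_rt + spec.beta * g + rng.normal(0.0, spec.noise_sd)
        rt = float(np.clip(rt, *RT_BOUNDS_MS))
        outcome = "S" if rng.random() < spec.p_success else "F"
        trials.append(TrialRecord(trial_id=i, stim_time=float(s), rt=rt, outcome=outcome))
    return trials


@dataclass(frozen=True)
class SessionSpec:
    """One synthetic recording session: background plus injected events.

    Event centers are drawn uniformly from ``center_labels``, radii from
    a normal with mean ``radius_mean`` (clipped at 5 degrees), depths
    from a normal with mean ``amplitude``; frequencies uniform in the
    theta band.  Event times are uniform with a minimum separation.
    """

    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    n_events: int = 40
    radius_mean: float = 35.0
    radius_sd: float = 5.0
    amplitude: float = 3.5
    amplitude_sd: float = 0.3
    center_labels: tuple[str, ...] = ("Fz", "F1", "F2", "AFz", "FCz", "CPz", "Pz")
    min_separation: float = 0.8

    def sample_events(self, rng: np.random.Generator) -> list[EventSpec]:
        dur = self.background.duration
        margin = 0.3
        times: list[float] = []
        while len(times) < self.n_events:
            t = rng.uniform(margin, dur - margin)
            if all(abs(t - u) >= self.min_separation for u in times):
                times.append(t)
        times.sort()
        events = []
        for t in times:
            events.append(
                EventSpec(
                    t_neg=t,
                    center_channel=str(rng.choice(self.center_labels)),
                    spatial_radius=float(
                        np.clip(rng.normal(self.radius_mean, self.radius_sd), 5.0, 110.0)
                    ),
                    amplitude=float(
                        max(rng.normal(self.amplitude, self.amplitude_sd), 0.5)
                    ),
                    freq=float(rng.uniform(5.2, 6.8)),
                )
            )
        return events


def gen_session(
    spec: SessionSpec, montage: Montage, seed: int
) -> tuple[Recording, list[EventSpec]]:
    """One recording with injected events; deterministic per seed."""
    rng = np.random.default_rng(seed)
    bg = replace(spec.background, seed=int(rng.integers(2**31)))
    rec = gen_background(bg, montage)
    events = spec.sample_events(rng)
    return inject_events(rec, events)[0], events


def gen_condition_pair(
    earth_spec: SessionSpec,
    space_spec: SessionSpec,
    n_subjects: int,
    seed: int,
    montage: Montage | None = None,
    subject_radius_sd: float = 1.5,
) -> dict[int, dict[str, tuple[Recording, list[EventSpec]]]]:
    """Paired Earth/space-style sessions per synthetic subject.

    Each subject gets a random radius offset applied to *both* conditions
    (random-intercept structure), so the condition contrast is identified
    while subjects differ in baseline globality.  Deterministic per seed.
    """
    if n_subjects < 2:
        raise ValueError("paired statistics need at least 2 subjects")
    if montage is None:
        montage = build_neighbors(standard_montage(ANALYSIS_56))
    root = np.random.SeedSequence(seed)
    subj_seeds = root.spawn(n_subjects)
    out: dict[int, dict[str, tuple[Recording, list[EventSpec]]]] = {}
    for s, ss in enumerate(subj_seeds):
        child = np.random.default_rng(ss)
        offset = float(child.normal(0.0, subject_radius_sd))
        sessions = {}
        for name, cspec in (("earth", earth_spec), ("space", space_spec)):
            shifted = replace(cspec, radius_mean=cspec.radius_mean + offset)
            sessions[name] = gen_session(shifted, montage, int(child.integers(2**31)))
        out[s] = sessions
    return out


def radius_for_globality(
    target_pct: float,
    montage: Montage,
    center_labels: tuple[str, ...],
    n_analyzed: int | None = None,
    radius_jitter_sd: float = 0.0,
    plateau: float = 0.8,
    min_weight: float = 0.3,
) -> float:
    """Spatial radius whose mean ground-truth globality hits ``target_pct``.

    Inverts the purely geometric map radius -> mean (over candidate
    centers) ground-truth involved fraction (channels with taper weight
    >= ``min_weight``, i.e. within the effective involvement radius).
    When the generator draws radii with Gaussian jitter around the mean
    (per-event scatter and/or per-subject offsets), pass the total
    jitter SD so the map is convolved with it first — the count
    function is a nonlinear staircase, so jitter shifts its mean.
    """
    n = len(montage.labels) if n_analyzed is None else n_analyzed
    # taper(d) >= min_weight  <=>  d <= eff * radius
    eff = plateau + (1.0 - plateau) * (2.0 / np.pi) * np.arccos(min_weight)
    radii = np.linspace(2.0, 130.0, 1024)
    dists = np.stack(
        [montage.angles_from(c, montage.labels) for c in center_labels]
    )  # centers x channels
    counts = (dists[:, :, None] <= eff * radii[None, None, :]).sum(axis=1).mean(axis=0)
    pct = 100.0 * counts / n
    if radius_jitter_sd > 0:
        step = radii[1] - radii[0]
        half = int(np.ceil(4 * radius_jitter_sd / step))
        kern = np.exp(-0.5 * (np.arange(-half, half + 1) * step / radius_jitter_sd) ** 2)
        kern /= kern.sum()
        pct = np.convolve(np.pad(pct, half, mode="edge"), kern, mode="valid")
    return float(np.interp(target_pct, pct, radii))
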