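"""End-to-end orchestration: simulate -> preprocess -> topo -> detect -> stats.

``run_session`` takes one recording through conditioning, theta
topography, event detection and (when trials are present) behavioral
linkage, returning a JSON-serializable report with full bookkeeping
(usable minutes, rejected channels, per-area thresholds, densities).
``compare_conditions`` runs paired condition sets through the
topographic permutation test and the globality/amplitude/density
contrasts.  Recovery helpers match detections to synthetic ground truth
for parameter-recovery studies.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from . import behavior_stats as bs
from .events import AreaSet, DetectionParams, compute_threshold, detect_all, theta_filter
from .montage_io import ANALYSIS_56, build_neighbors, standard_montage
from .preprocess import (
    PreprocParams,
    average_reference,
    bandpass_resample,
    detect_bad_channels,
    interpolate_channels,
    zscore_channels,
)
from .spectral import SpectralParams, band_topography
from .synthetic_data import EventSpec, event_truth_globality, expected_event_amplitude
from .types import EventRecord, Montage, Recording, TrialRecord

__all__ = [
    "RunConfig",
    "prepare_recording",
    "run_session",
    "compare_conditions",
    "match_events",
    "matched_event_metrics",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Bundle of all stage parameters plus seeds, hashed into reports."""

    preproc: PreprocParams = field(default_factory=PreprocParams)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    fix_central_overlap: bool = True
    neighbor_max_angle: float = 25.0
    use_prsa: bool = False
    seed: int = 0
    mode: str = "single-session"

    def areas(self) -> AreaSet:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return AreaSet.default(fix_central_overlap=self.fix_central_overlap)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "preproc": asdict(self.preproc),
                "spectral": asdict(self.spectral),
                "detection": asdict(self.detection),
                "fix_central_overlap": self.fix_central_overlap,
                "neighbor_max_angle": self.neighbor_max_angle,
                "use_prsa": self.use_prsa,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def prepare_recording(
    rec: Recording, montage: Montage, cfg: RunConfig
) -> tuple[Recording, dict[str, Any]]:
    """Condition a recording for analysis; returns (recording, log).

    Voltage recordings go through band-pass + downsampling, muscle-band
    bad-channel rejection, interpolation, average re-referencing and
    z-scoring.  Recordings already in z units (e.g. synthetic) are only
    re-referenced.  Stages that do not apply are skipped and logged.
    """
    log: dict[str, Any] = {"stages": [], "rejected_channels": []}
    if rec.unit_state == "volts":
        if rec.fs > cfg.preproc.fs_out:
            rec = bandpass_resample(rec, cfg.preproc)
            log["stages"].append("bandpass_resample")
        if rec.usable_seconds >= 60.0:
            bad = detect_bad_channels(rec, cfg.preproc)
            if bad:
                rec = rec.copy()
                rec.bad_channels |= bad
                log["rejected_channels"] = sorted(bad)
                rec = interpolate_channels(rec, montage)
                log["stages"].append("interpolate_channels")
        if rec.reference == "earlobe":
            rec = average_reference(rec)
            log["stages"].append("average_reference")
        rec = zscore_channels(rec)
        log["stages"].append("zscore_channels")
    elif rec.reference == "earlobe":
        rec = average_reference(rec)
        log["stages"].append("average_reference")
    log["usable_minutes"] = rec.usable_seconds / 60.0
    return rec, log


def run_session(
    rec: Recording,
    cfg: RunConfig | None = None,
    montage: Montage | None = None,
    trials: list[TrialRecord] | None = None,
    truth: list[EventSpec] | None = None,
) -> dict[str, Any]:
    """Analyze one session; deterministic given inputs and config.

    The report carries usable minutes, rejected channels, per-area
    thresholds and densities, event summaries, the normalized theta
    topography, reaction-time statistics when trials are given, and
    ground-truth recovery metrics when truth is given.
    """
    cfg = cfg or RunConfig()
    if montage is None:
        montage = build_neighbors(standard_montage(rec.labels), cfg.neighbor_max_angle)
    rec, log = prepare_recording(rec, montage, cfg)
    areas = cfg.areas()

    try:
        topo = band_topography(rec, cfg.spectral, use_prsa=cfg.use_prsa)
    except ValueError as exc:  # degenerate input (e.g. silent recording)
        logger.warning("topography skipped: %s", exc)
        topo = None
    events, density = detect_all(rec, areas, montage, cfg.detection)

    thresholds = {}
    for name, area in areas.areas.items():
        idx = [rec.labels.index(l) for l in area]
        refsig = theta_filter(rec.data[idx].mean(axis=0), rec.fs, cfg.detection)
        thresholds[name] = compute_threshold(refsig, cfg.detection, mask=rec.artifact_mask)

    report: dict[str, Any] = {
        "config_hash": cfg.config_hash(),
        "preprocessing": log,
        "thresholds": thresholds,
        "n_events": len(events),
        "density_per_min": density,
        "mean_amplitude_z": float(np.mean([e.amplitude_z for e in events])) if events else 0.0,
        "mean_globality_pct": float(np.mean([e.globality_pct for e in events])) if events else 0.0,
        "theta_topography": None
        if topo is None
        else {
            "labels": topo.labels,
            "values": topo.values.tolist(),
            "band": list(topo.band),
        },
    }

    if trials is not None:
        flagged, counts = bs.filter_rts(trials)
        summaries = bs.events_near_stimulus(events, flagged)
        report["behavior"] = {"exclusions": counts}
        try:
            reg = bs.regress_rt_on_globality(summaries, flagged)
            report["behavior"]["rt_on_globality"] = asdict(reg)
        except ValueError as exc:
            logger.warning("RT regression skipped: %s", exc)
            report["behavior"]["rt_on_globality"] = None

    if truth is not None:
        report["recovery"] = matched_event_metrics(events, truth, montage, rec)

    report["_events"] = events
    report["_topo"] = topo
    return report


def match_events(
    events: list[EventRecord],
    truth: list[EventSpec],
    tol_s: float = 0.02,
) -> dict[int, EventRecord]:
    """Match detections to ground-truth events by trough time.

    For each truth event, the detection with t_neg within ``tol_s``
    and the largest globality (events may surface in several areas)
    is selected.  Unmatched detections are background threshold
    crossings — an expected output of a relative-threshold detector.
    """
    ttimes = np.array([e.t_neg for e in truth])
    best: dict[int, EventRecord] = {}
    for e in events:
        if not len(ttimes):
            break
        j = int(np.argmin(np.abs(ttimes - e.t_neg)))
        if abs(ttimes[j] - e.t_neg) <= tol_s:
            if j not in best or e.globality_pct > best[j].globality_pct:
                best[j] = e
    return best


def matched_event_metrics(
    events: list[EventRecord],
    truth: list[EventSpec],
    montage: Montage,
    rec: Recording,
    amplitude_oracle: bool = True,
) -> dict[str, Any]:
    """Recovery metrics of detections against injected ground truth."""
    matched = match_events(events, truth)
    n_analyzed = len([l for l in rec.labels if l not in rec.bad_channels])
    terr, gerr, aerr, globs = [], [], [], []
    for j, e in matched.items():
        tg = event_truth_globality(truth[j], montage, n_analyzed)
        terr.append(abs(e.t_neg - truth[j].t_neg) * 1000.0)
        gerr.append((e.globality_pct - tg) * n_analyzed / 100.0)
        globs.append(e.globality_pct)
        if amplitude_oracle:
            a_true = expected_event_amplitude(truth[j], rec.labels, rec.fs)
            aerr.append(abs(e.amplitude_z - a_true))
    return {
        "n_truth": len(truth),
        "n_matched": len(matched),
        "recovered_frac": len(matched) / len(truth) if truth else 1.0,
        "t_err_ms": terr,
        "globality_err_channels": gerr,
        "amplitude_abs_err_z": aerr,
        "matched_mean_globality_pct": float(np.mean(globs)) if globs else 0.0,
    }


def compare_conditions(
    sessions: dict[Any, dict[str, dict[str, Any]]],
    cfg: RunConfig | None = None,
    montage: Montage | None = None,
    n_perm: int = 32,
) -> dict[str, Any]:
    """Paired condition comparison across subjects.

    ``sessions`` maps subject -> condition -> {"rec": Recording,
    optionally "truth": [EventSpec], "trials": [TrialRecord]}.  Emits
    globality / amplitude / density contrasts (matched-to-truth
    globality when truth is available), the paired theta-topography
    test with permutation cluster correction, and reaction-time
    analyses when trials are present.
    """
    cfg = cfg or RunConfig(mode="condition-compare")
    subjects = sorted(sessions)
    conds = sorted({c for s in subjects for c in sessions[s]})
    any_rec = next(iter(sessions[subjects[0]].values()))["rec"]
    if montage is None:
        montage = build_neighbors(standard_montage(any_rec.labels), cfg.neighbor_max_angle)

    measures: dict[str, dict[str, dict[str, float]]] = {
        m: {s: {} for s in subjects}
        for m in ("globality", "amplitude", "density", "matched_globality")
    }
    topos: dict[str, list] = {c: [] for c in conds}
    trials_by_cond: dict[str, dict[str, list[TrialRecord]]] = {c: {} for c in conds}
    unbalanced = []

    for s in subjects:
        for c in conds:
            if c not in sessions[s]:
                unbalanced.append((s, c))
                continue
            bundle = sessions[s][c]
            rep = run_session(
                bundle["rec"], cfg, montage,
                trials=bundle.get("trials"), truth=bundle.get("truth"),
            )
            measures["globality"][s][c] = rep["mean_globality_pct"]
            measures["amplitude"][s][c] = rep["mean_amplitude_z"]
            measures["density"][s][c] = float(np.mean(list(rep["density_per_min"].values())))
            if "recovery" in rep:
                measures["matched_globality"][s][c] = rep["recovery"][
                    "matched_mean_globality_pct"
                ]
            if rep["_topo"] is not None:
                topos[c].append(rep["_topo"])
            if bundle.get("trials") is not None:
                flagged, _ = bs.filter_rts(bundle["trials"])
                trials_by_cond[c][str(s)] = flagged
    if unbalanced:
        logger.warning("unbalanced design; missing cells: %s", unbalanced)

    report: dict[str, Any] = {"subjects": [str(s) for s in subjects], "conditions": conds}
    report["contrasts"] = {}
    for m, vals in measures.items():
        complete = {s: v for s, v in vals.items() if len(v) == len(conds)}
        if len(complete) >= 2 and conds and all(len(v) for v in complete.values()):
            try:
                report["contrasts"][m] = {
                    f"{a}->{b}": asdict(r)
                    for (a, b), r in bs.condition_contrast(complete).items()
                }
            except ValueError:
                pass

    # paired topographic test between the first two conditions
    if len(conds) >= 2 and all(len(topos[c]) == len(subjects) for c in conds[:2]):
        res = bs.paired_topo_test(topos[conds[0]], topos[conds[1]])
        res = bs.permutation_cluster_correct(
            res, montage, n_perm=min(n_perm, 2 ** len(subjects))
        )
        report["topo_test"] = {
            "cond_a": conds[0],
            "cond_b": conds[1],
            "t_map": res.t_map.tolist(),
            "p_map": res.p_map.tolist(),
            "sig_mask": res.sig_mask.tolist(),
            "min_cluster": res.min_cluster,
        }

    # reaction-time median split across all sessions
    all_sessions = {
        f"{c}/{s}": tr for c in conds for s, tr in trials_by_cond[c].items()
    }
    if all_sessions:
        try:
            med = bs.pooled_median_rt(all_sessions)
            pam = bs.percent_above_median(all_sessions, med)
            per_cond = {
                c: {s: pam[f"{c}/{s}"] for s in trials_by_cond[c] if f"{c}/{s}" in pam}
                for c in conds
            }
            report["reaction_time"] = {
                "pooled_median_ms": med,
                "pct_above_median": per_cond,
            }
        except ValueError as exc:
            logger.warning("RT section omitted: %s", exc)
    return report
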