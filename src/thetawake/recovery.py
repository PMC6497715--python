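"""Parameter-recovery harnesses: the pipeline's full-recovery mode.

Each harness generates synthetic sessions with known ground truth,
runs the full analysis chain, and measures how well the pipeline
recovers what was injected: event times, globality and amplitude;
Earth-to-space-style condition shifts in mean globality; the linear
reaction-time/globality coupling; and the type-I error of the
permutation cluster test.  Problem sizes are chosen so each harness
runs in minutes on one core; all randomness derives from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import stats

from . import behavior_stats as bs
from .events import AreaSet, detect_all
from .montage_io import ANALYSIS_56, build_neighbors, standard_montage
from .pipeline import compare_conditions, match_events
from .preprocess import average_reference
from .behavior_stats import TopoStatResult, permutation_cluster_correct
from .synthetic_data import (
    BackgroundSpec,
    EventSpec,
    SessionSpec,
    TrialGenSpec,
    event_truth_globality,
    expected_event_amplitude,
    gen_condition_pair,
    gen_session,
    gen_trials,
    radius_for_globality,
)
from .types import EventRecord, Montage

__all__ = [
    "RecoveryConditions",
    "event_recovery",
    "condition_shift_recovery",
    "regression_recovery",
    "regression_null_calibration",
    "cluster_type1_error",
    "truth_event_records",
]

#: study-scale conditions of the recovery harnesses: short quiet-background
#: sessions with theta events of ~10-channel extent and >= 3 z troughs.
FRONTAL_CENTERS = ("Fz", "F1", "F2", "AFz")
ALL_CENTERS = (
    "Fz", "AFz", "F1", "F2", "FCz", "FC1", "FC2", "CPz", "Pz", "P1", "P2", "POz",
)


@dataclass(frozen=True)
class RecoveryConditions:
    """Fixed study conditions for the recovery harnesses."""

    fs: float = 256.0
    duration: float = 90.0
    background_sd: float = 0.1
    n_events: int = 30
    radius_mean: float = 30.0
    radius_sd: float = 2.0
    amplitude: float = 3.5
    amplitude_sd: float = 0.2
    subject_radius_sd: float = 1.5

    def background(self, seed: int) -> BackgroundSpec:
        return BackgroundSpec(
            n_channels=56,
            fs=self.fs,
            duration=self.duration,
            amplitude_sd=self.background_sd,
            unit="zscored",
            seed=seed,
        )

    def session(self, centers: tuple[str, ...]) -> SessionSpec:
        return SessionSpec(
            background=self.background(0),
            n_events=self.n_events,
            radius_mean=self.radius_mean,
            radius_sd=self.radius_sd,
            amplitude=self.amplitude,
            amplitude_sd=self.amplitude_sd,
            center_labels=centers,
        )


def _montage() -> Montage:
    return build_neighbors(standard_montage(ANALYSIS_56))


def event_recovery(
    n_seeds: int = 20,
    seed: int = 0,
    conditions: RecoveryConditions = RecoveryConditions(),
) -> dict[str, Any]:
    """Detection recovery of injected frontal theta events, per seed.

    Injects ``n_events`` frontal events (trough >= 3 z) on a quiet
    background, runs the full detector, matches detections to ground
    truth, and pools timing error, globality error (channels) and
    amplitude error (z, against the noise-free forward model) over
    seeds.
    """
    mont = _montage()
    areas = _areas()
    recovered, t_err, g_err, a_err, frontal_frac = [], [], [], [], []
    root = np.random.SeedSequence(seed)
    for ss in root.spawn(n_seeds):
        rng = np.random.default_rng(ss)
        spec = conditions.session(FRONTAL_CENTERS)
        rec, truth = gen_session(spec, mont, int(rng.integers(2**31)))
        rec = average_reference(rec)
        events, _ = detect_all(rec, areas, mont)
        matched = match_events(events, truth)
        recovered.append(len(matched) / len(truth))
        frontal = match_events([e for e in events if e.area == "frontal"], truth)
        frontal_frac.append(len(frontal) / len(truth))
        for j, e in matched.items():
            t_err.append(abs(e.t_neg - truth[j].t_neg) * 1000.0)
            tg = event_truth_globality(truth[j], mont)
            g_err.append((e.globality_pct - tg) * len(mont.labels) / 100.0)
            a_true = expected_event_amplitude(truth[j], rec.labels, rec.fs)
            a_err.append(abs(e.amplitude_z - a_true))
    return {
        "n_seeds": n_seeds,
        "recovered_frac": float(np.mean(recovered)),
        "recovered_frac_frontal": float(np.mean(frontal_frac)),
        "t_err_ms_max": float(np.max(t_err)),
        "t_err_ms_mean": float(np.mean(t_err)),
        "globality_mae_channels": float(np.mean(np.abs(g_err))),
        "globality_bias_channels": float(np.mean(g_err)),
        "amplitude_mae_z": float(np.mean(a_err)),
    }


def _areas() -> AreaSet:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return AreaSet.default(fix_central_overlap=True)


def condition_shift_recovery(
    n_seeds: int = 20,
    seed: int = 0,
    n_subjects: int = 5,
    shift_pct: float = 4.0,
    base_pct: float = 17.0,
    conditions: RecoveryConditions = RecoveryConditions(n_events=40),
) -> dict[str, Any]:
    """Recovery of an Earth-to-space globality shift via paired contrast.

    Earth and space session specs differ only in the event radius,
    calibrated geometrically (accounting for radius jitter) so the
    designed ground-truth mean globality shift is ``shift_pct``
    percentage points.  Per seed, paired sessions for ``n_subjects``
    subjects run through the full pipeline; the matched-event mean
    globality enters the paired contrast.
    """
    mont = _montage()
    jitter = float(np.hypot(conditions.radius_sd, conditions.subject_radius_sd))
    r_earth = radius_for_globality(base_pct, mont, ALL_CENTERS, radius_jitter_sd=jitter)
    r_space = radius_for_globality(
        base_pct + shift_pct, mont, ALL_CENTERS, radius_jitter_sd=jitter
    )
    base = conditions.session(ALL_CENTERS)
    earth = replace(base, radius_mean=r_earth)
    space = replace(base, radius_mean=r_space)

    shifts, tvals, truth_shifts = [], [], []
    root = np.random.SeedSequence(seed)
    for ss in root.spawn(n_seeds):
        sub_seed = int(np.random.default_rng(ss).integers(2**31))
        pairs = gen_condition_pair(
            earth, space, n_subjects=n_subjects, seed=sub_seed, montage=mont,
            subject_radius_sd=conditions.subject_radius_sd,
        )
        sessions = {
            s: {c: {"rec": rec, "truth": tr} for c, (rec, tr) in d.items()}
            for s, d in pairs.items()
        }
        rep = compare_conditions(sessions, montage=mont)
        c = rep["contrasts"]["matched_globality"]["earth->space"]
        shifts.append(c["mean_diff"])
        tvals.append(c["t"])
        truth_shifts.append(
            float(
                np.mean(
                    [
                        np.mean([event_truth_globality(e, mont) for e in pairs[s]["space"][1]])
                        - np.mean([event_truth_globality(e, mont) for e in pairs[s]["earth"][1]])
                        for s in pairs
                    ]
                )
            )
        )
    return {
        "n_seeds": n_seeds,
        "designed_shift_pct": shift_pct,
        "radius_earth_deg": r_earth,
        "radius_space_deg": r_space,
        "recovered_shift_pct_mean": float(np.mean(shifts)),
        "recovered_shift_pct_per_seed": [float(s) for s in shifts],
        "truth_shift_pct_mean": float(np.mean(truth_shifts)),
        "positive_t_count": int(np.sum(np.array(tvals) > 0)),
    }


def truth_event_records(
    truth: list[EventSpec], montage: Montage, n_analyzed: int | None = None
) -> list[EventRecord]:
    """Ground-truth events as EventRecords (for generator-level stats)."""
    out = []
    for e in truth:
        inv = e.involved_labels(montage)
        out.append(
            EventRecord(
                area="truth",
                t_neg=e.t_neg,
                t_pos_prev=e.t_neg - 0.5 / e.freq,
                t_pos_next=e.t_neg + 0.5 / e.freq,
                amplitude_z=e.amplitude,
                involved=inv,
                globality_pct=event_truth_globality(e, montage, n_analyzed),
            )
        )
    return out


def _trial_harness_truth(
    rng: np.random.Generator,
    n_trials: int,
    iti: float,
    montage: Montage,
    p_event: float = 0.6,
) -> tuple[list[EventSpec], float]:
    """Events placed in a fraction of peristimulus windows, varied radius."""
    session_dur = (n_trials + 1) * iti
    truth = []
    for i in range(n_trials):
        if rng.random() < p_event:
            stim = (i + 0.5) * iti  # jitter applied inside gen_trials
            t = stim + rng.uniform(-0.2, 0.4)
            truth.append(
                EventSpec(
                    t_neg=t,
                    center_channel=str(rng.choice(ALL_CENTERS)),
                    spatial_radius=float(rng.uniform(15.0, 55.0)),
                    amplitude=3.5,
                )
            )
    return truth, session_dur


def regression_recovery(
    seed: int = 0,
    n_trials: int = 237,
    beta: float = 2.0,
    noise_sd: float = 40.0,
) -> dict[str, Any]:
    """OLS recovery of the reaction-time/globality coupling at study size."""
    mont = _montage()
    rng = np.random.default_rng(seed)
    truth, session_dur = _trial_harness_truth(rng, n_trials, iti=6.0, montage=mont)
    spec = TrialGenSpec(
        n_trials=n_trials, beta=beta, noise_sd=noise_sd, iti=6.0,
        seed=int(rng.integers(2**31)),
    )
    trials = gen_trials(truth, spec, session_dur, mont)
    flagged, _ = bs.filter_rts(trials)
    records = truth_event_records(truth, mont)
    summaries = bs.events_near_stimulus(records, flagged)
    reg = bs.regress_rt_on_globality(summaries, flagged)
    return {
        "beta_true": beta,
        "beta_hat": reg.slope,
        "beta_se": reg.slope_se,
        "within_2se": bool(abs(reg.slope - beta) <= 2 * reg.slope_se),
        "r2_adj": reg.r2_adj,
        "F": reg.F,
        "df": reg.df,
        "p": reg.p,
    }


def regression_null_calibration(
    n_seeds: int = 1000, seed: int = 0, n_trials: int = 200, alpha: float = 0.05
) -> dict[str, Any]:
    """Rejection rate of the slope test under zero coupling."""
    mont = _montage()
    root = np.random.SeedSequence(seed)
    rejections = 0
    used = 0
    for ss in root.spawn(n_seeds):
        rng = np.random.default_rng(ss)
        truth, session_dur = _trial_harness_truth(rng, n_trials, iti=6.0, montage=mont)
        spec = TrialGenSpec(
            n_trials=n_trials, beta=0.0, noise_sd=40.0, iti=6.0,
            seed=int(rng.integers(2**31)),
        )
        trials = gen_trials(truth, spec, session_dur, mont)
        flagged, _ = bs.filter_rts(trials)
        records = truth_event_records(truth, mont)
        summaries = bs.events_near_stimulus(records, flagged)
        try:
            reg = bs.regress_rt_on_globality(summaries, flagged)
        except ValueError:
            continue
        used += 1
        rejections += reg.p < alpha
    return {
        "n_experiments": used,
        "alpha": alpha,
        "rejection_rate": rejections / used if used else float("nan"),
    }


def cluster_type1_error(
    n_experiments: int = 500,
    seed: int = 0,
    n_subjects: int = 5,
    n_perm: int = 32,
) -> dict[str, Any]:
    """Family-wise error of the permutation cluster test under the null.

    Zero-mean Gaussian per-subject difference maps on the 56-channel
    montage; an experiment counts as a false positive when any cluster
    survives correction.
    """
    mont = _montage()
    n_ch = len(mont.labels)
    rng = np.random.default_rng(seed)
    fw = 0
    for _ in range(n_experiments):
        diffs = rng.standard_normal((n_subjects, n_ch))
        mean = diffs.mean(axis=0)
        sd = diffs.std(axis=0, ddof=1)
        t_map = mean / (sd / np.sqrt(n_subjects))
        p_map = 2 * stats.t.sf(np.abs(t_map), df=n_subjects - 1)
        res = TopoStatResult(
            labels=list(mont.labels), t_map=t_map, p_map=p_map, diffs=diffs
        )
        res = permutation_cluster_correct(res, mont, n_perm=n_perm)
        fw += bool(res.sig_mask.any())
    return {
        "n_experiments": n_experiments,
        "fwer": fw / n_experiments,
    }
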