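"""Reaction-time processing, event-behavior linkage, and statistics.

Covers the behavioral exclusion rules (false starts < 100 ms, outliers
> 500 ms), the pooled-median split, the peristimulus event window
(-250 ms to +500 ms around the stimulus), ordinary least-squares
regression of reaction time on event globality, channel-wise paired
t-topographies with sign-flip permutation cluster correction, and
paired condition contrasts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import BandTopography, EventRecord, Montage, TrialRecord

__all__ = [
    "RegressionResult",
    "TopoStatResult",
    "ContrastResult",
    "TrialEventSummary",
    "filter_rts",
    "pooled_median_rt",
    "percent_above_median",
    "events_near_stimulus",
    "regress_rt_on_globality",
    "paired_topo_test",
    "permutation_cluster_correct",
    "condition_contrast",
]

RT_VALID_MS = (100.0, 500.0)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2_adj: float
    F: float
    df: int
    p: float
    slope_se: float


@dataclass
class TopoStatResult:
    labels: list[str]
    t_map: np.ndarray
    p_map: np.ndarray
    diffs: np.ndarray  # subjects x channels, for permutation
    df: int = 0
    sig_mask: np.ndarray | None = None
    min_cluster: int | None = None


@dataclass(frozen=True)
class ContrastResult:
    cond_a: str
    cond_b: str
    mean_diff: float
    sem: float
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class TrialEventSummary:
    trial_id: int
    n_events: int
    max_globality: float
    mean_globality: float
    eventless: bool


def filter_rts(
    trials: list[TrialRecord],
) -> tuple[list[TrialRecord], dict[str, int]]:
    """Set validity flags: valid iff 100 ms <= RT <= 500 ms.

    Reaction times below 100 ms are anticipated movements (false
    starts); above 500 ms they are outliers.  Returns flagged copies
    and exclusion counts per reason.
    """
    lo, hi = RT_VALID_MS
    out = []
    counts = {"false_start": 0, "outlier": 0, "valid": 0}
    for t in trials:
        valid = lo <= t.rt <= hi
        if t.rt < lo:
            counts["false_start"] += 1
        elif t.rt > hi:
            counts["outlier"] += 1
        else:
            counts["valid"] += 1
        out.append(
            TrialRecord(
                trial_id=t.trial_id,
                stim_time=t.stim_time,
                rt=t.rt,
                outcome=t.outcome,
                valid=valid,
            )
        )
    return out, counts


def pooled_median_rt(sessions: dict[str, list[TrialRecord]]) -> float:
    """Median RT over all valid trials pooled across sessions."""
    rts = [t.rt for trials in sessions.values() for t in trials if t.valid]
    if not rts:
        raise ValueError("no valid trials to pool")
    return float(np.median(rts))


def percent_above_median(
    sessions: dict[str, list[TrialRecord]], global_median: float
) -> dict[str, float]:
    """Per-session percentage of valid RTs strictly above the pooled median.

    Ties at the median count as not-above.  Sessions with no valid
    trials are excluded with a warning.
    """
    out: dict[str, float] = {}
    for name, trials in sessions.items():
        valid = [t.rt for t in trials if t.valid]
        if not valid:
            warnings.warn(f"session {name!r} has no valid trials; excluded", stacklevel=2)
            continue
        out[name] = 100.0 * sum(rt > global_median for rt in valid) / len(valid)
    return out


def events_near_stimulus(
    events: list[EventRecord], trials: list[TrialRecord]
) -> list[TrialEventSummary]:
    """Per-trial globality summary over the window [stim-0.25 s, stim+0.5 s).

    The window spans motor-action planning (250 ms before the stimulus)
    through the maximal reaction time (500 ms after).  Trials with no
    event in the window get zero summaries and an ``eventless`` flag.
    """
    times = np.array([e.t_neg for e in events])
    globs = np.array([e.globality_pct for e in events])
    out = []
    for t in trials:
        if len(events):
            sel = (times >= t.stim_time - 0.25) & (times < t.stim_time + 0.5)
            g = globs[sel]
        else:
            g = np.array([])
        out.append(
            TrialEventSummary(
                trial_id=t.trial_id,
                n_events=int(len(g)),
                max_globality=float(g.max()) if len(g) else 0.0,
                mean_globality=float(g.mean()) if len(g) else 0.0,
                eventless=len(g) == 0,
            )
        )
    return out


def regress_rt_on_globality(
    summaries: list[TrialEventSummary],
    trials: list[TrialRecord],
    use: str = "max_globality",
) -> RegressionResult:
    """OLS of valid reaction times on peristimulus event globality.

    Reports the adjusted R-squared, the F-test of zero slope (df =
    n - 2) and its two-sided p-value.
    """
    import statsmodels.api as sm

    by_id = {s.trial_id: s for s in summaries}
    x, y = [], []
    for t in trials:
        if t.valid and t.trial_id in by_id:
            x.append(getattr(by_id[t.trial_id], use))
            y.append(t.rt)
    if len(x) < 10:
        raise ValueError(f"need >= 10 valid trials with summaries, got {len(x)}")
    x = np.asarray(x)
    if np.ptp(x) == 0:
        raise ValueError("globality predictor has zero variance")
    X = sm.add_constant(x)
    fit = sm.OLS(np.asarray(y), X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2_adj=float(fit.rsquared_adj),
        F=float(fit.fvalue),
        df=int(fit.df_resid),
        p=float(fit.f_pvalue),
        slope_se=float(fit.bse[1]),
    )


def paired_topo_test(
    topos_a: list[BandTopography], topos_b: list[BandTopography]
) -> TopoStatResult:
    """Channel-wise two-tailed paired t-test across subjects (B - A).

    df = n_subjects - 1.  Channels with zero-variance differences get
    +-inf t and p = 0 (degenerate but unambiguous).
    """
    if len(topos_a) != len(topos_b) or len(topos_a) < 2:
        raise ValueError("need matched topographies for >= 2 subjects")
    labels = topos_a[0].labels
    for t in itertools.chain(topos_a, topos_b):
        if t.labels != labels:
            raise ValueError("topographies cover different channel sets")
    A = np.stack([t.values for t in topos_a])
    B = np.stack([t.values for t in topos_b])
    diffs = B - A
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map = mean / (sd / np.sqrt(n))
        t_map = np.where(sd == 0, np.sign(mean) * np.inf, t_map)
    t_map = np.where((sd == 0) & (mean == 0), 0.0, t_map)
    p_map = 2 * stats.t.sf(np.abs(t_map), df=n - 1)
    return TopoStatResult(
        labels=list(labels), t_map=t_map, p_map=p_map, diffs=diffs, df=n - 1
    )


def _clusters(
    sig: np.ndarray, signs: np.ndarray, labels: list[str], montage: Montage
) -> list[set[int]]:
    """Connected components of significant same-sign channels."""
    index = {lab: i for i, lab in enumerate(labels)}
    unvisited = set(np.flatnonzero(sig))
    comps = []
    while unvisited:
        seed = unvisited.pop()
        comp = {seed}
        queue = [seed]
        while queue:
            i = queue.pop()
            for nb in montage.neighbor_map.get(labels[i], set()):
                j = index.get(nb)
                if j in unvisited and signs[j] == signs[seed]:
                    unvisited.discard(j)
                    comp.add(j)
                    queue.append(j)
        comps.append(comp)
    return comps


def permutation_cluster_correct(
    result: TopoStatResult,
    montage: Montage,
    n_perm: int = 32,
    alpha: float = 0.05,
    cluster_floor: int = 3,
    seed: int = 0,
) -> TopoStatResult:
    """Sign-flip permutation cluster correction of a paired topography test.

    Under exchangeability of condition order, each subject's difference
    map may flip sign; all ``2^n`` flips are enumerated when ``n_perm``
    equals that count (the identity flip included).  For each flip the
    channel-wise paired t-map is thresholded at uncorrected two-sided
    ``alpha``, and the size of the largest same-sign neighbor-connected
    cluster enters the null.  The minimum significant cluster size is
    the 95th percentile of that null, floored at ``cluster_floor`` (at
    least three neighboring electrodes).  Observed clusters meeting it
    form ``sig_mask``.
    """
    diffs = result.diffs
    n, n_ch = diffs.shape
    if n_perm > 2**n:
        raise ValueError(f"n_perm={n_perm} exceeds 2^{n} possible sign flips")
    if n_perm == 2**n:
        flips = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice((1.0, -1.0), size=(n_perm, n))
        flips[0] = 1.0  # identity always included
    t_crit = stats.t.ppf(1 - alpha / 2, df=n - 1)

    def max_cluster(d: np.ndarray) -> int:
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
            t = np.where(sd == 0, np.sign(mean) * np.inf, t)
        sig = np.abs(t) > t_crit
        if not sig.any():
            return 0
        comps = _clusters(sig, np.sign(t), result.labels, montage)
        return max(len(c) for c in comps)

    null_sizes = np.array([max_cluster(diffs * f[:, None]) for f in flips])
    min_cluster = int(
        max(cluster_floor, np.quantile(null_sizes, 0.95, method="higher"))
    )

    sig = result.p_map < alpha
    mask = np.zeros(n_ch, dtype=bool)
    if sig.any():
        for comp in _clusters(sig, np.sign(result.t_map), result.labels, montage):
            if len(comp) >= min_cluster:
                mask[list(comp)] = True
    result.sig_mask = mask
    result.min_cluster = min_cluster
    return result


def condition_contrast(
    values: dict[str, dict[str, float]]
) -> dict[tuple[str, str], ContrastResult]:
    """Paired contrasts between all condition pairs.

    ``values`` maps subject -> condition -> measure.  Every subject
    must have every condition (missing cells are an error listing
    subject and condition).  For each ordered pair (A, B) with A before
    B in sorted condition order, reports mean(B - A) +- sem, the paired
    t (df = n - 1) and its two-sided p.
    """
    subjects = sorted(values)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    conds = sorted({c for v in values.values() for c in v})
    if len(conds) < 2:
        raise ValueError("need at least 2 conditions")
    missing = [
        (s, c) for s in subjects for c in conds if c not in values[s]
    ]
    if missing:
        raise ValueError(f"missing subject/condition cells: {missing}")
    out: dict[tuple[str, str], ContrastResult] = {}
    for a, b in itertools.combinations(conds, 2):
        d = np.array([values[s][b] - values[s][a] for s in subjects])
        n = len(d)
        sem = float(d.std(ddof=1) / np.sqrt(n))
        if sem > 0:
            t = float(d.mean() / sem)
            p = float(2 * stats.t.sf(abs(t), df=n - 1))
        else:
            t = 0.0 if d.mean() == 0 else float(np.sign(d.mean()) * np.inf)
            p = 1.0 if d.mean() == 0 else 0.0
        out[(a, b)] = ContrastResult(
            cond_a=a, cond_b=b, mean_diff=float(d.mean()), sem=sem, t=t, df=n - 1, p=p
        )
    return out
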