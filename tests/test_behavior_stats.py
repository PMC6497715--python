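"""Reaction-time rules, event linkage, regression, topographic statistics."""

import numpy as np
import pytest
from scipy import stats

from thetawake import behavior_stats as bs
from thetawake.types import BandTopography, EventRecord, TrialRecord


def _trial(i, stim, rt, outcome="S"):
    return TrialRecord(trial_id=i, stim_time=stim, rt=rt, outcome=outcome)


def _event(t, glob=10.0):
    return EventRecord(
        area="frontal", t_neg=t, t_pos_prev=t - 0.08, t_pos_next=t + 0.08,
        amplitude_z=2.0, involved=frozenset({"Fz", "F1"}), globality_pct=glob,
    )


class TestFilterRts:
    @pytest.mark.parametrize(
        "rt,expected_valid",
        [(99.0, False), (100.0, True), (244.0, True), (500.0, True), (501.0, False)],
    )
    def test_validity_boundaries(self, rt, expected_valid):
        out, _ = bs.filter_rts([_trial(0, 1.0, rt)])
        assert out[0].valid is expected_valid

    def test_exclusion_counts(self):
        trials = [_trial(i, i * 2.0, rt) for i, rt in
                  enumerate([50, 99, 100, 300, 500, 501, 700])]
        _, counts = bs.filter_rts(trials)
        assert counts == {"false_start": 2, "outlier": 2, "valid": 3}


class TestMedianSplit:
    def test_all_at_median_gives_zero_percent(self):
        trials, _ = bs.filter_rts([_trial(i, i, 244.0) for i in range(5)])
        pct = bs.percent_above_median({"s": trials}, 244.0)
        assert pct["s"] == 0.0

    def test_half_above(self):
        trials, _ = bs.filter_rts([_trial(0, 0.0, 200.0), _trial(1, 2.0, 300.0)])
        pct = bs.percent_above_median({"s": trials}, 244.0)
        assert pct["s"] == 50.0

    def test_empty_session_excluded_with_warning(self):
        trials, _ = bs.filter_rts([_trial(0, 0.0, 700.0)])
        with pytest.warns(UserWarning, match="no valid"):
            pct = bs.percent_above_median({"bad": trials}, 244.0)
        assert "bad" not in pct

    def test_pooled_strictly_above_is_at_most_half(self, rng):
        sessions = {}
        for s in range(4):
            rts = rng.uniform(120, 480, size=50)
            sessions[str(s)], _ = bs.filter_rts(
                [_trial(i, i * 2.0, rt) for i, rt in enumerate(rts)]
            )
        med = bs.pooled_median_rt(sessions)
        all_rts = [t.rt for tr in sessions.values() for t in tr if t.valid]
        frac_above = np.mean([rt > med for rt in all_rts])
        assert frac_above <= 0.5


class TestEventsNearStimulus:
    def test_window_boundaries_half_open(self):
        trials, _ = bs.filter_rts([_trial(0, 10.0, 300.0)])
        at_start = [_event(10.0 - 0.25)]
        at_end = [_event(10.0 + 0.5)]
        assert bs.events_near_stimulus(at_start, trials)[0].n_events == 1
        assert bs.events_near_stimulus(at_end, trials)[0].n_events == 0

    def test_eventless_trials_flagged(self):
        trials, _ = bs.filter_rts([_trial(0, 10.0, 300.0)])
        out = bs.events_near_stimulus([], trials)
        assert out[0].eventless and out[0].max_globality == 0.0

    def test_max_and_mean_summaries(self):
        trials, _ = bs.filter_rts([_trial(0, 10.0, 300.0)])
        events = [_event(10.0, glob=10.0), _event(10.2, glob=30.0)]
        s = bs.events_near_stimulus(events, trials)[0]
        assert s.max_globality == 30.0
        assert s.mean_globality == 20.0
        assert s.n_events == 2


class TestRegression:
    def _linked(self, n, beta, noise, rng):
        trials = []
        summaries = []
        for i in range(n):
            g = float(rng.uniform(0, 40))
            rt = float(np.clip(250 + beta * g + rng.normal(0, noise), 100, 500))
            trials.append(_trial(i, i * 3.0, rt))
            summaries.append(
                bs.TrialEventSummary(trial_id=i, n_events=1, max_globality=g,
                                     mean_globality=g, eventless=False)
            )
        flagged, _ = bs.filter_rts(trials)
        return summaries, flagged

    def test_perfect_linear_relation(self, rng):
        summaries, trials = self._linked(50, 2.0, 0.0, rng)
        res = bs.regress_rt_on_globality(summaries, trials)
        assert res.r2_adj == pytest.approx(1.0, abs=1e-9)
        assert res.p < 1e-12
        assert res.slope == pytest.approx(2.0, abs=1e-9)
        assert res.df == 48

    def test_zero_variance_predictor_rejected(self):
        trials, _ = bs.filter_rts([_trial(i, i, 250.0) for i in range(20)])
        summaries = [
            bs.TrialEventSummary(trial_id=i, n_events=1, max_globality=5.0,
                                 mean_globality=5.0, eventless=False)
            for i in range(20)
        ]
        with pytest.raises(ValueError, match="variance"):
            bs.regress_rt_on_globality(summaries, trials)

    def test_too_few_trials_rejected(self, rng):
        summaries, trials = self._linked(5, 2.0, 10.0, rng)
        with pytest.raises(ValueError, match="10"):
            bs.regress_rt_on_globality(summaries, trials)

    def test_null_p_values_uniform(self):
        """Permuted globality against RT: p ~ U(0,1) (KS at alpha=0.01)."""
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(300):
            summaries, trials = self._linked(60, 0.0, 30.0, rng)
            pvals.append(bs.regress_rt_on_globality(summaries, trials).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def _topos(values_per_subject, labels):
    out = []
    for v in values_per_subject:
        v = np.asarray(v, float)
        out.append(BandTopography(labels=labels, values=v / v.mean(), band=(5, 7)))
    return out


class TestPairedTopoTest:
    def test_identical_conditions_give_zero_t(self, montage56, rng):
        labels = list(montage56.labels)
        vals = [rng.uniform(0.5, 1.5, 56) for _ in range(5)]
        a = _topos(vals, labels)
        b = _topos(vals, labels)
        res = bs.paired_topo_test(a, b)
        assert np.allclose(res.t_map, 0.0)
        assert res.df == 4

    def test_constant_offset_on_one_channel_gives_infinite_t(self, montage56):
        labels = list(montage56.labels)
        base = [np.ones(56) for _ in range(5)]
        shifted = []
        for v in base:
            u = v.copy()
            u[7] += 0.5
            shifted.append(u)
        res = bs.paired_topo_test(_topos(base, labels), _topos(shifted, labels))
        assert np.isinf(res.t_map[7]) and res.t_map[7] > 0

    def test_mismatched_channels_rejected(self, montage56):
        labels = list(montage56.labels)
        a = _topos([np.ones(56)] * 3, labels)
        other = labels[::-1]
        b = _topos([np.ones(56)] * 3, other)
        with pytest.raises(ValueError, match="channel"):
            bs.paired_topo_test(a, b)


class TestPermutationCluster:
    def _null_result(self, montage, rng, n=5):
        diffs = rng.standard_normal((n, len(montage.labels)))
        mean = diffs.mean(0)
        sd = diffs.std(0, ddof=1)
        t = mean / (sd / np.sqrt(n))
        p = 2 * stats.t.sf(np.abs(t), df=n - 1)
        return bs.TopoStatResult(labels=list(montage.labels), t_map=t,
                                 p_map=p, diffs=diffs, df=n - 1)

    def test_min_cluster_floor_is_three(self, montage56, rng):
        res = bs.permutation_cluster_correct(
            self._null_result(montage56, rng), montage56, n_perm=32
        )
        assert res.min_cluster >= 3

    def test_excess_permutations_rejected(self, montage56, rng):
        with pytest.raises(ValueError, match="exceeds"):
            bs.permutation_cluster_correct(
                self._null_result(montage56, rng), montage56, n_perm=64
            )

    def test_contiguous_effect_detected(self, montage56, rng):
        """A strong 10-channel neighbor-connected effect survives correction."""
        labels = list(montage56.labels)
        cluster = ["Fz", "F1", "F2", "AFz", "FCz", "FC1", "FC2", "AF3", "AF4", "F3"]
        idx = [labels.index(l) for l in cluster]
        hits = 0
        n_seeds = 20
        for _ in range(n_seeds):
            diffs = 0.2 * rng.standard_normal((5, 56))
            diffs[:, idx] += 1.0
            mean = diffs.mean(0)
            sd = diffs.std(0, ddof=1)
            t = mean / (sd / np.sqrt(5))
            p = 2 * stats.t.sf(np.abs(t), df=4)
            res = bs.TopoStatResult(labels=labels, t_map=t, p_map=p,
                                    diffs=diffs, df=4)
            res = bs.permutation_cluster_correct(res, montage56, n_perm=32)
            if res.sig_mask[idx].sum() >= 3:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_sig_mask_within_uncorrected_significance(self, montage56, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            diffs = r.standard_normal((5, 56)) + 0.5
            mean = diffs.mean(0)
            sd = diffs.std(0, ddof=1)
            t = mean / (sd / np.sqrt(5))
            p = 2 * stats.t.sf(np.abs(t), df=4)
            res = bs.TopoStatResult(labels=list(montage56.labels), t_map=t,
                                    p_map=p, diffs=diffs, df=4)
            res = bs.permutation_cluster_correct(res, montage56, n_perm=32)
            assert np.all(res.p_map[res.sig_mask] < 0.05)

    def test_invariant_under_mirror_relabeling(self, montage56, rng):
        """Left-right mirroring preserves adjacency, hence the cluster rule."""
        labels = list(montage56.labels)

        def mirror(lab):
            for a, b in (("1", "2"), ("3", "4"), ("5", "6"), ("7", "8")):
                if lab.endswith(a):
                    return lab[: -len(a)] + b
                if lab.endswith(b):
                    return lab[: -len(b)] + a
            return lab

        perm = [labels.index(mirror(l)) for l in labels]
        diffs = rng.standard_normal((5, 56)) + 0.4
        for d, dd in ((diffs, None),):
            mean = d.mean(0)
            sd = d.std(0, ddof=1)
            t = mean / (sd / np.sqrt(5))
            p = 2 * stats.t.sf(np.abs(t), df=4)
            res = bs.TopoStatResult(labels=labels, t_map=t, p_map=p,
                                    diffs=d, df=4)
            res = bs.permutation_cluster_correct(res, montage56, n_perm=32)
        d2 = diffs[:, perm]
        mean = d2.mean(0)
        sd = d2.std(0, ddof=1)
        t2 = mean / (sd / np.sqrt(5))
        p2 = 2 * stats.t.sf(np.abs(t2), df=4)
        res2 = bs.TopoStatResult(labels=labels, t_map=t2, p_map=p2,
                                 diffs=d2, df=4)
        res2 = bs.permutation_cluster_correct(res2, montage56, n_perm=32)
        assert res2.min_cluster == res.min_cluster
        assert np.array_equal(res2.sig_mask, res.sig_mask[perm])


class TestConditionContrast:
    def test_identical_conditions_are_null(self):
        values = {s: {"earth": 10.0, "space": 10.0} for s in range(4)}
        out = bs.condition_contrast(values)
        c = out[("earth", "space")]
        assert c.mean_diff == 0.0 and c.t == 0.0

    def test_antisymmetry(self, rng):
        values = {
            s: {"a": float(rng.normal(10)), "b": float(rng.normal(12))}
            for s in range(6)
        }
        swapped = {s: {"a": v["b"], "b": v["a"]} for s, v in values.items()}
        c1 = bs.condition_contrast(values)[("a", "b")]
        c2 = bs.condition_contrast(swapped)[("a", "b")]
        assert c1.mean_diff == pytest.approx(-c2.mean_diff)
        assert c1.t == pytest.approx(-c2.t)

    def test_missing_cell_reported(self):
        values = {0: {"a": 1.0, "b": 2.0}, 1: {"a": 1.0}}
        with pytest.raises(ValueError, match=r"\(1, 'b'\)"):
            bs.condition_contrast(values)

    def test_df_is_subjects_minus_one(self, rng):
        values = {
            s: {"a": float(rng.normal(0)), "b": float(rng.normal(1))}
            for s in range(5)
        }
        assert bs.condition_contrast(values)[("a", "b")].df == 4
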