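"""The local sleep-like event detector, stage by stage."""

import numpy as np
import pytest

from thetawake.events import (
    DEFAULT_AREAS,
    AreaSet,
    DetectionParams,
    area_reference,
    compute_threshold,
    detect_all,
    detect_negative_peaks,
    event_amplitude,
    event_involvement,
    theta_filter,
)
from thetawake.montage_io import ANALYSIS_56
from thetawake.types import Recording


def brute_force_negative_peaks(x, fs, thr, p=DetectionParams(), mask=None):
    """Independent oracle: exhaustive scan over all local extrema."""
    x = np.asarray(x, float)
    maxima = [
        i for i in range(1, len(x) - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]
    ]
    lo, hi = p.period_range
    out = []
    for m1, m2 in zip(maxima, maxima[1:]):
        sep = (m2 - m1) / fs
        if not (lo <= sep <= hi):
            continue
        seg = list(x[m1 + 1 : m2])
        imin = m1 + 1 + seg.index(min(seg))
        if not x[imin] < thr:
            continue
        if mask is not None and not all(mask[m1 : m2 + 1]):
            continue
        out.append((m1 / fs, imin / fs, m2 / fs))
    return out


def _zrec(data, fs=256.0, labels=None):
    labels = labels or list(ANALYSIS_56[: data.shape[0]])
    return Recording(data=data, fs=fs, labels=labels,
                     reference="average", unit_state="zscored")


class TestAreaSet:
    def test_printed_lists_overlap_and_warn(self):
        with pytest.warns(UserWarning, match="CPz/CP2"):
            a = AreaSet.default()
        assert set(a.areas["central"]) & set(a.areas["parietal"]) == {"CPz", "CP2"}

    def test_fixed_central_list_is_disjoint(self, areas):
        assert not set(areas.areas["central"]) & set(areas.areas["parietal"])
        assert areas.areas["central"] == ("FC1", "FCz", "FC2", "C1", "Cz", "C2")

    def test_frontal_list_as_published(self, areas):
        assert areas.areas["frontal"] == (
            "Fp1", "Fp2", "AF3", "AFz", "AF4", "F1", "Fz", "F2"
        )

    def test_missing_channel_reported(self, areas):
        with pytest.raises(ValueError, match="frontal"):
            areas.validate_against(["Fz", "Cz"])


class TestAreaReference:
    def test_identical_sinusoid_passes_through(self):
        fs = 256.0
        t = np.arange(int(fs * 20)) / fs
        x = np.sin(2 * np.pi * 6.0 * t)
        frontal = DEFAULT_AREAS["frontal"]
        data = np.tile(x, (len(frontal), 1))
        rec = _zrec(data, fs, labels=list(frontal))
        ref = area_reference(rec, frontal)
        mid = slice(int(2 * fs), int(-2 * fs))
        assert np.abs(ref[mid]).max() == pytest.approx(1.0, rel=0.02)

    def test_antisymmetric_channels_cancel(self, rng):
        fs = 256.0
        x = rng.standard_normal(int(fs * 10))
        rec = _zrec(np.stack([x, -x]), fs, labels=["Fz", "Cz"])
        ref = area_reference(rec, ["Fz", "Cz"])
        assert np.allclose(ref, 0.0, atol=1e-12)

    def test_reference_is_mean_of_exactly_eight_frontal_channels(self, rng):
        fs = 256.0
        frontal = DEFAULT_AREAS["frontal"]
        assert len(frontal) == 8
        data = rng.standard_normal((8, int(fs * 10)))
        rec = _zrec(data, fs, labels=list(frontal))
        ref = area_reference(rec, frontal)
        expected = theta_filter(data.mean(axis=0), fs)
        assert np.allclose(ref, expected)

    def test_missing_area_channel_rejected(self, rng):
        rec = _zrec(rng.standard_normal((2, 256)), labels=["Fz", "Cz"])
        with pytest.raises(ValueError, match="Pz"):
            area_reference(rec, ["Fz", "Pz"])


class TestThreshold:
    def test_formula_forced_small_vector(self):
        # median 0, MAD 0.5 -> threshold -1.0
        x = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        assert compute_threshold(x) == pytest.approx(-1.0)

    def test_positive_homogeneity(self, rng):
        x = rng.standard_normal(10_000)
        assert compute_threshold(3.0 * x) == pytest.approx(
            3.0 * compute_threshold(x)
        )

    def test_mean_abs_variant(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        p = DetectionParams(mad_kind="mean_abs")
        # median 0, mean |x| = 1.2 -> -2.4
        assert compute_threshold(x, p) == pytest.approx(-2.4)

    def test_mask_restricts_statistics(self, rng):
        x = rng.standard_normal(10_000)
        x[:5000] += 100.0
        mask = np.r_[np.zeros(5000, bool), np.ones(5000, bool)]
        thr = compute_threshold(x, mask=mask)
        assert -2.0 < thr < -1.0


class TestNegativePeaks:
    def test_flat_signal_yields_no_candidates(self):
        assert detect_negative_peaks(np.zeros(1000), 256.0, 0.0) == []

    def test_sinusoid_candidate_count_matches_oracle(self):
        fs = 512.0
        t = np.arange(int(fs * 10)) / fs
        x = 3.0 * np.sin(2 * np.pi * 6.0 * t)
        got = detect_negative_peaks(x, fs, -1.0)
        oracle = brute_force_negative_peaks(x, fs, -1.0)
        assert got == oracle
        assert abs(len(got) - 10 * 6) <= 1

    def test_trough_equal_to_threshold_rejected(self):
        fs = 256.0
        t = np.arange(int(fs * 2)) / fs
        x = np.sin(2 * np.pi * 6.0 * t)  # troughs at exactly -1
        assert detect_negative_peaks(x, fs, -1.0) == []
        assert len(detect_negative_peaks(x, fs, -0.999)) > 0

    def test_threshold_above_median_rejected(self, rng):
        x = rng.standard_normal(1000)
        with pytest.raises(ValueError, match="median"):
            detect_negative_peaks(x, 256.0, 1.0)

    def test_masked_candidates_dropped(self):
        fs = 256.0
        t = np.arange(int(fs * 10)) / fs
        x = 3.0 * np.sin(2 * np.pi * 6.0 * t)
        mask = np.ones_like(x, bool)
        mask[: len(x) // 2] = False
        got = detect_negative_peaks(x, fs, -1.0, mask=mask)
        assert all(tp > 4.9 for tp, _, _ in got)
        assert got == brute_force_negative_peaks(x, fs, -1.0, mask=mask)

    def test_deepening_threshold_never_adds_candidates(self, rng):
        fs = 256.0
        x = theta_filter(rng.standard_normal(int(fs * 30)), fs)
        thrs = [-0.1, -0.3, -0.5, -0.8]
        counts = [len(detect_negative_peaks(x, fs, t)) for t in thrs]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_translation_invariance(self, rng):
        fs = 256.0
        x = theta_filter(rng.standard_normal(int(fs * 30)), fs)
        k = 64
        shifted = np.r_[np.zeros(k), x]
        a = detect_negative_peaks(x, fs, -0.3)
        b = detect_negative_peaks(shifted, fs, -0.3)
        b_in_range = [c for c in b if c[0] >= k / fs]
        for (p1, n1, q1), (p2, n2, q2) in zip(a, b_in_range):
            assert n2 - n1 == pytest.approx(k / fs, abs=1e-9)


class TestInvolvement:
    def _setup(self, montage56, rng):
        fs = 256.0
        n = int(fs * 4)
        labels = list(montage56.labels)
        data = rng.standard_normal((len(labels), n))  # broadband, uncorrelated
        t = np.arange(n) / fs
        ref = np.sin(2 * np.pi * 6.0 * (t - 2.0)) * np.exp(-(((t - 2.0) / 0.12) ** 2))
        cand = (2.0 - 1 / 12.0, 2.0 + 1 / 12.0 - 1 / 256, 2.0 + 1 / 12.0)
        # candidate triple (prev max, trough, next max) around t=2.0
        cand = (2.0 - 0.08, 2.0, 2.0 + 0.08)
        return fs, labels, data, -ref, cand

    def test_channels_carrying_reference_marked(self, montage56, rng):
        fs, labels, data, refsig, cand = self._setup(montage56, rng)
        carriers = {"Fz", "F1", "F2", "AFz", "FCz"}
        for lab in carriers:
            data[labels.index(lab)] = refsig
        inv = event_involvement(cand, data, fs, refsig, montage56, labels)
        assert carriers <= inv

    def test_distant_isolated_channel_pruned(self, montage56, rng):
        fs, labels, data, refsig, cand = self._setup(montage56, rng)
        for lab in ("Fz", "F1", "F2"):
            data[labels.index(lab)] = refsig
        data[labels.index("O2")] = refsig  # isolated copy far away
        inv = event_involvement(cand, data, fs, refsig, montage56, labels)
        assert "O2" not in inv
        assert {"Fz", "F1", "F2"} <= inv

    def test_white_noise_channels_rarely_involved(self, montage56, rng):
        fs, labels, data, refsig, cand = self._setup(montage56, rng)
        for lab in ("Fz", "F1"):
            data[labels.index(lab)] = refsig
        inv = event_involvement(cand, data, fs, refsig, montage56, labels)
        assert len(inv - {"Fz", "F1"}) <= 2

    def test_raising_corr_cut_shrinks_involvement(self, montage56, rng):
        fs, labels, data, refsig, cand = self._setup(montage56, rng)
        for lab in ("Fz", "F1", "F2", "AFz"):
            data[labels.index(lab)] = refsig + 0.15 * rng.standard_normal(len(refsig))
        loose = event_involvement(
            cand, data, fs, refsig, montage56, labels, DetectionParams(corr_cut=0.5)
        )
        strict = event_involvement(
            cand, data, fs, refsig, montage56, labels, DetectionParams(corr_cut=0.99)
        )
        assert strict <= loose

    def test_edge_candidate_dropped(self, montage56, rng):
        fs, labels, data, refsig, cand = self._setup(montage56, rng)
        near_edge = (0.0, 0.04, 0.08)
        out = event_involvement(near_edge, data, fs, refsig, montage56, labels)
        assert out is None


class TestAmplitude:
    def test_identical_wave_trough_to_peak(self):
        fs = 100.0
        n = 200
        wave = np.zeros(n)
        wave[100] = -2.0
        wave[110] = 1.0
        data = np.tile(wave, (3, 1))
        cand = (0.9, 1.0, 1.1)
        amp = event_amplitude(cand, frozenset({"Fz", "Cz", "Pz"}), data, fs,
                              ["Fz", "Cz", "Pz"])
        assert amp == pytest.approx(3.0)

    def test_median_slope_channel_selected(self):
        fs = 100.0
        n = 200
        data = np.zeros((3, n))
        # slopes 1, 2, 9 (value at next peak over 0.1 s from trough at 0)
        for i, s in enumerate((1.0, 2.0, 9.0)):
            data[i, 110] = s * 0.1
        cand = (0.9, 1.0, 1.1)
        labels = ["Fz", "Cz", "Pz"]
        amp = event_amplitude(cand, frozenset(labels), data, fs, labels)
        assert amp == pytest.approx(0.2)  # the slope-2 channel

    def test_singleton_involved_set(self):
        fs = 100.0
        data = np.zeros((2, 200))
        data[1, 100] = -1.5
        data[1, 110] = 0.5
        amp = event_amplitude((0.9, 1.0, 1.1), frozenset({"Cz"}), data, fs,
                              ["Fz", "Cz"])
        assert amp == pytest.approx(2.0)

    def test_empty_involved_set_rejected(self):
        with pytest.raises(ValueError):
            event_amplitude((0.9, 1.0, 1.1), frozenset(), np.zeros((1, 200)),
                            100.0, ["Fz"])


class TestDetectAll:
    def test_zero_signal_yields_zero_events(self, areas, montage56):
        rec = _zrec(np.zeros((56, 256 * 10)), labels=list(ANALYSIS_56))
        events, density = detect_all(rec, areas, montage56)
        assert events == []
        assert all(v == 0.0 for v in density.values())

    def test_quiet_session_recovery(self, areas, montage56, quiet_session):
        """>= 90% of injected frontal events found with <= 10 ms error."""
        from thetawake.pipeline import match_events

        rec, truth = quiet_session
        events, density = detect_all(rec, areas, montage56)
        frontal = [e for e in events if e.area == "frontal"]
        matched = match_events(frontal, truth, tol_s=0.01)
        assert len(matched) >= 0.9 * len(truth)
        assert density["frontal"] > 0
        for j, e in matched.items():
            assert abs(e.t_neg - truth[j].t_neg) <= 0.010
            assert e.t_pos_prev < e.t_neg < e.t_pos_next
            assert e.amplitude_z > 0

    def test_globality_within_two_channels_of_truth(self, areas, montage56,
                                                    quiet_session):
        from thetawake.pipeline import match_events
        from thetawake.synthetic_data import event_truth_globality

        rec, truth = quiet_session
        events, _ = detect_all(rec, areas, montage56)
        matched = match_events(events, truth, tol_s=0.01)
        errs = [
            abs(e.globality_pct - event_truth_globality(truth[j], montage56))
            * 56 / 100
            for j, e in matched.items()
        ]
        assert np.mean(errs) <= 2.0
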