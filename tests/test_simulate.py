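"""Generator contracts: determinism, ground-truth recovery, regimes."""

import numpy as np
import pytest

import syncphase as sp
from syncphase.exceptions import ValidationError
from syncphase.pipeline import analyze_records

# forward smoothing anchors the window start, advancing detected peak
# times by ~half the smoothing window relative to true event centers
SMOOTH_SHIFT_S = 0.05
MATCH_TOL_S = 0.25


def detection_stats(true_times, detected_times):
    det = np.asarray(detected_times) + SMOOTH_SHIFT_S
    true = np.asarray(true_times)
    if len(true) == 0:
        return float("nan"), 0.0 if len(det) == 0 else 1.0
    if len(det) == 0:
        return 0.0, 0.0
    recall = np.mean([np.min(np.abs(det - t)) <= MATCH_TOL_S for t in true])
    fpr = np.mean([np.min(np.abs(true - d)) > MATCH_TOL_S for d in det])
    return recall, fpr


def analyze(speaker, listener, duration_s, dyad_id="d"):
    m = sp.SessionManifest(dyad_id, "TD", "s", "l", 0.0, duration_s)
    return sp.analyze_session(m, speaker=speaker, listener=listener)


class TestDeterminism:
    def test_same_seed_identical_traces(self):
        cfg = sp.td_like_config(seed=5, duration_s=30.0)
        s1, l1, g1 = sp.simulate_dyad(cfg)
        s2, l2, g2 = sp.simulate_dyad(cfg)
        np.testing.assert_array_equal(s1.az, s2.az)
        np.testing.assert_array_equal(l1.ax, l2.ax)
        np.testing.assert_array_equal(g1.speaker_event_times, g2.speaker_event_times)

    def test_different_seed_differs(self):
        s1, _, _ = sp.simulate_dyad(sp.td_like_config(seed=1, duration_s=30.0))
        s2, _, _ = sp.simulate_dyad(sp.td_like_config(seed=2, duration_s=30.0))
        assert not np.array_equal(s1.az, s2.az)

    def test_corpus_reproducible(self, tmp_path):
        cfg_td = sp.td_like_config(duration_s=20.0)
        cfg_asd = sp.asd_like_config(duration_s=20.0)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sp.simulate_group_study(cfg_td, cfg_asd, 2, seed=9, out_dir=d1)
        sp.simulate_group_study(cfg_td, cfg_asd, 2, seed=9, out_dir=d2)
        f = "TD01_speaker.csv"
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes()


class TestConfigValidation:
    def test_rate_too_high_for_separation(self):
        with pytest.raises(ValidationError):
            sp.simulate_dyad(sp.td_like_config(
                duration_s=30.0, speaker_nod_rate_per_min=80.0))

    def test_amplitude_target_unreachable(self):
        with pytest.raises(ValidationError):
            sp.simulate_dyad(sp.td_like_config(
                duration_s=60.0, speaker_nod_rate_per_min=30.0,
                nod_amplitude_z=5.0))

    def test_amplitude_must_exceed_threshold(self):
        with pytest.raises(ValidationError):
            sp.DyadSimConfig(nod_amplitude_z=1.5)

    def test_bad_response_prob(self):
        with pytest.raises(ValidationError):
            sp.DyadSimConfig(response_prob=1.2)


class TestZeroCoupling:
    def test_no_responses_no_spontaneous_yields_zero_matches(self):
        cfg = sp.td_like_config(seed=3, duration_s=120.0, response_prob=0.0,
                                spontaneous_listener_rate_per_min=0.0)
        s, l, gt = sp.simulate_dyad(cfg)
        assert len(gt.listener_event_times) == 0
        res = analyze(s, l, 120.0)
        assert len(res.listener_peaks) == 0
        assert res.features.n_events == 0


class TestDetectorValidation:
    def test_recall_and_false_positive_rate(self):
        recalls, fprs = [], []
        for seed in range(3):
            cfg = sp.td_like_config(seed=seed, duration_s=300.0)
            s, l, gt = sp.simulate_dyad(cfg)
            res = analyze(s, l, 300.0)
            for true, det in [
                (gt.speaker_event_times, res.speaker_peaks.peak_times),
                (gt.listener_event_times, res.listener_peaks.peak_times),
            ]:
                rec, fpr = detection_stats(true, det)
                recalls.append(rec)
                fprs.append(fpr)
        assert np.mean(recalls) >= 0.95
        assert np.mean(fprs) <= 0.05

    def test_matched_lags_correlate_with_true_lags(self):
        cfg = sp.td_like_config(seed=11, duration_s=600.0,
                                spontaneous_listener_rate_per_min=0.0)
        s, l, gt = sp.simulate_dyad(cfg)
        res = analyze(s, l, 600.0)
        det_s = res.speaker_peaks.peak_times + SMOOTH_SHIFT_S
        det_l = res.listener_peaks.peak_times + SMOOTH_SHIFT_S
        true_lags, det_lags = [], []
        for ts, tl, lag in gt.coupled_pairs:
            i = np.argmin(np.abs(det_s - ts))
            j = np.argmin(np.abs(det_l - tl))
            if abs(det_s[i] - ts) < MATCH_TOL_S and abs(det_l[j] - tl) < MATCH_TOL_S:
                true_lags.append(lag)
                det_lags.append((det_l[j] - det_s[i]) * 1000.0)
        assert len(true_lags) > 0.9 * len(gt.coupled_pairs)
        r = sp.pearson(true_lags, det_lags)
        assert r.r >= 0.9


class TestParameterRecovery:
    def test_density_matches_rate_times_response_prob(self):
        # expectation: 23.3 nods/min * 0.41 responses/nod ~ 9.55/min
        densities = []
        for seed in range(4):
            cfg = sp.td_like_config(seed=seed, duration_s=1200.0,
                                    spontaneous_listener_rate_per_min=0.0)
            s, l, gt = sp.simulate_dyad(cfg)
            densities.append(analyze(s, l, 1200.0).features.density_per_min)
        expected = 23.3 * 0.41
        assert np.mean(densities) == pytest.approx(expected, abs=1.0)

    def test_lag_mean_and_jitter_recovered(self):
        cfg = sp.td_like_config(seed=7, duration_s=1800.0,
                                response_lag_sd_ms=50.0,
                                spontaneous_listener_rate_per_min=0.0)
        s, l, gt = sp.simulate_dyad(cfg)
        f = analyze(s, l, 1800.0).features
        assert f.mean_ms == pytest.approx(90.0, abs=10.0)
        assert f.sd_ms == pytest.approx(50.0, abs=15.0)

    def test_speaker_nod_rate_realized(self):
        cfg = sp.td_like_config(seed=13, duration_s=1800.0)
        _, _, gt = sp.simulate_dyad(cfg)
        rate = len(gt.speaker_event_times) / 30.0
        assert rate == pytest.approx(23.3, abs=1.5)


class TestGroupStudy:
    def test_corpus_shape_and_files(self, tmp_path):
        recs = sp.simulate_group_study(
            sp.td_like_config(duration_s=20.0),
            sp.asd_like_config(duration_s=20.0),
            3, seed=1, out_dir=tmp_path,
        )
        assert len(recs) == 6
        assert len(list(tmp_path.glob("*_speaker.csv"))) == 6
        assert len(list(tmp_path.glob("*_listener.csv"))) == 6
        assert (tmp_path / "manifest.yaml").exists()
        assert (tmp_path / "ground_truth.json").exists()
        groups = [r.manifest.group_label for r in recs]
        assert groups.count("TD") == 3 and groups.count("ASD") == 3

    def test_regime_contrast_on_one_corpus(self):
        recs = sp.simulate_group_study(
            sp.td_like_config(duration_s=300.0),
            sp.asd_like_config(duration_s=300.0),
            6, seed=21,
        )
        df, _ = analyze_records(recs)
        td = df[df.group == "TD"]["density_per_min"]
        asd = df[df.group == "ASD"]["density_per_min"]
        assert td.mean() > asd.mean()
        r = sp.t_and_d(td.to_numpy(), asd.to_numpy())
        assert r.p_two_sided < 0.01
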