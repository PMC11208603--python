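"""Epoch features, staging cascade, arousal scoring, weighted statistics."""

import numpy as np
import pandas as pd
import pytest

from engage import sleepproc as sp
from engage import synthgen as sg
from engage.synthgen.sleep import _band_noise
from engage.types import Hypnogram, Trace

RATE = 100.0


def make_recording(frontal, parietal, emg):
    return (Trace(frontal, RATE), Trace(parietal, RATE), Trace(emg, RATE))


class TestEpochFeatures:
    def test_pure_slow_content_gives_near_zero_ratio(self):
        t = np.arange(int(40 * RATE)) / RATE
        slow = np.sin(2 * np.pi * 2.0 * t)
        f = sp.compute_epoch_features(*make_recording(slow, slow, slow))
        assert (f["power_ratio"] < 0.01).all()

    def test_pure_fast_content_gives_large_ratio(self):
        t = np.arange(int(40 * RATE)) / RATE
        fast = np.sin(2 * np.pi * 35.0 * t)
        f = sp.compute_epoch_features(*make_recording(fast, fast, fast))
        assert (f["power_ratio"] > 10).all()

    def test_white_noise_ratio_matches_bandwidth(self, rng):
        # flat spectrum: ratio of band powers equals ratio of bandwidths,
        # (50−25)/5 = 5, within sampling tolerance when pooled over epochs
        x = rng.standard_normal(int(1200 * RATE))
        f = sp.compute_epoch_features(*make_recording(x, x, x))
        assert abs(f["power_ratio"].mean() - 5.0) < 0.5

    def test_short_recording_rejected(self):
        x = np.zeros(int(2 * RATE))
        with pytest.raises(ValueError, match="shorter"):
            sp.compute_epoch_features(*make_recording(x, x, x))


class TestStaging:
    def test_cascade_on_constructed_features(self):
        # high EMG -> wake; low EMG splits on power ratio, then theta
        f = pd.DataFrame({
            "start_s": np.arange(12) * 4.0,
            "power_ratio": [5, 5, 5, 0.01, 0.01, 0.01, 4, 4, 4, 5, 5, 5],
            "theta_delta": [1, 1, 1, 0.1, 0.1, 0.1, 30, 30, 30, 1, 1, 1],
            "emg_rms": [1, 1, 1, 0.1, 0.1, 0.1, 0.05, 0.05, 0.05, 1, 1, 1],
        })
        thr = sp.StageThresholds(emg=0.4, power_ratio=0.3, theta_delta=3.0)
        hyp = sp.stage_sleep(f, thr)
        assert list(hyp.to_epochs()) == (["wake"] * 3 + ["nrem"] * 3
                                         + ["rem"] * 3 + ["wake"] * 3)

    def test_recovery_of_ground_truth(self, short_sleep_recording):
        rec = short_sleep_recording
        f = sp.compute_epoch_features(rec.eeg_frontal, rec.eeg_parietal,
                                      rec.emg)
        hyp = sp.stage_sleep(f)
        agreement = (hyp.to_epochs() == rec.hypnogram.to_epochs()).mean()
        assert agreement >= 0.90

    def test_invariant_to_affine_channel_rescaling(self, short_sleep_recording):
        rec = short_sleep_recording
        f1 = sp.compute_epoch_features(rec.eeg_frontal, rec.eeg_parietal,
                                       rec.emg)
        scaled = make_recording(rec.eeg_frontal.values * 7.0,
                                rec.eeg_parietal.values * 0.2,
                                rec.emg.values * 3.0)
        f2 = sp.compute_epoch_features(*scaled)
        h1 = sp.stage_sleep(f1)
        h2 = sp.stage_sleep(f2)
        assert np.array_equal(h1.to_epochs(), h2.to_epochs())

    def test_degenerate_features_fall_back_with_warning(self, rng):
        f = pd.DataFrame({
            "start_s": np.arange(100) * 4.0,
            "power_ratio": 1.0 + 0.01 * rng.random(100),
            "theta_delta": 1.0 + 0.01 * rng.random(100),
            "emg_rms": 1.0 + 0.01 * rng.random(100),
        })
        with pytest.warns(UserWarning, match="unimodal"):
            sp.fit_stage_thresholds(f)

    def test_smoothing_enforces_minimum_duration(self):
        states = np.array(["nrem"] * 10 + ["wake"] + ["nrem"] * 10,
                          dtype=object)
        out = sp._smooth_min_duration(states, min_epochs=3)
        assert (out == "nrem").all()


def _nrem_background(n_s, rng_seed=0):
    """NREM-like traces: strong delta, weak high band, quiet EMG."""
    rng = np.random.default_rng(rng_seed)
    n = int(n_s * RATE)
    eeg = 2.2 * _band_noise(n, RATE, 0.5, 5.0, rng) + \
        0.25 * _band_noise(n, RATE, 25.0, 49.0, rng)
    emg = 0.12 * _band_noise(n, RATE, 10.0, 49.0, rng)
    return eeg, emg


def _insert_wake(eeg, emg, start_s, dur_s, rng_seed=1):
    rng = np.random.default_rng(rng_seed)
    i0, i1 = int(start_s * RATE), int((start_s + dur_s) * RATE)
    eeg[i0:i1] = 0.4 * _band_noise(i1 - i0, RATE, 0.5, 5.0, rng) + \
        1.0 * _band_noise(i1 - i0, RATE, 25.0, 49.0, rng)
    emg[i0:i1] = 1.0 * _band_noise(i1 - i0, RATE, 10.0, 49.0, rng)


THR = sp.StageThresholds(emg=0.4, power_ratio=0.3, theta_delta=3.0)


class TestArousalClassification:
    def test_prompt_sustained_desync_with_emg_is_awakening(self):
        eeg, emg = _nrem_background(60.0)
        _insert_wake(eeg, emg, 31.5, 20.0)  # 1.5 s after a tone at t=30
        out = sp.classify_arousal(Trace(eeg, RATE), Trace(emg, RATE),
                                  30.0, THR)
        assert out == "awakening"

    def test_late_desync_is_maintained(self):
        eeg, emg = _nrem_background(60.0)
        _insert_wake(eeg, emg, 34.5, 20.0)  # 4.5 s: outside the 3-s window
        out = sp.classify_arousal(Trace(eeg, RATE), Trace(emg, RATE),
                                  30.0, THR)
        assert out == "maintained"

    def test_brief_desync_is_maintained(self):
        eeg, emg = _nrem_background(60.0)
        _insert_wake(eeg, emg, 31.5, 1.0)  # shorter than 2 s
        out = sp.classify_arousal(Trace(eeg, RATE), Trace(emg, RATE),
                                  30.0, THR)
        assert out == "maintained"

    def test_desync_without_emg_activation_is_maintained(self):
        eeg, emg = _nrem_background(60.0)
        quiet = emg.copy()
        _insert_wake(eeg, emg, 31.5, 20.0)
        out = sp.classify_arousal(Trace(eeg, RATE), Trace(quiet, RATE),
                                  30.0, THR)
        assert out == "maintained"

    def test_pre_desynchronized_trial_not_scorable(self):
        eeg, emg = _nrem_background(60.0)
        _insert_wake(eeg, emg, 20.0, 30.0)  # awake well before the tone
        out = sp.classify_arousal(Trace(eeg, RATE), Trace(emg, RATE),
                                  30.0, THR)
        assert out == "pre_desync"

    def test_edge_tone_ignored(self):
        eeg, emg = _nrem_background(20.0)
        out = sp.classify_arousal(Trace(eeg, RATE), Trace(emg, RATE),
                                  2.0, THR)
        assert out == "edge"


class TestSwaFilter:
    @pytest.mark.parametrize("pre,post,keep", [
        (10.0, 5.0, False),   # ratio 2 > 1.5: excluded
        (10.0, 10.0, True),   # unchanged SWA: kept
        (10.0, 6.9, True),    # ratio 1.449: boundary below 1.5
        (10.0, 0.0, False),   # degenerate post power
    ])
    def test_ratio_boundary(self, pre, post, keep):
        assert sp.filter_ambiguous_maintained(pre, post) is keep

    def test_pipeline_only_excludes_maintained_trials(self, arousal_recording):
        out = sp.process_arousal_session(arousal_recording)
        # every excluded trial was NREM at onset and classified maintained
        exc = out[out["outcome"] == "excluded"]
        assert (exc["state"] == "nrem").all()
        assert set(out["outcome"]) <= {"awakening", "maintained", "excluded",
                                       "ignored", "edge", "pre_desync"}


class TestArousalPipeline:
    def test_recovers_generator_awakening_ordering(self, arousal_recording):
        out = sp.process_arousal_session(arousal_recording)
        scored = out[out["outcome"].isin(["awakening", "maintained"])]
        frac = scored.groupby("level_db")["outcome"].apply(
            lambda s: (s == "awakening").mean())
        assert frac[80] > frac[65]

    def test_detection_matches_ground_truth(self, arousal_recording):
        out = sp.process_arousal_session(arousal_recording)
        scored = out[out["outcome"].isin(["awakening", "maintained"])]
        true_pos = ((scored["outcome"] == "awakening")
                    & scored["awakening_true"]).sum()
        false_pos = ((scored["outcome"] == "awakening")
                     & ~scored["awakening_true"]).sum()
        n_true = scored["awakening_true"].sum()
        assert true_pos >= 0.8 * n_true
        assert false_pos <= max(2, 0.05 * len(scored))


class TestWeightedStats:
    def test_weights_proportional_to_counts(self):
        counts = np.array([10, 20, 30])
        w = counts / counts.mean()
        assert np.allclose(w, [0.5, 1.0, 1.5])
        # weighted mean equals the hand oracle sum(n x)/sum(n)
        assert np.isclose(sp.weighted_group_mean([1, 2, 3], counts), 7 / 3)

    def test_equal_counts_reduce_to_plain_mean(self):
        assert np.isclose(sp.weighted_group_mean([1.0, 5.0], [7, 7]), 3.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sp.weighted_group_mean([], [])


class TestStateMeans:
    def test_constructed_state_contrast(self):
        states = np.array(["nrem"] * 5 + ["wake"] * 5, dtype=object)
        hyp = Hypnogram.from_epochs(states, epoch_s=4.0)
        vals = np.where(np.arange(4000) < 2000, 1.0, -1.0)
        means = sp.state_mean_activity(Trace(vals, RATE, units="z"), hyp)
        assert means["nrem"] == 1.0 and means["wake"] == -1.0

    def test_missing_state_flagged(self):
        hyp = Hypnogram.from_epochs(np.array(["wake"] * 4, dtype=object))
        with pytest.warns(UserWarning, match="absent"):
            means = sp.state_mean_activity(
                Trace(np.zeros(1600), RATE, units="z"), hyp)
        assert np.isnan(means["rem"])

    def test_generator_nrem_elevation_recovered(self, short_sleep_recording):
        rec = short_sleep_recording
        means = sp.state_mean_activity(rec.meta["accp_z"], rec.hypnogram)
        assert means["nrem"] > means["wake"]


class TestBaselineContrast:
    def test_positive_coupling_recovered(self):
        rows = []
        rng = np.random.default_rng(3)
        for mouse in range(6):
            rec = sg.simulate_sleep_session(
                sg.SleepGenConfig(duration_h=3.0, tones=True,
                                  arousal_coupling=2.0, seed=300 + mouse))
            accp = rec.meta["accp_z"]
            nrem = rec.tones[rec.tones["state_true"] == "nrem"]
            for _, r in nrem.iterrows():
                rows.append({
                    "mouse": mouse,
                    "outcome": ("awakening" if r["awakening_true"]
                                else "maintained"),
                    "pre_baseline": r["accp_pre"],
                })
        contrast, table = sp.arousal_baseline_contrast(pd.DataFrame(rows))
        assert contrast > 0  # maintained trials have higher pre-tone ACCp

    def test_single_mouse_reduces_to_difference_of_means(self):
        df = pd.DataFrame({
            "mouse": 0,
            "outcome": ["maintained"] * 3 + ["awakening"] * 3,
            "pre_baseline": [1.0, 2.0, 3.0, 0.0, 1.0, -1.0],
        })
        contrast, _ = sp.arousal_baseline_contrast(df)
        assert np.isclose(contrast, 2.0 - 0.0)

    def test_mouse_missing_class_dropped_with_warning(self):
        df = pd.DataFrame({
            "mouse": [0, 0, 1],
            "outcome": ["maintained", "awakening", "maintained"],
            "pre_baseline": [1.0, 0.0, 5.0],
        })
        with pytest.warns(UserWarning, match="dropped"):
            contrast, table = sp.arousal_baseline_contrast(df)
        assert list(table.index) == [0]
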