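"""Eye-trace analytics and the behavioral response model."""

import math

import numpy as np
import pandas as pd
import pytest

from preyscope.behavior import (
    BEST_MODEL_TERMS,
    BehaviorModel,
    DetectorParams,
    SaccadeEvent,
    SeparationError,
    angular_geometry,
    classify_evoked,
    compute_vergence,
    detect_convergent_saccades,
    fit_logistic_model,
    predict_response_rate,
    response_location_stats,
    response_rate_table,
    saccade_kinematics,
    stepwise_select,
    trial_table,
)
from preyscope.stimulus import StimulusEpoch, feature_code, generate_schedule
from preyscope.synthdata import BehaviorParams, EyeTrace, synthesize_saccade_train
from preyscope.synthdata.eyes import logistic_response_probability

FS = 60.0

PRINTED = {"intercept": -6.51, "size": 1.33, "polarity": 1.87,
           "speed:size:polarity": 0.90}


def _ramp_trace(n, onsets_l, onsets_r, amp=9.0, dur_samples=2, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    left = rng.normal(0, noise, n) if noise else np.zeros(n)
    right = rng.normal(0, noise, n) if noise else np.zeros(n)
    for chan, onsets in ((left, onsets_l), (right, onsets_r)):
        for i in onsets:
            ramp = np.linspace(0, amp, dur_samples + 1)[1:]
            chan[i + 1:i + 1 + dur_samples] += ramp[:max(0, n - i - 1)]
            chan[i + 1 + dur_samples:] += amp
    return EyeTrace(left=left, right=right, fs=FS)


class TestVergence:
    def test_additivity(self):
        tr = EyeTrace(left=np.full(10, 20.0), right=np.full(10, 25.0))
        assert np.all(compute_vergence(tr) == 45.0)
        tr0 = EyeTrace(left=np.zeros(5), right=np.zeros(5))
        assert np.all(compute_vergence(tr0) == 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            EyeTrace(left=np.zeros(5), right=np.zeros(6))

    def test_vergence_mean_recovery(self):
        trace, truth = synthesize_saccade_train(200, seed=3)
        events = detect_convergent_saccades(trace)
        assert len(events) == 200
        measured = np.mean([e.dvergence for e in events])
        generated = np.mean([t.dvergence for t in truth])
        assert measured == pytest.approx(generated, abs=0.15)


class TestDetector:
    def test_flat_trace_empty(self):
        tr = EyeTrace(left=np.zeros(2000), right=np.zeros(2000))
        assert detect_convergent_saccades(tr) == []

    def test_asynchrony_boundary_200ms_rejected(self):
        # nasal ramps in the two eyes 200 ms apart: not a convergent saccade
        gap = int(0.200 * FS)
        tr = _ramp_trace(1200, [300], [300 + gap])
        assert detect_convergent_saccades(tr) == []
        # 100 ms apart: accepted
        tr2 = _ramp_trace(1200, [300], [300 + int(0.100 * FS)])
        assert len(detect_convergent_saccades(tr2)) == 1

    def test_planted_synchronous_in_noise(self):
        p = BehaviorParams(fixation_noise_sd=0.5)
        trace, truth = synthesize_saccade_train(100, p, seed=7)
        events = detect_convergent_saccades(trace)
        assert len(events) == 100
        det = np.array([e.onset_time for e in events])
        tru = np.array([t.time for t in truth])
        assert np.all(np.abs(det - tru) < 0.3)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_convergent_saccades(EyeTrace(left=np.zeros(2), right=np.zeros(2)))

    def test_matches_brute_force_oracle(self):
        """Detected events equal an exhaustive scan over candidate pairs."""
        params = DetectorParams()
        for seed in range(4):
            trace, _ = synthesize_saccade_train(
                12, BehaviorParams(fixation_noise_sd=0.3), seed=seed, spacing_s=9.0
            )
            assert trace.n <= 10_000
            got = [e.onset_time for e in detect_convergent_saccades(trace, params)]
            expect = _oracle_onsets(trace, params)
            assert got == pytest.approx(expect)


def _oracle_onsets(trace, p):
    """Independent O(n^2) implementation of the detection rules."""
    fs = trace.fs

    def onsets(chan):
        v = np.diff(chan) * fs
        idx = [i for i in range(v.size) if v[i] > p.velocity_threshold]
        gap = max(1, int(round(p.merge_gap_s * fs)))
        keep = []
        for i in idx:
            if not keep or i - keep[-1] > gap:
                keep.append(i)
        return keep

    def disp(chan, i, w):
        a = i + int(round(w[0] * fs))
        b = i + int(round(w[1] * fs))
        if a < 0 or b > chan.size:
            return None
        return chan[a:b].mean()

    L, R = onsets(trace.left), onsets(trace.right)
    max_async = int(round(p.max_asynchrony_s * fs))
    events = []
    last = -10**9
    for i in L:
        best = None
        for j in R:
            if abs(j - i) <= max_async and (
                best is None or abs(j - i) < abs(best - i)
            ):
                best = j
        if best is None:
            continue
        onset = min(i, best)
        if onset - last < int(round(p.refractory_s * fs)):
            continue
        ok = True
        for chan in (trace.left, trace.right):
            pre = disp(chan, onset, p.pre_window)
            post = disp(chan, onset, p.post_window)
            if pre is None or post is None or post - pre < p.min_displacement_deg:
                ok = False
        if ok:
            events.append(trace.t0 + onset / fs)
            last = onset
    return events


class TestKinematics:
    def test_step_displacement(self):
        tr = _ramp_trace(600, [300], [300], amp=10.0)
        ev = SaccadeEvent(onset_time=300 / FS)
        saccade_kinematics(ev, tr)
        assert ev.delta_left == pytest.approx(10.0, abs=1e-9)
        assert ev.delta_right == pytest.approx(10.0, abs=1e-9)
        assert ev.dvergence == pytest.approx(20.0, abs=1e-9)

    def test_peak_velocity_of_known_ramp(self):
        # 100 deg/s ramp for 100 ms in both eyes
        n = 600
        t = np.arange(n) / FS
        chan = np.clip((t - 5.0), 0, 0.1) * 100.0
        tr = EyeTrace(left=chan.copy(), right=chan.copy(), fs=FS)
        ev = SaccadeEvent(onset_time=5.0)
        saccade_kinematics(ev, tr)
        assert ev.peak_velocity_left == pytest.approx(100.0, rel=0.15)

    def test_window_outside_trace_rejected(self):
        tr = EyeTrace(left=np.zeros(20), right=np.zeros(20))
        with pytest.raises(ValueError):
            saccade_kinematics(SaccadeEvent(onset_time=0.0), tr)

    def test_contralateral_bias_direction(self):
        """Eye contralateral to the spot rotates more (paired, >= 50 events)."""
        sched = [
            StimulusEpoch(epoch_index=i, stimulus_id=7, epoch_onset=32.0 * i)
            for i in range(120)
        ]
        p = BehaviorParams(spontaneous_rate_hr=0.0)
        p.logistic_coeffs = {"intercept": 2.0}
        from preyscope.synthdata import generate_eye_traces

        trace, truth = generate_eye_traces(sched, p, seed=5)
        assert len(truth) >= 50
        events = detect_convergent_saccades(trace)
        classify_evoked(events, sched)
        by_time = {round(t.time, 1): t for t in truth}
        contra, ipsi = [], []
        for e in events:
            t = by_time.get(round(e.onset_time, 1))
            if t is None or t.contra_eye is None:
                continue
            c = e.delta_left if t.contra_eye == "L" else e.delta_right
            i = e.delta_right if t.contra_eye == "L" else e.delta_left
            contra.append(c)
            ipsi.append(i)
        from scipy import stats

        tstat, pval = stats.ttest_rel(contra, ipsi)
        assert tstat > 0 and pval < 1e-6


class TestClassifyEvoked:
    def test_inter_stimulus_event_is_spontaneous(self, schedule5):
        ep = schedule5[0]
        ev = SaccadeEvent(onset_time=ep.epoch_onset + 1.0)
        classify_evoked([ev], schedule5)
        assert not ev.evoked and ev.epoch_index is None

    def test_midpoint_event_has_zero_azimuth(self, schedule5):
        ep = next(e for e in schedule5 if not e.is_flash)
        mid = (ep.spot_onset + ep.spot_offset) / 2
        ev = SaccadeEvent(onset_time=mid)
        classify_evoked([ev], schedule5)
        assert ev.evoked and ev.spot_azimuth_at_event == pytest.approx(0.0)

    def test_spontaneous_rate_recovery_short(self):
        """Stimulus-free detection recovers the generating Poisson rate."""
        from preyscope.synthdata import generate_eye_traces

        hours = 20.0
        p = BehaviorParams()
        trace, truth = generate_eye_traces([], p, seed=42, duration_s=hours * 3600)
        events = detect_convergent_saccades(trace)
        lam = p.spontaneous_rate_hr * hours
        assert len(events) == len(truth)
        assert abs(len(events) / hours - p.spontaneous_rate_hr) <= \
            3 * math.sqrt(lam) / hours


class TestLocationStats:
    def test_symmetric_azimuths(self, schedule5):
        rng = np.random.default_rng(0)
        events = []
        spots = [ep for ep in schedule5 if not ep.is_flash][:60]
        from preyscope.stimulus import time_at_azimuth

        for ep in spots:
            az = float(rng.uniform(-40, 40))
            events.append(
                SaccadeEvent(onset_time=time_at_azimuth(ep, az), evoked=True,
                             epoch_index=ep.epoch_index,
                             spot_azimuth_at_event=az)
            )
        out = response_location_stats(events, schedule5)
        assert abs(out["median_azimuth"]) < 15
        assert out["signed_rank_p"] > 0.05

    def test_null_direction_comparison_is_calibrated(self):
        """KS p-values under identical generating distributions ~ U(0,1)."""
        from scipy import stats

        rng = np.random.default_rng(1)
        ps = []
        for _ in range(500):
            a = rng.normal(-5, 20, 40)
            b = rng.normal(-5, 20, 40)
            ps.append(stats.ks_2samp(a, b)[1])
        # discrete exact KS p-values are not perfectly uniform; check the
        # operating characteristics instead of distributional identity
        ps = np.asarray(ps)
        assert abs(np.mean(ps < 0.05) - 0.05) < 0.03
        assert 0.4 < ps.mean() < 0.65

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            response_location_stats([])


class TestRateTableAndModel:
    def test_rate_table_extremes(self, schedule5):
        tab = response_rate_table([], schedule5)
        assert (tab["rate"] == 0).all() and len(tab) == 16
        all_ev = [
            SaccadeEvent(onset_time=ep.spot_onset + 0.1, evoked=True,
                         epoch_index=ep.epoch_index)
            for ep in schedule5 if not ep.is_flash
        ]
        tab2 = response_rate_table(all_ev, schedule5)
        assert (tab2["rate"] == 1).all()

    def test_logistic_fit_recovers_generator(self):
        tab = _bernoulli_table(4000, seed=2)
        m = fit_logistic_model(tab, BEST_MODEL_TERMS)
        for k, v in PRINTED.items():
            assert m.coefficients[k] == pytest.approx(v, abs=0.25)
        for k in m.coefficients:
            assert m.odds_ratios[k] == pytest.approx(math.exp(m.coefficients[k]))

    def test_all_zero_responses_degenerate(self):
        tab = _bernoulli_table(10, seed=0)
        tab["responded"] = 0
        with pytest.raises(SeparationError):
            fit_logistic_model(tab, BEST_MODEL_TERMS)

    def test_predictions(self):
        m = BehaviorModel(terms=tuple(k for k in PRINTED if k != "intercept"),
                          coefficients=dict(PRINTED))
        assert predict_response_rate(m, (0, 1, 1, 1)) == pytest.approx(
            1 / (1 + math.exp(6.51 - 1.33 - 1.87 - 0.90)), rel=1e-9
        )
        assert predict_response_rate(m, (0, 0, 0, 0)) == pytest.approx(
            1 / (1 + math.exp(6.51)), rel=1e-9
        )
        zero = BehaviorModel(terms=(), coefficients={"intercept": 0.0})
        assert predict_response_rate(zero, (1, 0, 1, 0)) == 0.5

    def test_monotonicity_in_positive_coefficients(self):
        m = BehaviorModel(terms=tuple(k for k in PRINTED if k != "intercept"),
                          coefficients=dict(PRINTED))
        # size coefficient positive: enabling the size bit raises the rate
        assert predict_response_rate(m, (0, 0, 1, 1)) > \
            predict_response_rate(m, (0, 0, 0, 1))
        assert predict_response_rate(m, (0, 1, 1, 1)) > \
            predict_response_rate(m, (0, 0, 1, 1))


class TestStepwise:
    def test_noise_gives_intercept_only(self):
        rng = np.random.default_rng(3)
        tab = _bernoulli_table(2000, seed=3)
        tab["responded"] = (rng.random(len(tab)) < 0.05).astype(int)
        m = stepwise_select(tab, n_splits=5, seed=0)
        assert m.terms == ()
        assert abs(m.cv_r2) < 0.05

    def test_selected_model_predictively_matches_generator(self):
        tab = _bernoulli_table(8000, seed=4)
        m = stepwise_select(tab, n_splits=5, seed=0)
        assert m.cv_r2 > 0.8
        truth = BehaviorModel(
            terms=tuple(k for k in PRINTED if k != "intercept"),
            coefficients=dict(PRINTED),
        )
        for sid in range(16):
            code = feature_code(sid)
            assert predict_response_rate(m, code) == pytest.approx(
                truth.predict(code), abs=0.02
            )

    def test_invalid_splits(self):
        with pytest.raises(ValueError):
            stepwise_select(_bernoulli_table(10, seed=0), n_splits=0)


def _bernoulli_table(n_per_stim, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for sid in range(16):
        code = feature_code(sid)
        prob = logistic_response_probability(code, PRINTED)
        d, s, z, p = code
        rows.append(pd.DataFrame({
            "direction": d, "speed": s, "size": z, "polarity": p,
            "responded": (rng.random(n_per_stim) < prob).astype(int),
        }))
    return pd.concat(rows, ignore_index=True)


class TestAngularGeometry:
    def test_paramecium(self):
        angle, speed = angular_geometry(0.135, 0.5, 0.5)
        assert round(angle) == 15
        assert speed == pytest.approx(math.degrees(1.0), rel=1e-9)

    def test_small_size_limit_and_scale_invariance(self):
        a1, _ = angular_geometry(1e-9, 0.5)
        assert a1 == pytest.approx(0.0, abs=1e-6)
        a, _ = angular_geometry(1.0, 0.5)
        b, _ = angular_geometry(2.0, 1.0)
        assert a == pytest.approx(b)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            angular_geometry(0.1, 0.0)


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=60)
@given(
    st.floats(min_value=1e-3, max_value=10.0),
    st.floats(min_value=1e-3, max_value=10.0),
    st.floats(min_value=0.1, max_value=100.0),
)
def test_angular_geometry_scale_invariance(size, dist, scale):
    """Angular size depends only on the size/distance ratio."""
    a, _ = angular_geometry(size, dist)
    b, _ = angular_geometry(size * scale, dist * scale)
    assert a == pytest.approx(b, rel=1e-9)
    assert 0.0 < a < 180.0
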