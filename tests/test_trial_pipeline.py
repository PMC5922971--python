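"""Event-detection oracles on hand-built traces, plus summary statistics."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from edgecode.trial_pipeline import (
    EventSet,
    NoContactError,
    PipelineParams,
    TrialMeta,
    TrialRecord,
    UnsegmentableError,
    analyze_dataset,
    analyze_trial,
    detect_force_plateau,
    detect_touch,
    extract_events,
    find_speed_peaks,
    rotation_velocity,
    segment_rotation,
    summarize_dataset,
    trial_measures,
)
from edgecode.trial_pipeline import _threshold_75


def _min_jerk(u):
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def make_trial(
    touch_ms=1000.0,
    onset_ms=1200.0,
    amplitude=-20.0,
    duration_ms=360.0,
    initial=20.0,
    plateau=1.5,
    rise_ms=300.0,
    total_ms=3500,
    shutter_ms=None,
    second_onset_ms=None,
    second_amplitude=0.0,
    edge_length=math.inf,
):
    """Analytically clean trial: smoothstep force, min-jerk rotation(s)."""
    t = np.arange(total_ms, dtype=float)
    force = plateau * _smoothstep((t - touch_ms) / rise_ms)
    theta = np.full(total_ms, initial) + amplitude * _min_jerk(
        (t - onset_ms) / duration_ms
    )
    end_ms = onset_ms + duration_ms
    if second_onset_ms is not None:
        theta += second_amplitude * _min_jerk((t - second_onset_ms) / duration_ms)
        end_ms = second_onset_ms + duration_ms
    if shutter_ms is None:
        shutter_ms = end_ms + 300.0
    meta = TrialMeta(
        go_time_ms=600.0,
        shutter_open_ms=shutter_ms,
        initial_orientation=initial,
        edge_length=edge_length,
    )
    return TrialRecord(t, force, theta, meta), end_ms


def test_detect_touch_exact_on_clean_ramp():
    trial, _ = make_trial()
    # smoothstep exceeds baseline+0.01 N at u where 1.5*3u^2 ~ 0.01
    u = 0.01
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2
        lo, hi = (mid, hi) if 1.5 * _smoothstep(np.array([mid]))[0] <= u else (lo, mid)
    expected = 1000.0 + hi * 300.0
    assert detect_touch(trial) == pytest.approx(expected, abs=2.0)


def test_detect_touch_ignores_pre_contact_blip():
    trial, _ = make_trial()
    # a brief 0.05 N blip before contact must not capture the backward walk;
    # the clean ramp crosses baseline + 0.01 N at ~1014 ms (smoothstep root)
    trial.force[800:820] += 0.05
    assert detect_touch(trial) == pytest.approx(1015.0, abs=3.0)


def test_detect_touch_requires_contact():
    trial, _ = make_trial(plateau=0.1)  # never crosses the 0.2 N search level
    with pytest.raises(NoContactError):
        detect_touch(trial)


def test_plateau_on_smoothstep_oracle():
    # smoothstep rate r(u) = (plateau/rise) * 6u(1-u) peaks at u=0.5 and
    # falls below 10% of the peak at the larger root of 6u(1-u) = 0.6*0.25,
    # i.e. u = (1+sqrt(1-0.1))/2
    trial, _ = make_trial(touch_ms=1000.0, rise_ms=300.0, plateau=1.5)
    touch = detect_touch(trial)
    t_plateau, f_plateau = detect_force_plateau(trial, touch)
    u_star = (1.0 + math.sqrt(0.9)) / 2.0
    assert t_plateau == pytest.approx(1000.0 + u_star * 300.0, abs=6.0)
    assert f_plateau == pytest.approx(1.5 * _smoothstep(np.array([u_star]))[0], rel=0.02)


def test_plateau_window_skips_impact_transient():
    trial, _ = make_trial()
    touch = detect_touch(trial)
    # sharp 0.3 N impact bump within 20 ms of touch must not become the peak
    t = trial.time_ms
    s = np.maximum(t - touch, 0.0) / 8.0
    trial.force += np.where(t >= touch, 0.3 * s * np.exp(1.0 - s), 0.0)
    t_plateau, _ = detect_force_plateau(trial, touch)
    u_star = (1.0 + math.sqrt(0.9)) / 2.0
    assert t_plateau == pytest.approx(1000.0 + u_star * 300.0, abs=10.0)


def test_rotation_velocity_matches_min_jerk_derivative():
    trial, _ = make_trial(onset_ms=1200.0, amplitude=-20.0, duration_ms=360.0)
    v = rotation_velocity(trial)
    t = trial.time_ms
    u = np.clip((t - 1200.0) / 360.0, 0.0, 1.0)
    analytic = -20.0 * 30.0 * u**2 * (1 - u) ** 2 / 0.360
    mid = slice(1250, 1500)
    assert np.max(np.abs(v[mid] - analytic[mid])) < 0.5  # deg/s


def test_find_speed_peaks_single_min_jerk():
    trial, _ = make_trial()
    speed = np.abs(rotation_velocity(trial))
    peaks = find_speed_peaks(speed)
    assert len(peaks) == 1
    idx, val = peaks[0]
    assert idx == pytest.approx(1200 + 180, abs=5)  # min-jerk peak at mid-duration
    assert val == pytest.approx(1.875 * 20.0 / 0.360, rel=0.02)  # 15/8 * A/D


def test_find_speed_peaks_two_submovements():
    trial, _ = make_trial(
        amplitude=-12.0, second_onset_ms=1500.0, second_amplitude=-8.0
    )
    speed = np.abs(rotation_velocity(trial))
    peaks = find_speed_peaks(speed)
    assert len(peaks) == 2


def test_segment_single_movement_within_10ms():
    # the single minimum-jerk rotation oracle: onset/end within +/-10 ms
    trial, end_ms = make_trial(onset_ms=1200.0, duration_ms=360.0)
    speed = np.abs(rotation_velocity(trial))
    onset, boundaries, end = segment_rotation(trial, speed)
    assert abs(onset - 1200.0) <= 10.0
    assert abs(end - end_ms) <= 10.0
    assert boundaries == []


def test_segment_two_submovements():
    trial, end_ms = make_trial(
        onset_ms=1200.0,
        amplitude=-12.0,
        duration_ms=340.0,
        second_onset_ms=1490.0,
        second_amplitude=-8.0,
    )
    speed = np.abs(rotation_velocity(trial))
    onset, boundaries, end = segment_rotation(trial, speed)
    assert abs(onset - 1200.0) <= 10.0
    assert abs(end - end_ms) <= 10.0
    assert len(boundaries) == 1
    assert onset < boundaries[0] < end


def test_segment_excludes_post_shutter_correction():
    # a visually guided correction after the shutter opens must not drag the
    # detected end forward
    trial, end_ms = make_trial(shutter_ms=1900.0, total_ms=3500)
    t = trial.time_ms
    trial.orientation[:] = trial.orientation + 3.0 * _min_jerk((t - 2300.0) / 300.0)
    speed = np.abs(rotation_velocity(trial))
    _, _, end = segment_rotation(trial, speed)
    assert abs(end - end_ms) <= 10.0


def test_segment_requires_motion():
    trial, _ = make_trial(amplitude=0.0)
    speed = np.abs(rotation_velocity(trial))
    with pytest.raises(UnsegmentableError):
        segment_rotation(trial, speed)


def test_extract_events_ordering_and_measures():
    trial, end_ms = make_trial(initial=20.0, amplitude=-20.0)
    ev = extract_events(trial)
    assert ev.touch_ms <= ev.rotation_onset_ms <= ev.rotation_end_ms
    m = trial_measures(trial, ev)
    assert m.alignment_error == pytest.approx(0.0, abs=0.05)
    assert m.direction_correct
    assert m.displacement_toward_target == pytest.approx(20.0, abs=0.05)
    assert m.n_submovements == 1
    assert not m.aborted
    # touch is detected at the 0.01 N crossing (~1014 ms, not the nominal
    # 1000 ms ramp start), so the measured latency is ~186 ms
    assert m.rotation_onset_latency_ms == pytest.approx(186.0, abs=15.0)


def test_wrong_direction_measures():
    trial, _ = make_trial(initial=10.0, amplitude=8.0)  # rotates away from 0
    _, m = analyze_trial(trial)
    assert not m.direction_correct
    assert m.displacement_toward_target < 0


def test_eventset_invariant_validation():
    with pytest.raises(ValueError):
        EventSet(100.0, 150.0, 1.0, 90.0, [], 200.0, 0.5)  # onset before touch
    with pytest.raises(ValueError):
        EventSet(100.0, 150.0, 1.0, 120.0, [300.0], 250.0, 0.5)  # boundary > end
    with pytest.raises(ValueError):
        EventSet(100.0, 150.0, 1.0, 120.0, [200.0, 180.0], 250.0, 0.5)


def test_trialrecord_validation():
    t = np.arange(2000.0)
    with pytest.raises(ValueError):
        TrialRecord(t, np.zeros(1999), np.zeros(2000), TrialMeta(600, 1500, 10, 1.0))
    with pytest.raises(ValueError):
        TrialRecord(t[::2], np.zeros(1000), np.zeros(1000), TrialMeta(600, 1500, 10, 1.0))
    with pytest.raises(ValueError):
        # insufficient pre-go baseline
        TrialRecord(t, np.zeros(2000), np.zeros(2000), TrialMeta(300, 1500, 10, 1.0))


def test_analyze_dataset_keeps_failures_visible():
    good, _ = make_trial()
    bad, _ = make_trial(plateau=0.1)
    df = analyze_dataset([good, bad])
    assert list(df.analyzable) == [True, False]
    assert df.loc[1, "failure"] != ""
    assert np.isnan(df.loc[1, "alignment_error"])


def _measures_frame():
    rows = []
    for p in range(4):
        for length in (1.0, 2.0, 4.0):
            for k in range(5):
                err = (p + 1) + k  # medians: p+3 per participant
                rows.append(
                    {
                        "participant": p,
                        "edge_length": length,
                        "abs_error": float(err),
                        "direction_correct": bool((k + p) % 2 == 0) if length < 4 else True,
                        "analyzable": True,
                        "aborted": False,
                    }
                )
    return pd.DataFrame(rows)


def test_summarize_medians_before_means():
    df = _measures_frame()
    s = summarize_dataset(df)
    # per-participant medians are 3,4,5,6 -> mean 4.5 at every length
    assert np.allclose(s.abs_error["mean_of_medians"], 4.5)
    expected_sem = np.std([3, 4, 5, 6], ddof=1) / 2.0
    assert np.allclose(s.abs_error["sem"], expected_sem)
    assert (s.abs_error["n_participants"] == 4).all()


def test_summarize_excludes_aborted_and_unanalyzable():
    df = _measures_frame()
    df.loc[0, "abs_error"] = 1e9
    df.loc[0, "aborted"] = True
    df.loc[1, "abs_error"] = 1e9
    df.loc[1, "analyzable"] = False
    s = summarize_dataset(df)
    assert s.abs_error["mean_of_medians"].max() < 100


def test_threshold_75_interpolation_oracle():
    lengths = np.array([1.0, 2.0, 4.0, 8.0, np.inf])
    props = np.array([0.55, 0.70, 0.90, 0.99, 1.0])
    thr, censored = _threshold_75(lengths, props)
    # crossing between 2 and 4: 2 + 2*(0.05/0.20)
    assert thr == pytest.approx(2.5)
    assert not censored
    thr2, censored2 = _threshold_75(np.array([1.0, 2.0]), np.array([0.80, 0.99]))
    assert thr2 == 1.0 and censored2
    thr3, _ = _threshold_75(np.array([1.0, 2.0]), np.array([0.5, 0.6]))
    assert thr3 is None


def test_summary_threshold_from_frame():
    df = _measures_frame()  # p_correct 0.5 at 1,2 mm and 1.0 at 4 mm
    s = summarize_dataset(df)
    assert s.threshold_mm == pytest.approx(2.0 + 2.0 * 0.25 / 0.5)


def test_log_and_arcsine_transforms_run():
    df = _measures_frame()
    s = summarize_dataset(df, log_transform=True, arcsine_transform=True)
    # geometric mean of medians 3,4,5,6
    gm = 10 ** np.mean(np.log10([3, 4, 5, 6]))
    assert np.allclose(s.abs_error["mean_of_medians"], gm)
    assert ((s.proportion_correct["proportion"] >= 0) & (s.proportion_correct["proportion"] <= 1)).all()


def test_abort_rule():
    trial, _ = make_trial(onset_ms=1400.0)  # 400 ms latency > 350 ms rule
    _, m = analyze_trial(trial)
    assert m.aborted
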