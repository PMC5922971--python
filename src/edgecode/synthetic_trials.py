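"""Synthetic pointer-alignment trials with ground truth.

The generator emulates the structure of tactile pointer-alignment data so
the event-detection pipeline can be validated by parameter recovery:

* normal force rises from baseline to a plateau (~1.64 N) over ~0.31 s via
  a smooth ramp with a fast contact-compliance component at touch;
* the dial rotation is a minimum-jerk displacement from the initial
  orientation to a sampled final orientation, starting ~0.20 s after touch,
  optionally split into two overlapping minimum-jerk sub-movements (44% of
  eligible trials, second sub-movement ~0.22 s after rotation onset);
* per-edge-length outcome models control the probability of rotating in the
  correct direction and the spread of the signed alignment error, with the
  pointer range clipped to +/-38 deg and ~15 deg movements for the
  orientation-free raised dot;
* the shutter-opening time follows the apparatus' online rule -- rotation
  speed (first-order low-pass, 10 ms time constant) below 10 deg/s for at
  least 200 ms -- plus a command/opening latency, and trials ending outside
  the +/-2 deg target zone get a visually guided correction after the
  shutter opens.

Every trial is emitted together with its ground truth so detection bias and
RMSE can be reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .filters import first_order_lowpass
from .trial_pipeline import TrialMeta, TrialRecord

__all__ = [
    "LengthModel",
    "GeneratorConfig",
    "GroundTruth",
    "sample_trial_outcome",
    "synthesize_traces",
    "generate_participant",
    "generate_dataset",
    "expected_summary",
    "recovery_report",
]

FS = 1000.0  # Hz
DT_MS = 1.0

DEFAULT_EDGE_LENGTHS = (0.0, 1.0, 2.0, 4.0, 8.0, math.inf)
DEFAULT_ORIENTATIONS = (-30.0, -20.0, -10.0, 10.0, 20.0, 30.0)


@dataclass(frozen=True)
class LengthModel:
    """Outcome model for one edge length."""

    p_correct: float
    error_sd: float  # deg, signed error about the target on correct trials

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError("p_correct must lie in [0, 1]")


def _default_length_models() -> dict[float, LengthModel]:
    # p_correct falls from near-ceiling (full-span edge) to chance (dot),
    # crossing 75% at 2 mm; error SDs are back-derived from the absolute
    # alignment-error levels the task produces at each length
    # (median |error| ~2.9 deg full-span, ~11.1 deg at 2 mm, roughly
    # doubling again for the orientation-free dot).
    return {
        math.inf: LengthModel(0.995, 4.30),
        8.0: LengthModel(0.98, 5.93),
        4.0: LengthModel(0.92, 8.70),
        2.0: LengthModel(0.75, 11.47),
        1.0: LengthModel(0.58, 13.50),
        0.0: LengthModel(0.50, float("nan")),  # dot: magnitude model applies
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design and trace-synthesis parameters (defaults: task values)."""

    # design
    edge_lengths: tuple[float, ...] = DEFAULT_EDGE_LENGTHS
    initial_orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS
    repeats: int = 18  # per (length, orientation); 3 blocks x 6
    blocks_per_length: int = 3
    n_participants: int = 10
    length_models: dict[float, LengthModel] = field(
        default_factory=_default_length_models
    )
    pointer_range_deg: float = 38.0
    target_zone_deg: float = 2.0

    # outcome model
    wrong_magnitude_mean: float = 15.0  # deg, dot / wrong-direction movements
    wrong_magnitude_sd: float = 5.0
    min_movement_deg: float = 3.0  # task movements are never this small
    submovement_prob: float = 0.44
    submovement_lag_s: float = 0.22
    submovement_lag_sd_s: float = 0.02
    submovement_min_amplitude_deg: float = 10.0
    submovement_min_second_deg: float = 5.0

    # timing
    go_time_ms: float = 600.0
    reach_mean_s: float = 0.35
    reach_sd_s: float = 0.05
    onset_latency_mean_s: float = 0.20
    onset_latency_between_sd_s: float = 0.02
    onset_latency_within_sd_range_s: tuple[float, float] = (0.046, 0.055)
    max_latency_s: float = 0.34  # apparatus aborts trials starting later
    rotation_duration_base_s: float = 0.30
    rotation_duration_per_deg_s: float = 0.003

    # force profile
    plateau_force_mean: float = 1.64
    plateau_force_sd: float = 0.83
    plateau_force_range: tuple[float, float] = (0.3, 4.0)
    force_rise_mean_s: float = 0.31
    force_rise_sd_s: float = 0.09
    force_rise_range_s: tuple[float, float] = (0.15, 0.60)
    contact_fraction: float = 0.05  # fast compliance component of the ramp
    contact_tau_s: float = 0.003
    impact_transient_n: float = 0.10  # brief impact bump at touch
    impact_tau_s: float = 0.008

    # apparatus online logic
    online_speed_threshold: float = 10.0  # deg/s
    online_dwell_ms: float = 200.0
    online_filter_tau_s: float = 0.010
    # Command + glasses-opening latency.  Must exceed the longest stretch of
    # sub-threshold speed before the true rotation end, or the offline
    # ">=200 ms before shutter" rule would discard the end-of-rotation
    # minimum: a minimum-jerk tail stays below 10 deg/s for at most
    # ~0.25 * duration ~= 76 ms at the smallest task amplitude (3 deg,
    # ~0.31 s), so 100 ms leaves a >=24 ms margin.
    shutter_latency_ms: float = 100.0
    correction_reaction_ms: float = 250.0
    correction_duration_ms: float = 300.0

    # sensor noise (SD of additive Gaussian noise); noise_scale=0 disables
    force_noise_sd: float = 0.002  # N
    orientation_noise_sd: float = 0.005  # deg
    noise_scale: float = 1.0


@dataclass
class GroundTruth:
    """Event times and outcomes as constructed, for recovery testing."""

    touch_ms: float
    onset_ms: float
    submovement_onsets_ms: list[float]
    end_ms: float
    final_orientation: float
    plateau_force: float
    direction_correct: bool
    shutter_open_ms: float = float("nan")

    @property
    def n_submovements(self) -> int:
        return 1 + len(self.submovement_onsets_ms)


def sample_trial_outcome(
    edge_length: float,
    initial_orientation: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """Draw (final orientation deg, direction_correct) for one trial.

    Direction is Bernoulli(p_correct(length)).  Correct trials land at a
    Normal(0, sd(length)) orientation about the target (resampled until the
    movement actually heads toward the target and is at least the minimum
    task amplitude); wrong-direction trials move ~15 deg away.  The raised
    dot carries no orientation information: movements are ~15 deg with a
    random sign.  Final orientations are clipped to the +/-38 deg pointer
    range.
    """
    if edge_length not in cfg.length_models:
        raise KeyError(f"no outcome model for edge length {edge_length}")
    model = cfg.length_models[edge_length]
    lo, hi = -cfg.pointer_range_deg, cfg.pointer_range_deg
    sign = math.copysign(1.0, initial_orientation)
    correct = bool(rng.random() < model.p_correct)

    def magnitude() -> float:
        return float(
            np.clip(
                rng.normal(cfg.wrong_magnitude_mean, cfg.wrong_magnitude_sd),
                cfg.min_movement_deg,
                35.0,
            )
        )

    if edge_length == 0.0:
        m = magnitude()
        final = initial_orientation - sign * m if correct else initial_orientation + sign * m
    elif correct:
        final = 0.0
        for _ in range(200):
            cand = rng.normal(0.0, model.error_sd)
            toward = sign * (initial_orientation - cand) > 0
            if toward and abs(initial_orientation - cand) >= cfg.min_movement_deg:
                final = cand
                break
    else:
        final = initial_orientation + sign * magnitude()
    return float(np.clip(final, lo, hi)), correct


def _min_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def synthesize_traces(
    final_orientation: float,
    direction_correct: bool,
    edge_length: float,
    initial_orientation: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    participant: int = 0,
    trial: int = 0,
    latency_mean_s: float | None = None,
    latency_sd_s: float | None = None,
) -> tuple[TrialRecord, GroundTruth]:
    """Emit one 1 kHz trial trace pair plus its ground truth."""
    latency_mean = cfg.onset_latency_mean_s if latency_mean_s is None else latency_mean_s
    latency_sd = (
        float(np.mean(cfg.onset_latency_within_sd_range_s))
        if latency_sd_s is None
        else latency_sd_s
    )

    touch_ms = cfg.go_time_ms + 1000.0 * float(
        np.clip(rng.normal(cfg.reach_mean_s, cfg.reach_sd_s), 0.25, 0.50)
    )
    onset_ms = touch_ms + 1000.0 * float(
        np.clip(rng.normal(latency_mean, latency_sd), 0.08, cfg.max_latency_s)
    )
    delta = final_orientation - initial_orientation

    def duration_ms(amplitude: float) -> float:
        return 1000.0 * (
            cfg.rotation_duration_base_s + cfg.rotation_duration_per_deg_s * abs(amplitude)
        )

    # sub-movement split: only when the movement is big enough that the
    # second sub-movement still exceeds the apparatus' 10 deg/s threshold
    segments: list[tuple[float, float, float]] = []  # (start_ms, amplitude, dur_ms)
    use_sub = (
        abs(delta) >= cfg.submovement_min_amplitude_deg
        and rng.random() < cfg.submovement_prob
    )
    if use_sub:
        f_hi = min(0.7, 1.0 - cfg.submovement_min_second_deg / abs(delta))
        f1 = rng.uniform(0.4, max(0.4, f_hi))
        d1, d2 = f1 * delta, (1.0 - f1) * delta
        dur1 = duration_ms(d1)
        # The second sub-movement commences only after the first's velocity
        # peak (mid-duration) with some margin; starting earlier would merge
        # the two components into a single-peaked speed profile, which the
        # label "two sub-movements" would then misdescribe.
        lag_ms = max(
            1000.0 * rng.normal(cfg.submovement_lag_s, cfg.submovement_lag_sd_s),
            0.5 * dur1 + 60.0,
        )
        segments.append((onset_ms, d1, dur1))
        segments.append((onset_ms + lag_ms, d2, duration_ms(d2)))
    else:
        segments.append((onset_ms, delta, duration_ms(delta)))
    true_end_ms = max(start + dur for start, _, dur in segments)

    # --- provisional clean orientation profile for the online shutter rule
    t_prov = int(math.ceil(true_end_ms + 1500.0))
    t = np.arange(t_prov, dtype=float)
    theta = np.full(t_prov, initial_orientation, dtype=float)
    for start, amp, dur in segments:
        theta += amp * _min_jerk((t - start) / dur)

    shutter_ms = _online_shutter_time(theta, onset_ms, true_end_ms, cfg)

    # --- visually guided correction when the rotation missed the target zone
    needs_fix = abs(final_orientation) > cfg.target_zone_deg
    if needs_fix:
        fix_start = shutter_ms + max(100.0, rng.normal(cfg.correction_reaction_ms, 30.0))
        fix_target = float(rng.uniform(-1.0, 1.0))
        total_ms = int(math.ceil(fix_start + cfg.correction_duration_ms + 400.0))
    else:
        fix_start, fix_target = None, None
        total_ms = int(math.ceil(shutter_ms + 700.0))

    t = np.arange(total_ms, dtype=float)
    theta = np.full(total_ms, initial_orientation, dtype=float)
    for start, amp, dur in segments:
        theta += amp * _min_jerk((t - start) / dur)
    if needs_fix:
        theta += (fix_target - final_orientation) * _min_jerk(
            (t - fix_start) / cfg.correction_duration_ms
        )

    # --- force trace: fast contact compliance + smooth ramp to plateau
    plateau = float(
        np.clip(
            rng.normal(cfg.plateau_force_mean, cfg.plateau_force_sd),
            *cfg.plateau_force_range,
        )
    )
    rise_ms = 1000.0 * float(
        np.clip(rng.normal(cfg.force_rise_mean_s, cfg.force_rise_sd_s), *cfg.force_rise_range_s)
    )
    s = t - touch_ms
    contact = np.where(s >= 0.0, 1.0 - np.exp(-np.maximum(s, 0.0) / (1000.0 * cfg.contact_tau_s)), 0.0)
    ramp = _smoothstep(s / rise_ms)
    force = plateau * ((1.0 - cfg.contact_fraction) * ramp + cfg.contact_fraction * contact)
    if cfg.impact_transient_n > 0.0:
        tau = 1000.0 * cfg.impact_tau_s
        sn = np.maximum(s, 0.0) / tau
        force += np.where(s >= 0.0, cfg.impact_transient_n * sn * np.exp(1.0 - sn), 0.0)

    if cfg.noise_scale > 0.0:
        force = force + rng.normal(0.0, cfg.noise_scale * cfg.force_noise_sd, total_ms)
        theta = theta + rng.normal(
            0.0, cfg.noise_scale * cfg.orientation_noise_sd, total_ms
        )

    meta = TrialMeta(
        go_time_ms=cfg.go_time_ms,
        shutter_open_ms=shutter_ms,
        initial_orientation=initial_orientation,
        edge_length=edge_length,
        participant=participant,
        trial=trial,
    )
    record = TrialRecord(time_ms=t, force=force, orientation=theta, meta=meta)
    truth = GroundTruth(
        touch_ms=touch_ms,
        onset_ms=onset_ms,
        submovement_onsets_ms=[seg[0] for seg in segments[1:]],
        end_ms=true_end_ms,
        final_orientation=final_orientation,
        plateau_force=plateau,
        direction_correct=direction_correct,
        shutter_open_ms=shutter_ms,
    )
    return record, truth


def _online_shutter_time(
    theta: np.ndarray, onset_ms: float, true_end_ms: float, cfg: GeneratorConfig
) -> float:
    """Apparatus rule: shutter opens once the first-order-filtered rotation
    speed has stayed below 10 deg/s for 200 ms, plus opening latency."""
    v = np.abs(np.diff(theta, prepend=theta[0])) * FS
    speed = first_order_lowpass(v, cfg.online_filter_tau_s, FS)
    dwell = int(cfg.online_dwell_ms)
    above = np.flatnonzero(speed >= cfg.online_speed_threshold)
    if above.size == 0:
        # no detectable rotation: the rule would fire on the quiet trace;
        # anchor it just after the true kinematic end instead
        return true_end_ms + cfg.online_dwell_ms + cfg.shutter_latency_ms
    start = int(above[-1]) + 1
    below = speed[start:] < cfg.online_speed_threshold
    run = 0
    for i, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run >= dwell:
            return float(start + i + 1) + cfg.shutter_latency_ms
    return float(len(speed)) + cfg.shutter_latency_ms


def generate_participant(
    participant: int,
    cfg: GeneratorConfig,
    seed: np.random.SeedSequence | int,
) -> list[tuple[TrialRecord, GroundTruth]]:
    """All trials of one participant: blocks of constant edge length with
    the initial orientations randomly interleaved within blocks."""
    rng = np.random.default_rng(seed)
    latency_mean = float(rng.normal(cfg.onset_latency_mean_s, cfg.onset_latency_between_sd_s))
    latency_sd = float(rng.uniform(*cfg.onset_latency_within_sd_range_s))
    repeats_per_block = cfg.repeats // cfg.blocks_per_length

    out: list[tuple[TrialRecord, GroundTruth]] = []
    trial_id = 0
    for length in cfg.edge_lengths:
        for _ in range(cfg.blocks_per_length):
            block = np.repeat(cfg.initial_orientations, repeats_per_block)
            rng.shuffle(block)
            for init in block:
                final, correct = sample_trial_outcome(length, float(init), cfg, rng)
                rec, truth = synthesize_traces(
                    final,
                    correct,
                    length,
                    float(init),
                    cfg,
                    rng,
                    participant=participant,
                    trial=trial_id,
                    latency_mean_s=latency_mean,
                    latency_sd_s=latency_sd,
                )
                out.append((rec, truth))
                trial_id += 1
    return out


def generate_dataset(
    cfg: GeneratorConfig, seed: int = 0
) -> list[tuple[TrialRecord, GroundTruth]]:
    """Full factorial dataset: participants x lengths x orientations x repeats."""
    children = np.random.SeedSequence(seed).spawn(cfg.n_participants)
    out: list[tuple[TrialRecord, GroundTruth]] = []
    for p, child in enumerate(children):
        out.extend(generate_participant(p, cfg, child))
    return out


def expected_summary(
    cfg: GeneratorConfig, seed: int = 12345, n_per_length: int = 20000
) -> pd.DataFrame:
    """Monte-Carlo expectation of the summary statistics implied by the
    outcome model alone (no traces, no event detection).

    Columns: edge_length, abs_error_median, p_correct.  These are the
    calibration targets that an end-to-end analysis of generated traces
    should recover up to sampling error.
    """
    rng = np.random.default_rng(seed)
    orients = np.asarray(cfg.initial_orientations, float)
    rows = []
    for length in cfg.edge_lengths:
        finals = np.empty(n_per_length)
        corrects = np.empty(n_per_length, dtype=bool)
        for i in range(n_per_length):
            init = float(orients[i % len(orients)])
            finals[i], corrects[i] = sample_trial_outcome(length, init, cfg, rng)
        rows.append(
            {
                "edge_length": length,
                "abs_error_median": float(np.median(np.abs(finals))),
                "p_correct": float(corrects.mean()),
            }
        )
    return pd.DataFrame(rows)


def recovery_report(
    truths: list[GroundTruth], results: pd.DataFrame
) -> pd.DataFrame:
    """Per-event bias and RMSE of the pipeline against ground truth.

    ``results`` is the tidy table from ``analyze_dataset`` in the same trial
    order as ``truths``.  Columns of the report: event, bias, rmse, max_abs,
    n; a final row counts trials whose event-ordering invariants failed
    (the pipeline flags these as unanalyzable).
    """
    if len(truths) != len(results):
        raise ValueError("ground truth and results must align one-to-one")
    if not truths:
        return pd.DataFrame(columns=["event", "bias", "rmse", "max_abs", "n"])
    ok = results["analyzable"].to_numpy(bool)
    rows = []
    pairs = {
        "touch_ms": [t.touch_ms for t in truths],
        "rotation_onset_ms": [t.onset_ms for t in truths],
        "rotation_end_ms": [t.end_ms for t in truths],
    }
    for col, truth_vals in pairs.items():
        err = results[col].to_numpy(float)[ok] - np.asarray(truth_vals)[ok]
        rows.append(_err_row(col.replace("_ms", ""), err))
    rel = (
        results["plateau_force"].to_numpy(float)[ok]
        / np.asarray([t.plateau_force for t in truths])[ok]
        - 1.0
    )
    rows.append(_err_row("plateau_force_rel", rel))
    rows.append(
        {
            "event": "unanalyzable_trials",
            "bias": np.nan,
            "rmse": np.nan,
            "max_abs": np.nan,
            "n": int((~ok).sum()),
        }
    )
    return pd.DataFrame(rows)


def _err_row(name: str, err: np.ndarray) -> dict:
    err = err[~np.isnan(err)]
    if err.size == 0:
        return {"event": name, "bias": np.nan, "rmse": np.nan, "max_abs": np.nan, "n": 0}
    return {
        "event": name,
        "bias": float(err.mean()),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "max_abs": float(np.abs(err).max()),
        "n": int(err.size),
    }
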