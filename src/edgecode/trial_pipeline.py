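"""Event detection and summary statistics for pointer-alignment trials.

Each trial consists of a normal-force trace (N) and a dial-orientation
trace (deg) sampled at 1 kHz, plus metadata (go-signal time, shutter-open
time, initial orientation, edge length).  The pipeline extracts:

* touch -- first force sample above 0.01 N over the pre-go baseline median,
  found by locating a 0.2 N crossing and walking backwards (robust to brief
  force blips before true contact);
* force plateau -- the instant the 8.7 Hz-filtered force rate first drops
  below 10% of its maximum local peak in the 50-350 ms post-touch window
  (the window excludes the initial impact transient);
* rotation onset, sub-movement boundaries and rotation end -- minima of a
  2.1 Hz high-pass-filtered version of the rotation speed, anchored on the
  velocity peaks;
* per-trial measures (signed alignment error, displacement toward the
  target, direction correctness, latency, duration, sub-movement count);
* per-edge-length summaries: participant medians of |error| averaged across
  participants, proportion of correct-direction rotations, and the 75%
  correct-direction edge-length threshold by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import (
    highpass_triangular,
    lowpass_triangular,
    symmetric_difference,
)

__all__ = [
    "TrialMeta",
    "TrialRecord",
    "EventSet",
    "TrialMeasures",
    "SummaryTable",
    "PipelineParams",
    "PipelineError",
    "NoContactError",
    "NoRatePeakError",
    "UnsegmentableError",
    "make_triangular_filter",
    "detect_touch",
    "detect_force_plateau",
    "rotation_velocity",
    "find_speed_peaks",
    "segment_rotation",
    "extract_events",
    "trial_measures",
    "analyze_trial",
    "analyze_dataset",
    "summarize_dataset",
]

FS_HZ = 1000.0


class PipelineError(RuntimeError):
    """A trial that cannot be analyzed (no contact, no rotation, ...)."""


class NoContactError(PipelineError):
    pass


class NoRatePeakError(PipelineError):
    pass


class UnsegmentableError(PipelineError):
    pass


@dataclass(frozen=True)
class TrialMeta:
    go_time_ms: float
    shutter_open_ms: float
    initial_orientation: float  # deg
    edge_length: float  # mm (inf allowed for the full-span edge)
    participant: int = 0
    trial: int = 0


@dataclass
class TrialRecord:
    """1 kHz force and orientation traces plus trial metadata."""

    time_ms: np.ndarray
    force: np.ndarray  # N
    orientation: np.ndarray  # deg
    meta: TrialMeta

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, float)
        self.force = np.asarray(self.force, float)
        self.orientation = np.asarray(self.orientation, float)
        n = len(self.time_ms)
        if len(self.force) != n or len(self.orientation) != n:
            raise ValueError("traces must have equal length")
        dt = np.diff(self.time_ms)
        if n > 1 and not np.allclose(dt, 1.0, atol=1e-6):
            raise ValueError("traces must be sampled on a uniform 1 ms grid")
        if self.meta.go_time_ms - self.time_ms[0] < 500.0:
            raise ValueError("need >= 500 ms of pre-go baseline")

    def index_of(self, t_ms: float) -> int:
        return int(round(t_ms - self.time_ms[0]))

    def time_at(self, idx: int) -> float:
        return float(self.time_ms[idx])


@dataclass(frozen=True)
class PipelineParams:
    """Tunable detection parameters (defaults follow the analysis recipe)."""

    touch_force_search: float = 0.2  # N, forward search level
    touch_force_criterion: float = 0.01  # N above pre-go baseline median
    baseline_window_ms: float = 500.0
    rate_cutoff_hz: float = 8.7
    rate_peak_window_ms: tuple[float, float] = (50.0, 350.0)
    rate_peak_fraction: float = 0.1
    rate_min_peak: float = 0.05  # N/s, smallest credible force-rate peak
    velocity_cutoff_hz: float = 17.0
    speed_peak_cutoff_hz: float = 8.7
    highpass_cutoff_hz: float = 2.1
    min_peak_speed: float = 5.0  # deg/s, ignore sub-noise ripples
    minimum_prominence_sds: float = 8.0  # noise gate for high-pass minima
    end_rule_ms: float = 200.0  # minima this close to shutter opening are excluded
    max_onset_latency_ms: float = 350.0  # the apparatus' abort rule


@dataclass
class EventSet:
    touch_ms: float
    force_plateau_ms: float
    plateau_force: float
    rotation_onset_ms: float
    submovement_boundaries_ms: list[float]
    rotation_end_ms: float
    force_at_onset: float

    def __post_init__(self) -> None:
        if not (self.touch_ms <= self.rotation_onset_ms <= self.rotation_end_ms):
            raise ValueError("event ordering violated: touch <= onset <= end")
        b = self.submovement_boundaries_ms
        if any(x >= y for x, y in zip(b, b[1:])):
            raise ValueError("sub-movement boundaries must strictly increase")
        if b and not (self.rotation_onset_ms < b[0] and b[-1] < self.rotation_end_ms):
            raise ValueError("boundaries must lie inside (onset, end)")


@dataclass
class TrialMeasures:
    alignment_error: float  # deg, signed (target at 0)
    abs_error: float
    displacement_toward_target: float  # deg, positive = toward target
    direction_correct: bool
    rotation_onset_latency_ms: float
    rotation_duration_ms: float
    n_submovements: int
    aborted: bool = False  # onset later than the apparatus' 350 ms rule


def make_triangular_filter(cutoff_hz: float, fs: float = FS_HZ) -> np.ndarray:
    """Symmetric triangular kernel whose -3 dB point matches the cutoff."""
    from .filters import triangular_halfwidth, triangular_kernel

    return triangular_kernel(triangular_halfwidth(cutoff_hz, fs))


def detect_touch(trial: TrialRecord, params: PipelineParams = PipelineParams()) -> float:
    """Time (ms) the finger first contacted the dial."""
    go = trial.index_of(trial.meta.go_time_ms)
    b0 = trial.index_of(trial.meta.go_time_ms - params.baseline_window_ms)
    baseline = float(np.median(trial.force[max(b0, 0) : go]))
    criterion = baseline + params.touch_force_criterion

    above = np.flatnonzero(trial.force[go:] > params.touch_force_search)
    if above.size == 0:
        raise NoContactError("normal force never exceeded the 0.2 N search level")
    anchor = go + int(above[0])
    i = anchor
    while i > 0 and trial.force[i - 1] > criterion:
        i -= 1
    # i is now the first sample of the run exceeding the criterion that
    # contains the 0.2 N crossing, i.e. the sample after the last one at or
    # below the criterion level.
    return trial.time_at(i)


def _force_rate(trial: TrialRecord, params: PipelineParams) -> np.ndarray:
    smooth = lowpass_triangular(trial.force, params.rate_cutoff_hz, FS_HZ)
    return symmetric_difference(smooth, FS_HZ)


def detect_force_plateau(
    trial: TrialRecord,
    touch_ms: float,
    params: PipelineParams = PipelineParams(),
) -> tuple[float, float]:
    """(plateau time ms, plateau force N).

    The force-rate peak is the maximum of the smoothed rate in the 50-350 ms
    post-touch window (the lower bound skips the brief impact transient at
    contact); the plateau is where the rate first falls below 10% of that
    peak.  Taking the window maximum rather than an interior local peak
    keeps fast force ramps analyzable: their true rate peak can precede the
    window, in which case the decaying flank inside it is the right anchor.
    """
    rate = _force_rate(trial, params)
    lo = trial.index_of(touch_ms + params.rate_peak_window_ms[0])
    hi = trial.index_of(touch_ms + params.rate_peak_window_ms[1])
    lo, hi = max(lo, 0), min(hi, len(rate) - 1)
    window = rate[lo : hi + 1]
    peak_idx = lo + int(np.argmax(window))
    peak_rate = rate[peak_idx]
    if peak_rate < params.rate_min_peak:
        raise NoRatePeakError(
            "no credible force-rate peak 50-350 ms after touch"
        )
    below = np.flatnonzero(rate[peak_idx:] < params.rate_peak_fraction * peak_rate)
    if below.size == 0:
        raise NoRatePeakError("force rate never fell below 10% of its peak")
    idx = peak_idx + int(below[0])
    return trial.time_at(idx), float(trial.force[idx])


def rotation_velocity(
    trial: TrialRecord, params: PipelineParams = PipelineParams()
) -> np.ndarray:
    """Dial rotation velocity (deg/s): 17 Hz low-pass then +/-1-sample
    central difference."""
    smooth = lowpass_triangular(trial.orientation, params.velocity_cutoff_hz, FS_HZ)
    return symmetric_difference(smooth, FS_HZ)


def _local_minima(x: np.ndarray) -> np.ndarray:
    """Strict local minima; plateaus resolve to their earliest sample."""
    d = np.sign(np.diff(x))
    # carry the next non-zero slope backwards across flat runs
    for i in range(len(d) - 2, -1, -1):
        if d[i] == 0:
            d[i] = d[i + 1]
    return np.flatnonzero((d[1:] > 0) & (d[:-1] < 0)) + 1


def find_speed_peaks(
    speed: np.ndarray, params: PipelineParams = PipelineParams()
) -> list[tuple[int, float]]:
    """Velocity-profile peaks: negative-slope zero crossings of the 8.7 Hz
    low-passed derivative of the rotation speed (|velocity|).

    Returns (sample index, speed) pairs; ripples below ``min_peak_speed``
    are ignored.
    """
    dspeed = lowpass_triangular(
        symmetric_difference(speed, FS_HZ), params.speed_peak_cutoff_hz, FS_HZ
    )
    pos = dspeed > 0
    crossings = np.flatnonzero(pos[:-1] & ~pos[1:]) + 1
    return [(int(i), float(speed[i])) for i in crossings if speed[i] >= params.min_peak_speed]


def segment_rotation(
    trial: TrialRecord,
    speed: np.ndarray,
    shutter_open_ms: float | None = None,
    params: PipelineParams = PipelineParams(),
) -> tuple[float, list[float], float]:
    """(onset ms, sub-movement boundaries ms, end ms).

    Minima of the 2.1 Hz high-pass-filtered speed segment the rotation.
    Everything within ``end_rule_ms`` of the shutter opening (and later) is
    excluded first -- those peaks and minima belong to the visually guided
    final adjustment, not to the rotation under study.  The onset is the
    first remaining minimum searching backwards from the first velocity
    peak; the end is the last remaining minimum (for a single-peak trial
    this is simply the next minimum after the peak); interior minima are
    sub-movement boundaries.
    """
    if shutter_open_ms is None:
        shutter_open_ms = trial.meta.shutter_open_ms
    cutoff = trial.index_of(shutter_open_ms - params.end_rule_ms)
    peaks = [p for p in find_speed_peaks(speed, params) if p[0] <= cutoff]
    if not peaks:
        raise UnsegmentableError("no velocity peak before shutter opening")
    first_peak = peaks[0][0]

    hp = highpass_triangular(speed, params.highpass_cutoff_hz, FS_HZ)
    minima = _local_minima(hp)
    # Sensor noise sprinkles shallow ripples over the high-passed speed;
    # keep only minima whose prominence clears the trace's own noise floor,
    # estimated robustly from the quiet pre-go baseline (zero when clean).
    base_hi = max(trial.index_of(trial.meta.go_time_ms), 2)
    base = hp[:base_hi]
    noise_sd = 1.4826 * float(np.median(np.abs(base - np.median(base))))
    if noise_sd > 0.0 and minima.size:
        from scipy.signal import peak_prominences

        prom = peak_prominences(-hp, minima)[0]
        minima = minima[prom >= params.minimum_prominence_sds * noise_sd]
    minima = minima[minima <= cutoff]
    before = minima[minima <= first_peak]
    if before.size == 0:
        raise UnsegmentableError("no high-pass speed minimum before the first peak")
    onset_idx = int(before[-1])

    after = minima[minima > first_peak]
    if after.size == 0:
        raise UnsegmentableError(
            "no qualifying end minimum >= 200 ms before shutter opening"
        )
    end_idx = int(after[-1])

    interior = [int(i) for i in after if onset_idx < i < end_idx]
    return (
        trial.time_at(onset_idx),
        [trial.time_at(i) for i in interior],
        trial.time_at(end_idx),
    )


def extract_events(
    trial: TrialRecord, params: PipelineParams = PipelineParams()
) -> EventSet:
    """Run the full event-detection chain on one trial."""
    touch = detect_touch(trial, params)
    plateau_t, plateau_f = detect_force_plateau(trial, touch, params)
    speed = np.abs(rotation_velocity(trial, params))
    onset, boundaries, end = segment_rotation(
        trial, speed, trial.meta.shutter_open_ms, params
    )
    if onset < touch:
        raise UnsegmentableError("rotation onset detected before touch")
    return EventSet(
        touch_ms=touch,
        force_plateau_ms=plateau_t,
        plateau_force=plateau_f,
        rotation_onset_ms=onset,
        submovement_boundaries_ms=boundaries,
        rotation_end_ms=end,
        force_at_onset=float(trial.force[trial.index_of(onset)]),
    )


def trial_measures(
    trial: TrialRecord,
    events: EventSet,
    params: PipelineParams = PipelineParams(),
) -> TrialMeasures:
    """Per-trial outcome measures from the detected events.

    The resultant orientation is read at the rotation end; since the target
    sits at 0 deg it is the signed alignment error.  Displacement is signed
    positive toward the target: rotating from the initial orientation toward
    0 counts as correct, away (or not at all) as incorrect.
    """
    final = float(trial.orientation[trial.index_of(events.rotation_end_ms)])
    initial = trial.meta.initial_orientation
    displacement = float(np.sign(initial)) * (initial - final)
    latency = events.rotation_onset_ms - events.touch_ms
    return TrialMeasures(
        alignment_error=final,
        abs_error=abs(final),
        displacement_toward_target=displacement,
        direction_correct=displacement > 0,
        rotation_onset_latency_ms=latency,
        rotation_duration_ms=events.rotation_end_ms - events.rotation_onset_ms,
        n_submovements=len(events.submovement_boundaries_ms) + 1,
        aborted=latency > params.max_onset_latency_ms,
    )


def analyze_trial(
    trial: TrialRecord, params: PipelineParams = PipelineParams()
) -> tuple[EventSet, TrialMeasures]:
    events = extract_events(trial, params)
    return events, trial_measures(trial, events, params)


def analyze_dataset(
    trials: list[TrialRecord], params: PipelineParams = PipelineParams()
) -> pd.DataFrame:
    """Analyze many trials into a tidy per-trial table.

    Trials the pipeline cannot segment are kept with ``analyzable = False``
    and NaN measures so the failure rate stays visible.
    """
    rows = []
    for trial in trials:
        meta = trial.meta
        row = {
            "participant": meta.participant,
            "trial": meta.trial,
            "edge_length": meta.edge_length,
            "initial_orientation": meta.initial_orientation,
            "analyzable": True,
            "aborted": False,
        }
        try:
            ev, m = analyze_trial(trial, params)
        except PipelineError as exc:
            row.update(
                analyzable=False,
                failure=str(exc),
                **dict.fromkeys(
                    [
                        "touch_ms", "force_plateau_ms", "plateau_force",
                        "rotation_onset_ms", "rotation_end_ms", "force_at_onset",
                        "alignment_error", "abs_error",
                        "displacement_toward_target", "direction_correct",
                        "rotation_onset_latency_ms", "rotation_duration_ms",
                        "n_submovements",
                    ],
                    np.nan,
                ),
            )
        else:
            row.update(
                failure="",
                touch_ms=ev.touch_ms,
                force_plateau_ms=ev.force_plateau_ms,
                plateau_force=ev.plateau_force,
                rotation_onset_ms=ev.rotation_onset_ms,
                rotation_end_ms=ev.rotation_end_ms,
                force_at_onset=ev.force_at_onset,
                alignment_error=m.alignment_error,
                abs_error=m.abs_error,
                displacement_toward_target=m.displacement_toward_target,
                direction_correct=m.direction_correct,
                rotation_onset_latency_ms=m.rotation_onset_latency_ms,
                rotation_duration_ms=m.rotation_duration_ms,
                n_submovements=m.n_submovements,
                aborted=m.aborted,
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SummaryTable:
    """Per-edge-length aggregates of the pointer-alignment task.

    ``abs_error`` columns: edge_length, mean_of_medians, sem, n_participants
    (participant medians are computed first, then averaged -- the order
    matters and is enforced here).  ``proportion_correct`` columns:
    edge_length, proportion (mean of per-participant proportions), sem.
    ``threshold_mm`` is the edge length at which the mean proportion of
    correct-direction rotations crosses 75%, linearly interpolated over the
    finite lengths; None when never crossed, with ``threshold_censored``
    flagging an always-above-threshold dataset (left-censored at the
    shortest length).
    """

    abs_error: pd.DataFrame
    proportion_correct: pd.DataFrame
    threshold_mm: float | None
    threshold_censored: bool = False
    per_participant_medians: pd.DataFrame = field(default_factory=pd.DataFrame)


def _threshold_75(lengths: np.ndarray, props: np.ndarray) -> tuple[float | None, bool]:
    """Linear interpolation of the 75% crossing over finite edge lengths."""
    finite = np.isfinite(lengths)
    lengths, props = lengths[finite], props[finite]
    order = np.argsort(lengths)
    lengths, props = lengths[order], props[order]
    if len(lengths) == 0:
        return None, False
    if props[0] >= 0.75:
        return float(lengths[0]), True  # left-censored: already above threshold
    for i in range(1, len(lengths)):
        if props[i] >= 0.75 > props[i - 1]:
            frac = (0.75 - props[i - 1]) / (props[i] - props[i - 1])
            return float(lengths[i - 1] + frac * (lengths[i] - lengths[i - 1])), False
    return None, False


def summarize_dataset(
    measures: pd.DataFrame,
    log_transform: bool = False,
    arcsine_transform: bool = False,
) -> SummaryTable:
    """Aggregate per-trial measures into the task summary.

    Aborted and unanalyzable trials are excluded.  Optional transforms
    mirror the conventions for parametric statistics on these quantities
    (log for absolute errors, arcsine-square-root for proportions); the
    reported tables stay on the natural scale, the transforms apply to the
    across-participant averaging when requested.
    """
    df = measures[(measures.analyzable) & (~measures.aborted.astype(bool))]
    if df.empty:
        raise ValueError("no analyzable, non-aborted trials to summarize")

    med = (
        df.groupby(["participant", "edge_length"])["abs_error"]
        .median()
        .reset_index(name="median_abs_error")
    )

    def _agg_error(values: np.ndarray) -> tuple[float, float]:
        if log_transform:
            logs = np.log10(np.maximum(values, 1e-9))
            mean = 10 ** logs.mean()
            sem = (
                10 ** (logs.mean() + logs.std(ddof=1) / np.sqrt(len(logs))) - mean
                if len(logs) > 1
                else 0.0
            )
            return float(mean), float(sem)
        mean = float(values.mean())
        sem = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
        return mean, sem

    err_rows = []
    for length, grp in med.groupby("edge_length"):
        mean, sem = _agg_error(grp["median_abs_error"].to_numpy())
        err_rows.append(
            {
                "edge_length": length,
                "mean_of_medians": mean,
                "sem": sem,
                "n_participants": len(grp),
            }
        )
    abs_error = pd.DataFrame(err_rows).sort_values("edge_length", ignore_index=True)

    prop = (
        df.groupby(["participant", "edge_length"])["direction_correct"]
        .mean()
        .reset_index(name="p_correct")
    )
    prop_rows = []
    for length, grp in prop.groupby("edge_length"):
        vals = grp["p_correct"].to_numpy()
        if arcsine_transform:
            t = np.arcsin(np.sqrt(np.clip(vals, 0, 1)))
            mean = float(np.sin(t.mean()) ** 2)
            sem_t = t.std(ddof=1) / np.sqrt(len(t)) if len(t) > 1 else 0.0
            sem = float(np.sin(t.mean() + sem_t) ** 2 - mean)
        else:
            mean = float(vals.mean())
            sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        prop_rows.append({"edge_length": length, "proportion": mean, "sem": sem})
    proportion = pd.DataFrame(prop_rows).sort_values("edge_length", ignore_index=True)

    threshold, censored = _threshold_75(
        proportion["edge_length"].to_numpy(float),
        proportion["proportion"].to_numpy(float),
    )
    return SummaryTable(
        abs_error=abs_error,
        proportion_correct=proportion,
        threshold_mm=threshold,
        threshold_censored=censored,
        per_participant_medians=med,
    )
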