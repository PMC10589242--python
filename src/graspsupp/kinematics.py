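"""Kinematic event detection and trial measures from motion-capture marker streams.

A trial records five markers at 100 Hz (thumb nail, index nail, three object markers)
in lab coordinates: x lateral (+right), y anterior, z vertical (+up), in cm.  From a
trial we derive:

* hand and object speed — Euclidean speed of the marker centroids, obtained by central
  differencing and dual-pass (zero-phase) 2nd-order Butterworth low-pass filtering;
* object lift onset — first sample at which the object speed exceeds 10 cm/s;
* object contact — start of the final sub-threshold dwell of the hand speed before
  lift onset (the last downward crossing below 10 cm/s; if the hand never exceeded
  the threshold, the latest slow sample before lift);
* digit separation — mean vertical thumb-minus-index distance over the first 100 ms
  after contact (positive = thumb higher);
* loading time — contact-to-lift interval in ms;
* object roll — maximal absolute frontal-plane tilt of the object's long marker edge,
  relative to its own pre-lift orientation, within the first 250 ms of the lift.

Note on the filter cutoff: protocols built on MATLAB-style ``filtfilt`` pipelines
often quote a cutoff of "0.3", which in MATLAB ``butter`` is the normalized fraction
of Nyquist; an absolute 0.3 Hz at 100 Hz would smear events over seconds.  The
default therefore reads 0.3 as normalized (15 Hz effective); an absolute-Hz mode is
available via :class:`FilterSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .errors import InvalidMeasureError

__all__ = [
    "MarkerTimeSeries",
    "FilterSpec",
    "EventTime",
    "TrialEvents",
    "KinematicMeasures",
    "compute_speed",
    "detect_lift_onset",
    "detect_contact",
    "digit_separation",
    "loading_time",
    "object_roll",
    "analyze_trial",
]

HAND_MARKERS = ("thumb", "index")
OBJECT_MARKERS = ("obj1", "obj2", "obj3")

SPEED_THRESHOLD_CM_S = 10.0
SEPARATION_WINDOW_MS = 100.0
ROLL_WINDOW_MS = 250.0


@dataclass
class MarkerTimeSeries:
    """Uniformly sampled 3-D positions (cm) of a named marker set."""

    t: np.ndarray
    positions: dict[str, np.ndarray]  # marker -> (n, 3)
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.size
        if n < 2:
            raise ValueError("a marker series needs at least 2 samples")
        dt = np.diff(self.t)
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
            raise ValueError("sampling must be uniform")
        self.positions = {k: np.asarray(v, dtype=float) for k, v in self.positions.items()}
        for k, v in self.positions.items():
            if v.shape != (n, 3):
                raise ValueError(f"marker {k!r} has shape {v.shape}, expected ({n}, 3)")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    def index_of(self, time_s: float) -> int:
        """Nearest sample index for a time on this series' clock."""
        return int(round((time_s - self.t[0]) * self.fs))

    def interpolate_gaps(self, max_gap_ms: float = 100.0) -> "MarkerTimeSeries":
        """Linearly fill NaN runs up to ``max_gap_ms``; longer gaps raise."""
        max_gap = int(round(max_gap_ms / 1000.0 * self.fs))
        filled = {}
        for name, pos in self.positions.items():
            out = pos.copy()
            for axis in range(3):
                col = out[:, axis]
                bad = np.isnan(col)
                if not bad.any():
                    continue
                run = _longest_true_run(bad)
                if run > max_gap or bad[0] or bad[-1]:
                    raise ValueError(
                        f"marker {name!r}: NaN gap of {run} samples exceeds the "
                        f"{max_gap}-sample interpolation cap (or touches an endpoint)"
                    )
                idx = np.arange(col.size)
                out[:, axis] = np.interp(idx, idx[~bad], col[~bad])
            filled[name] = out
        return MarkerTimeSeries(t=self.t.copy(), positions=filled, fs=self.fs)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for name, pos in self.positions.items():
            df = pd.DataFrame(pos, columns=["x", "y", "z"])
            df.insert(0, "marker", name)
            df.insert(0, "time_s", self.t)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, fs: float | None = None) -> "MarkerTimeSeries":
        markers = {}
        t_ref = None
        for name, grp in df.groupby("marker", sort=False):
            grp = grp.sort_values("time_s")
            t = grp["time_s"].to_numpy(dtype=float)
            if t_ref is None:
                t_ref = t
            elif t.size != t_ref.size or not np.allclose(t, t_ref):
                raise ValueError("all markers must share one time base")
            markers[str(name)] = grp[["x", "y", "z"]].to_numpy(dtype=float)
        if t_ref is None:
            raise ValueError("empty series frame")
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t_ref)))
        return cls(t=t_ref, positions=markers, fs=fs)


def _longest_true_run(mask: np.ndarray) -> int:
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


@dataclass(frozen=True)
class FilterSpec:
    """Dual-pass (zero-phase) low-pass Butterworth filter settings.

    ``cutoff`` is a fraction of Nyquist when ``mode='fraction_nyquist'`` (the MATLAB
    ``butter`` convention) or an absolute frequency in Hz when ``mode='hz'``.
    """

    order: int = 2
    cutoff: float = 0.3
    mode: str = "fraction_nyquist"

    def normalized_cutoff(self, fs: float) -> float:
        wn = self.cutoff if self.mode == "fraction_nyquist" else self.cutoff / (fs / 2.0)
        if not 0 < wn < 1:
            raise ValueError(f"normalized cutoff {wn} outside (0, 1) at fs={fs}")
        return wn

    def apply(self, x: np.ndarray, fs: float) -> np.ndarray:
        b, a = butter(self.order, self.normalized_cutoff(fs), btype="low")
        return filtfilt(b, a, x)


@dataclass(frozen=True)
class EventTime:
    """One detected event; invalidity is encoded, not raised."""

    time_s: float
    index: int
    valid: bool
    reason: str = ""


@dataclass(frozen=True)
class TrialEvents:
    contact_time: float
    lift_time: float
    valid: bool
    reason: str = ""


@dataclass(frozen=True)
class KinematicMeasures:
    digit_separation: float  # cm, + = thumb above index
    loading_time: float  # ms
    max_roll: float  # deg, >= 0
    contact_time: float
    lift_time: float
    valid: bool = True
    reason: str = ""


def compute_speed(
    series: MarkerTimeSeries,
    markers: tuple[str, ...],
    filt: FilterSpec = FilterSpec(),
) -> np.ndarray:
    """Filtered Euclidean speed (cm/s) of the centroid of the requested markers.

    Central differences in the interior, one-sided at the endpoints; the resulting
    speed vector is then dual-pass filtered (zero phase, unit DC gain).
    """
    missing = [m for m in markers if m not in series.positions]
    if missing:
        raise ValueError(f"markers not present in series: {missing}")
    if series.n_samples < 3:
        raise ValueError("need at least 3 samples to differentiate")
    centroid = np.mean([series.positions[m] for m in markers], axis=0)
    vel = np.gradient(centroid, series.dt, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    return filt.apply(speed, series.fs)


def detect_lift_onset(
    object_speed: np.ndarray,
    t: np.ndarray,
    threshold: float = SPEED_THRESHOLD_CM_S,
) -> EventTime:
    """First sample at which the object speed strictly exceeds ``threshold``."""
    above = np.flatnonzero(np.asarray(object_speed) > threshold)
    if above.size == 0:
        return EventTime(math.nan, -1, False, "no lift: object speed never exceeded threshold")
    k = int(above[0])
    return EventTime(float(t[k]), k, True)


def detect_contact(
    hand_speed: np.ndarray,
    t: np.ndarray,
    lift: EventTime,
    threshold: float = SPEED_THRESHOLD_CM_S,
) -> EventTime:
    """Moment of object contact from the hand-speed trace.

    Contact is the start of the final continuous sub-threshold dwell of the hand
    before lift onset, i.e. the last sample before lift at which the hand speed
    crossed below ``threshold`` (its predecessor was at or above it).  When the hand
    speed never reached the threshold before lift, the latest sub-threshold sample is
    returned instead.  Samples exactly at the threshold count as not-slow (the rule is
    strictly-below).
    """
    if not lift.valid:
        return EventTime(math.nan, -1, False, "no contact: lift onset invalid")
    hs = np.asarray(hand_speed, dtype=float)
    if lift.index <= 0 or lift.index > hs.size:
        return EventTime(math.nan, -1, False, "no contact: no samples before lift onset")
    pre = hs[: lift.index]
    slow = pre < threshold
    if not slow.any():
        return EventTime(math.nan, -1, False, "no contact: hand speed never below threshold")
    crossings = np.flatnonzero(slow[1:] & ~slow[:-1]) + 1
    k = int(crossings[-1]) if crossings.size else int(np.flatnonzero(slow)[-1])
    return EventTime(float(t[k]), k, True)


def digit_separation(
    series: MarkerTimeSeries,
    contact: EventTime,
    window_ms: float = SEPARATION_WINDOW_MS,
    thumb: str = "thumb",
    index_marker: str = "index",
) -> float:
    """Mean vertical thumb-minus-index distance (cm) over ``window_ms`` after contact.

    ``window_ms = 0`` returns the instantaneous separation at the contact sample.
    """
    if not contact.valid:
        raise InvalidMeasureError("digit separation undefined: contact invalid")
    dz = series.positions[thumb][:, 2] - series.positions[index_marker][:, 2]
    if window_ms == 0:
        return float(dz[contact.index])
    n_win = int(round(window_ms / 1000.0 * series.fs))
    stop = min(contact.index + n_win, series.n_samples)
    if stop - contact.index < 2:
        raise InvalidMeasureError("digit separation undefined: window truncated below 2 samples")
    return float(np.mean(dz[contact.index : stop]))


def loading_time(events: TrialEvents) -> float:
    """Contact-to-lift interval in ms."""
    if not events.valid:
        raise InvalidMeasureError(f"loading time undefined: {events.reason}")
    lt = (events.lift_time - events.contact_time) * 1000.0
    if lt < 0:
        raise InvalidMeasureError("loading time undefined: contact after lift")
    return float(lt)


def object_roll(
    series: MarkerTimeSeries,
    lift: EventTime,
    window_ms: float = ROLL_WINDOW_MS,
    edge: tuple[str, str] = ("obj1", "obj3"),
) -> float:
    """Maximal absolute frontal-plane tilt (deg) within ``window_ms`` after lift onset.

    Per-sample tilt is the signed angle, in the lateral–vertical (x–z) plane, of the
    object-marker long edge relative to its mean pre-lift orientation.
    """
    if not lift.valid:
        raise InvalidMeasureError("object roll undefined: lift invalid")
    a, b = (series.positions[m] for m in edge)
    dx = b[:, 0] - a[:, 0]
    dz = b[:, 2] - a[:, 2]
    if np.min(np.hypot(dx, dz)) < 1.0:
        raise ValueError("degenerate object-marker geometry: frontal edge shorter than 1 cm")
    angle = np.unwrap(np.arctan2(dz, dx))
    if lift.index < 1:
        raise InvalidMeasureError("object roll undefined: no pre-lift samples for reference")
    ref = float(np.mean(angle[: lift.index]))
    n_win = int(round(window_ms / 1000.0 * series.fs))
    stop = min(lift.index + n_win + 1, series.n_samples)
    tilt = angle[lift.index : stop] - ref
    return float(np.degrees(np.max(np.abs(tilt))))


def analyze_trial(
    series: MarkerTimeSeries,
    filt: FilterSpec = FilterSpec(),
    speed_threshold: float = SPEED_THRESHOLD_CM_S,
    separation_window_ms: float = SEPARATION_WINDOW_MS,
    roll_window_ms: float = ROLL_WINDOW_MS,
    hand_markers: tuple[str, ...] = HAND_MARKERS,
    object_markers: tuple[str, ...] = OBJECT_MARKERS,
) -> KinematicMeasures:
    """Full per-trial extraction; failures are encoded in ``valid``/``reason``."""
    hand_speed = compute_speed(series, hand_markers, filt)
    obj_speed = compute_speed(series, object_markers, filt)
    lift = detect_lift_onset(obj_speed, series.t, speed_threshold)
    contact = detect_contact(hand_speed, series.t, lift, speed_threshold)
    if not (lift.valid and contact.valid):
        reason = lift.reason if not lift.valid else contact.reason
        return KinematicMeasures(math.nan, math.nan, math.nan, math.nan, math.nan, False, reason)
    events = TrialEvents(contact.time_s, lift.time_s, True)
    try:
        sep = digit_separation(series, contact, separation_window_ms)
        lt = loading_time(events)
        roll = object_roll(series, lift, roll_window_ms)
    except InvalidMeasureError as exc:
        return KinematicMeasures(
            math.nan, math.nan, math.nan, contact.time_s, lift.time_s, False, str(exc)
        )
    return KinematicMeasures(sep, lt, roll, contact.time_s, lift.time_s, True)
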