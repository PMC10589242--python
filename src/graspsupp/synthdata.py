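"""Synthetic marker streams and detection responses with the structure the analysis assumes.

The generator emulates one reach-grasp-lift trial of the study: a minimum-jerk
transport of the digit pair over ~34 cm toward the object, a loading dwell during
which the hand speed stays below the 10 cm/s event threshold, and a ~10 cm object
lift.  The grasp policy sets the vertical thumb–index separation from the *previous*
trial's mass distribution (the sensorimotor-memory rule under study), and the object
rolls during the lift in proportion to the mismatch between the anticipated and the
actual lateral mass position.  Yes/no detection responses are drawn from a logistic
observer whose threshold shifts during movement (tactile suppression).

Ground-truth event times are stored as the analytic threshold crossings of the
noise-free speed profiles, which is exactly what the downstream event detector
estimates; the dwell parameter is therefore the sub-threshold hand-speed interval.

Coordinate convention: x lateral (+right), y anterior, z vertical (+up), units cm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .design import SequenceDesign, TrialSpec
from .kinematics import MarkerTimeSeries

__all__ = [
    "GraspPolicy",
    "ObjectModel",
    "ObserverModel",
    "SyntheticTrial",
    "ExperimentDataset",
    "simulate_trajectory",
    "simulate_response",
    "simulate_experiment",
    "read_dataset",
    "minimum_jerk_position",
    "minimum_jerk_speed",
]

FS_HZ = 100.0
REACH_CM = 34.0
REACH_S = 0.8
LIFT_CM = 10.0
LIFT_S = 0.4
POST_S = 0.3
SPEED_THRESHOLD = 10.0

#: lateral object-position centers (cm); both are 34 cm from the start position
POSITION_X = {"left": -8.0, "right": 8.0}
GRASP_HEIGHT_CM = 8.0  # object grasp area above the table


@dataclass
class GraspPolicy:
    """How digit placement and loading depend on the previous trial's mass distribution.

    ``separation_amplitude`` is the magnitude s (cm) of the vertical thumb–index
    offset adopted at contact: +s (thumb higher) when the policy anticipates a left
    mass, −s for a right mass.  ``rule`` selects what is anticipated: the previous
    mass side (``predictive``), its opposite (``anti_predictive``), or a coin flip
    (``random``).  ``loading_time_ms`` maps the trial condition (MD_same /
    MD_different) to the dwell duration.
    """

    separation_amplitude: float = 0.8
    rule: str = "predictive"
    kinematic_noise_sd: float = 0.0
    loading_time_ms: dict = field(
        default_factory=lambda: {"MD_same": 300.0, "MD_different": 250.0}
    )
    loading_jitter_sd_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.separation_amplitude < 0:
            raise ValueError("separation_amplitude must be >= 0")
        if self.kinematic_noise_sd < 0 or self.loading_jitter_sd_ms < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.rule not in ("predictive", "anti_predictive", "random"):
            raise ValueError(f"unknown rule {self.rule!r}")

    def anticipated_md(self, prev_md: str, rng: np.random.Generator) -> str:
        if self.rule == "predictive":
            return prev_md
        if self.rule == "anti_predictive":
            return "R" if prev_md == "L" else "L"
        return "L" if rng.integers(2) == 0 else "R"

    def dwell_s(self, condition: str) -> float:
        try:
            return float(self.loading_time_ms[condition]) / 1000.0
        except KeyError:
            raise KeyError(f"no loading time configured for condition {condition!r}")


@dataclass
class ObjectModel:
    """Inverted-T object: 15 x 3 cm base, 5 x 7 cm upper part, 5 cm deep, 273 g total
    with a 116 g brass mass hidden in a left/central/right tube."""

    base_width: float = 15.0
    base_height: float = 3.0
    upper_width: float = 5.0
    upper_height: float = 7.0
    depth: float = 5.0
    total_mass_g: float = 273.0
    brass_mass_g: float = 116.0
    tube_offsets: dict = field(default_factory=lambda: {"L": -4.5, "C": 0.0, "R": 4.5})
    roll_gain: float = 1.0  # deg of roll per cm of anticipated-vs-actual mass offset
    roll_rise_ms: float = 200.0
    roll_noise_sd_deg: float = 0.0  # trial-to-trial variability of the realized roll

    def __post_init__(self) -> None:
        if self.total_mass_g <= 0 or self.brass_mass_g <= 0:
            raise ValueError("masses must be positive")
        for md, off in self.tube_offsets.items():
            if abs(off) > self.base_width / 2:
                raise ValueError(f"tube offset for {md!r} outside the object base")

    def roll_magnitude(self, anticipated_md: str, actual_md: str) -> float:
        """Max roll (deg): proportional to the lateral mass-offset mismatch, 0 on match."""
        mismatch = abs(self.tube_offsets[anticipated_md] - self.tube_offsets[actual_md])
        return self.roll_gain * mismatch


@dataclass
class ObserverModel:
    """Logistic yes/no detection observer with guess and lapse rates.

    P(yes | x, cond) = gamma + (1 - gamma - lambda) * F((x - m_cond) / s) with
    m_cond = baseline_threshold + threshold_shift[cond] and width w defined as the
    95%–5% span of the logistic core, s = w / (2 ln 19).
    """

    guess_rate: float = 0.10
    lapse_rate: float = 0.02
    baseline_threshold_um: float = 18.0
    width_um: float = 20.0
    threshold_shift_um: dict = field(
        default_factory=lambda: {
            "baseline": 0.0,
            "MD_same": 10.0,
            "MD_different": 10.0,
            "constant": 10.0,
            "mixed": 10.0,
            "practice": 10.0,
        }
    )

    def __post_init__(self) -> None:
        if not 0 <= self.guess_rate < 1:
            raise ValueError("guess rate must be in [0, 1)")
        if not 0 <= self.lapse_rate <= 0.5:
            raise ValueError("lapse rate must be in [0, 0.5]")
        if self.guess_rate + self.lapse_rate >= 1:
            raise ValueError("guess + lapse must be < 1")
        if self.width_um <= 0 or self.baseline_threshold_um <= 0:
            raise ValueError("threshold and width must be positive")

    def location(self, condition: str) -> float:
        return self.baseline_threshold_um + float(self.threshold_shift_um.get(condition, 0.0))

    def p_yes(self, intensity_um: float, condition: str) -> float:
        s = self.width_um / (2.0 * math.log(19.0))
        core = 1.0 / (1.0 + math.exp(-(intensity_um - self.location(condition)) / s))
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * core


@dataclass
class SyntheticTrial:
    spec: TrialSpec
    series: MarkerTimeSeries
    true_contact_time: float
    true_lift_time: float
    true_roll_max: float
    true_separation: float
    prev_md: str
    condition: str
    response: bool | None = None


def minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_speed(tau: np.ndarray) -> np.ndarray:
    """d/d(tau) of the normalized profile; multiply by D/T for physical speed."""
    tau = np.clip(tau, 0.0, 1.0)
    return 30 * tau**2 - 60 * tau**3 + 30 * tau**4


def _descending_crossing_tau(v_norm: float) -> float:
    """tau in (0.5, 1) where the min-jerk speed falls back to ``v_norm`` (normalized)."""
    return brentq(lambda u: minimum_jerk_speed(np.array(u)) - v_norm, 0.5, 1.0 - 1e-12)


def _ascending_crossing_tau(v_norm: float) -> float:
    """tau in (0, 0.5) where the min-jerk speed first reaches ``v_norm`` (normalized)."""
    return brentq(lambda u: minimum_jerk_speed(np.array(u)) - v_norm, 1e-12, 0.5)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def simulate_trajectory(
    spec: TrialSpec,
    prev_md: str,
    policy: GraspPolicy,
    obj: ObjectModel | None = None,
    fs: float = FS_HZ,
    seed: int | np.random.Generator = 0,
    reach_cm: float = REACH_CM,
    reach_s: float = REACH_S,
    lift_cm: float = LIFT_CM,
    lift_s: float = LIFT_S,
    post_s: float = POST_S,
    speed_threshold: float = SPEED_THRESHOLD,
) -> SyntheticTrial:
    """Simulate the 5-marker stream of one grasping trial.

    The digit-pair centroid travels along a minimum-jerk path to the grasp point,
    dwells with zero speed for the policy's condition-specific loading time (measured
    between the analytic threshold crossings of hand and object speed), then rises
    with the object by ``lift_cm``.  Object markers stay static until the lift and
    roll toward ``roll_gain x mismatch`` degrees within ``roll_rise_ms``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if spec.block != "grasping":
        raise ValueError("trajectories are only simulated for grasping trials")
    if prev_md not in ("L", "R"):
        raise ValueError("prev_md must be 'L' or 'R'")
    obj = obj or ObjectModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    condition = "MD_same" if prev_md == spec.mass_distribution else "MD_different"
    dwell = policy.dwell_s(condition)
    if dwell < 2.0 / fs:
        raise ValueError(f"dwell of {dwell * 1e3:.1f} ms is shorter than 2 samples at {fs} Hz")

    # Analytic threshold crossings of the noise-free speed profiles.
    tail_tau = _descending_crossing_tau(speed_threshold * reach_s / reach_cm)
    t_contact = tail_tau * reach_s
    rise_tau = _ascending_crossing_tau(speed_threshold * lift_s / lift_cm)
    lift_delay = rise_tau * lift_s
    min_dwell = (reach_s - t_contact) + lift_delay + 2.0 / fs
    if dwell < min_dwell - 1e-12:
        raise ValueError(
            f"loading time {dwell * 1e3:.0f} ms too short: the lift would have to start "
            f"before the transport ends ({min_dwell * 1e3:.0f} ms minimum)"
        )
    if policy.loading_jitter_sd_ms:
        dwell = max(min_dwell, dwell + rng.normal(0.0, policy.loading_jitter_sd_ms / 1000.0))
    t_lift = t_contact + dwell
    t_lift_start = t_lift - lift_delay

    duration = t_lift_start + lift_s + post_s
    n = int(math.ceil(duration * fs)) + 1
    t = np.arange(n) / fs

    # Digit-pair centroid: transport then lift.
    x_obj = POSITION_X[spec.object_position or "left"]
    y_obj = math.sqrt(reach_cm**2 - x_obj**2)
    start = np.zeros(3)
    grasp = np.array([x_obj, y_obj, GRASP_HEIGHT_CM])
    prog = minimum_jerk_position(t / reach_s)
    centroid = start[None, :] + (grasp - start)[None, :] * prog[:, None]
    lift_prog = minimum_jerk_position((t - t_lift_start) / lift_s)
    centroid[:, 2] += lift_cm * lift_prog

    anticipated = policy.anticipated_md(prev_md, rng)
    separation = policy.separation_amplitude * (1.0 if anticipated == "L" else -1.0)
    separation += rng.normal(0.0, policy.kinematic_noise_sd) if policy.kinematic_noise_sd else 0.0

    half_grip = obj.upper_width / 2.0
    thumb = centroid + np.array([-half_grip, 0.0, separation / 2.0])
    index = centroid + np.array([half_grip, 0.0, -separation / 2.0])

    # Object markers: long edge along x, rigid rise plus a frontal-plane roll ramp.
    roll_max_deg = obj.roll_magnitude(anticipated, spec.mass_distribution)
    if obj.roll_noise_sd_deg:
        roll_max_deg = abs(roll_max_deg + rng.normal(0.0, obj.roll_noise_sd_deg))
    theta = np.radians(roll_max_deg) * _smoothstep((t - t_lift_start) / (obj.roll_rise_ms / 1000.0))
    center = np.tile(np.array([x_obj, y_obj, GRASP_HEIGHT_CM]), (n, 1))
    center[:, 2] += lift_cm * lift_prog
    offsets = [np.array([-obj.base_width / 3.0, 0.0, 0.0]), np.zeros(3), np.array([obj.base_width / 3.0, 0.0, 0.0])]
    obj_markers = {}
    for name, off in zip(("obj1", "obj2", "obj3"), offsets):
        ox = off[0] * np.cos(theta) - off[2] * np.sin(theta)
        oz = off[0] * np.sin(theta) + off[2] * np.cos(theta)
        obj_markers[name] = center + np.stack([ox, np.full(n, off[1]), oz], axis=1)

    series = MarkerTimeSeries(
        t=t,
        positions={"thumb": thumb, "index": index, **obj_markers},
        fs=fs,
    )
    return SyntheticTrial(
        spec=spec,
        series=series,
        true_contact_time=t_contact,
        true_lift_time=t_lift,
        true_roll_max=roll_max_deg,
        true_separation=separation,
        prev_md=prev_md,
        condition=condition,
    )


def simulate_response(
    observer: ObserverModel,
    intensity_um: float,
    condition: str,
    seed: int | np.random.Generator = 0,
) -> bool:
    """One Bernoulli yes/no draw from the observer's psychometric function."""
    if intensity_um < 0:
        raise ValueError("intensity must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return bool(rng.random() < observer.p_yes(intensity_um, condition))


@dataclass
class ExperimentDataset:
    """One simulated participant-session: trial table plus per-trial marker series."""

    trial_table: pd.DataFrame
    series: dict  # trial_id -> MarkerTimeSeries
    seed: int = 0
    experiment: str = "exp1"

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "series").mkdir(exist_ok=True)
        self.trial_table.to_csv(out / "trials.tsv", sep="\t", index=False)
        files = {}
        for trial_id, s in sorted(self.series.items()):
            name = f"series/trial_{trial_id:04d}.csv"
            s.to_long_frame().to_csv(out / name, index=False)
            files[str(trial_id)] = name
        manifest = {
            "experiment": self.experiment,
            "seed": self.seed,
            "trial_table": "trials.tsv",
            "series_files": files,
            "coordinates": "x lateral (+right), y anterior, z vertical (+up), cm",
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def read_dataset(in_dir) -> ExperimentDataset:
    """Read the on-disk layout written by :meth:`ExperimentDataset.write`."""
    root = Path(in_dir)
    try:
        with open(root / "manifest.json") as fh:
            manifest = json.load(fh)
        table = pd.read_csv(root / manifest["trial_table"], sep="\t")
        series = {
            int(tid): MarkerTimeSeries.from_long_frame(pd.read_csv(root / rel))
            for tid, rel in manifest["series_files"].items()
        }
    except OSError as exc:
        raise OSError(f"cannot read dataset under {root}: {exc}") from exc
    return ExperimentDataset(
        trial_table=table,
        series=series,
        seed=int(manifest.get("seed", 0)),
        experiment=str(manifest.get("experiment", "exp1")),
    )


def simulate_experiment(
    design: SequenceDesign,
    policy: GraspPolicy | None = None,
    observer: ObserverModel | None = None,
    obj: ObjectModel | None = None,
    seed: int = 0,
    fs: float = FS_HZ,
) -> ExperimentDataset:
    """Simulate every trial of a sequence design.

    Grasping trials get a full marker series and a detection response (probe delivered
    at object contact); baseline and practice trials get a response only (practice is
    not analyzed downstream).  All randomness flows from ``seed`` through a single
    generator.
    """
    policy = policy or GraspPolicy()
    observer = observer or ObserverModel()
    obj = obj or ObjectModel()
    rng = np.random.default_rng(seed)

    rows = []
    series: dict[int, MarkerTimeSeries] = {}
    prev_md = "L" if rng.integers(2) == 0 else "R"
    for spec in design.trials:
        rec = {
            "trial_id": spec.trial_id,
            "block": spec.block,
            "md": spec.mass_distribution,
            "position": spec.object_position,
            "intensity_um": spec.intensity_um,
            "part": spec.part,
            "session": spec.session,
            "lead_in": spec.lead_in,
            "prev_md": None,
            "condition": None,
            "response": None,
            "true_contact_s": np.nan,
            "true_lift_s": np.nan,
            "true_roll_deg": np.nan,
            "true_separation_cm": np.nan,
        }
        if spec.block.startswith("baseline"):
            rec["condition"] = "baseline"
            rec["response"] = simulate_response(observer, spec.intensity_um, "baseline", rng)
        elif spec.block == "practice":
            rec["condition"] = "practice"
            rec["response"] = simulate_response(observer, spec.intensity_um, "practice", rng)
        else:
            trial = simulate_trajectory(spec, prev_md, policy, obj, fs=fs, seed=rng)
            if design.experiment == "exp2":
                condition = spec.part  # suppression compared between mixed and constant parts
            else:
                condition = trial.condition
            trial.response = simulate_response(observer, spec.intensity_um, condition, rng)
            series[spec.trial_id] = trial.series
            rec.update(
                prev_md=trial.prev_md,
                condition=condition,
                response=trial.response,
                true_contact_s=trial.true_contact_time,
                true_lift_s=trial.true_lift_time,
                true_roll_deg=trial.true_roll_max,
                true_separation_cm=trial.true_separation,
            )
            prev_md = spec.mass_distribution
        rows.append(rec)
    table = pd.DataFrame(rows)
    return ExperimentDataset(
        trial_table=table, series=series, seed=seed, experiment=design.experiment
    )
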