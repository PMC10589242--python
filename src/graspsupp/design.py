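"""Trial-sequence construction for the two grasping/tactile-suppression experiments.

The experiments present reach-to-grasp trials in which a hidden brass mass sits in the
left (L) or right (R) side of an inverted-T object, plus rest ("baseline") blocks in
which vibrotactile probes are judged without movement.  This module builds the stimulus
grids and pseudorandom trial sequences deterministically from an integer seed while
enforcing the designs' counting constraints:

* Experiment 1 — one mixed grasping block of 180 analyzed trials in which each ordered
  pair of consecutive mass distributions (LL, RL, LR, RR) occurs exactly 45 times,
  30 of them with a vibrotactile probe and 15 catch trials, with 90 trials at each
  object position.  A flagged lead-in trial makes all 180 trials classifiable by their
  predecessor.
* Experiment 2 — 216 trials alternating six 9-trial "mixed" parts with six 27-trial
  "constant" parts (three with a left mass, three with a right mass), always starting
  with a mixed part.
* Baseline blocks of 45 trials: five repetitions of each of six probe intensities plus
  15 catch trials.

"Pseudorandom with no apparent regularity" is operationalized as rejection sampling
with a cap on runs of identical probe intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError

__all__ = [
    "IntensityGrid",
    "TrialSpec",
    "SequenceDesign",
    "build_intensity_grid",
    "build_baseline_block",
    "build_practice_block",
    "build_exp1_sequence",
    "build_exp2_sequence",
    "DEFAULT_GRID",
]

BLOCKS = ("baseline_pre", "practice", "grasping", "baseline_post")
MASS_DISTRIBUTIONS = ("L", "C", "R")
POSITIONS = ("left", "right")
PARTS = ("mixed", "constant", "none")
SESSIONS = ("implicit", "explicit", "none")

#: Default cap on runs of identical probe intensities (catch counts as an intensity).
DEFAULT_MAX_INTENSITY_RUN = 3

_MAX_TRIES = 10_000


@dataclass(frozen=True)
class IntensityGrid:
    """Ordered vibrotactile probe intensities (peak-to-peak displacement, µm)."""

    levels: tuple[float, ...]
    catch_level: float = 0.0

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise ValueError("grid needs at least one level")
        arr = np.asarray(self.levels, dtype=float)
        if np.any(arr <= 0):
            raise ValueError("all grid levels must be strictly positive")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("grid levels must be strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def step(self) -> float:
        return float(self.levels[1] - self.levels[0]) if self.n_levels > 1 else 0.0


@dataclass(frozen=True)
class TrialSpec:
    """Design metadata for a single trial."""

    trial_id: int
    block: str
    mass_distribution: str | None = None
    object_position: str | None = None
    intensity_um: float = 0.0
    part: str = "none"
    session: str = "none"
    lead_in: bool = False

    def __post_init__(self) -> None:
        if self.trial_id < 1:
            raise ValueError("trial_id must be >= 1")
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}")
        if self.mass_distribution is not None and self.mass_distribution not in MASS_DISTRIBUTIONS:
            raise ValueError(f"unknown mass distribution {self.mass_distribution!r}")
        if self.mass_distribution == "C" and self.block != "practice":
            raise ValueError("central mass distribution is only used in the practice block")
        if self.block.startswith("baseline") and (
            self.mass_distribution is not None or self.object_position is not None
        ):
            raise ValueError("baseline trials carry no mass distribution or object position")
        if self.intensity_um < 0:
            raise ValueError("intensity must be >= 0 (0 = catch)")
        if self.part not in PARTS:
            raise ValueError(f"unknown part {self.part!r}")
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session {self.session!r}")

    @property
    def is_catch(self) -> bool:
        return self.intensity_um == 0.0


@dataclass
class SequenceDesign:
    """An ordered trial sequence plus the seed that generated it."""

    trials: list[TrialSpec]
    experiment: str = "exp1"
    seed: int = 0

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            d = asdict(t)
            d["md"] = d.pop("mass_distribution")
            d["position"] = d.pop("object_position")
            rows.append(d)
        df = pd.DataFrame(rows)
        return df[["trial_id", "block", "md", "position", "intensity_um", "part", "session", "lead_in"]]

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "experiment": self.experiment,
            "seed": self.seed,
            "trials": self.to_frame().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=_json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_frame(cls, df: pd.DataFrame, experiment: str = "exp1", seed: int = 0) -> "SequenceDesign":
        trials = []
        for row in df.itertuples(index=False):
            trials.append(
                TrialSpec(
                    trial_id=int(row.trial_id),
                    block=str(row.block),
                    mass_distribution=None if pd.isna(row.md) else str(row.md),
                    object_position=None if pd.isna(row.position) else str(row.position),
                    intensity_um=float(row.intensity_um),
                    part=str(row.part),
                    session=str(row.session),
                    lead_in=bool(row.lead_in),
                )
            )
        return cls(trials=trials, experiment=experiment, seed=seed)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def build_intensity_grid(min_um: float = 9.4, max_um: float = 56.7, n_levels: int = 6) -> IntensityGrid:
    """Equally spaced probe-intensity grid from ``min_um`` to ``max_um`` inclusive.

    The default reproduces the study grid of six peak-to-peak displacements spanning
    9.4–56.7 µm.  The endpoints define the grid; the step follows from them.
    """
    if min_um <= 0:
        raise ValueError("min_um must be > 0")
    if max_um <= min_um:
        raise ValueError("max_um must exceed min_um")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    levels = tuple(float(x) for x in np.linspace(min_um, max_um, n_levels))
    return IntensityGrid(levels=levels)


DEFAULT_GRID = build_intensity_grid()


def _max_run(values: Sequence) -> int:
    best = run = 1
    for a, b in zip(values, values[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if len(values) else 0


def _permute_with_run_cap(values: Iterable, rng: np.random.Generator, max_run: int) -> list:
    """Random permutation with no more than ``max_run`` equal consecutive values."""
    arr = list(values)
    for _ in range(_MAX_TRIES):
        perm = [arr[i] for i in rng.permutation(len(arr))]
        if _max_run(perm) <= max_run:
            return perm
    raise GenerationError(
        f"could not permute {len(arr)} values with run cap {max_run} in {_MAX_TRIES} tries"
    )


def build_baseline_block(
    grid: IntensityGrid = DEFAULT_GRID,
    reps_per_level: int = 5,
    n_catch: int = 15,
    seed: int = 0,
    block: str = "baseline_pre",
    session: str = "none",
    max_intensity_run: int = DEFAULT_MAX_INTENSITY_RUN,
    start_id: int = 1,
) -> SequenceDesign:
    """One rest block: each intensity ``reps_per_level`` times plus ``n_catch`` catch trials."""
    if reps_per_level < 1:
        raise ValueError("reps_per_level must be >= 1")
    if n_catch < 0:
        raise ValueError("n_catch must be >= 0")
    if block not in ("baseline_pre", "baseline_post"):
        raise ValueError("block must be a baseline block")
    rng = np.random.default_rng(seed)
    intensities = list(grid.levels) * reps_per_level + [grid.catch_level] * n_catch
    order = _permute_with_run_cap(intensities, rng, max_intensity_run)
    trials = [
        TrialSpec(trial_id=start_id + i, block=block, intensity_um=x, session=session)
        for i, x in enumerate(order)
    ]
    return SequenceDesign(trials=trials, experiment="exp1", seed=seed)


def build_practice_block(
    grid: IntensityGrid = DEFAULT_GRID,
    seed: int = 0,
    session: str = "none",
    max_intensity_run: int = DEFAULT_MAX_INTENSITY_RUN,
    start_id: int = 1,
) -> SequenceDesign:
    """Nine practice trials with the central mass: each intensity once plus three catch.

    The object sits five times on one position and four on the other; which position
    gets five is decided by the seed (counterbalance across participants).
    """
    rng = np.random.default_rng(seed)
    intensities = list(grid.levels) + [grid.catch_level] * 3
    order = _permute_with_run_cap(intensities, rng, max_intensity_run)
    majority = "left" if rng.integers(2) == 0 else "right"
    minority = "right" if majority == "left" else "left"
    positions = _permute_with_run_cap([majority] * 5 + [minority] * 4, rng, max_run=9)
    trials = [
        TrialSpec(
            trial_id=start_id + i,
            block="practice",
            mass_distribution="C",
            object_position=pos,
            intensity_um=x,
            session=session,
        )
        for i, (x, pos) in enumerate(zip(order, positions))
    ]
    return SequenceDesign(trials=trials, experiment="exp1", seed=seed)


def _md_sequence_balanced_pairs(rng: np.random.Generator, md_run_cap: int = 5) -> list[str]:
    """181-long L/R sequence whose 180 consecutive pairs split 45/45/45/45 over LL, RL, LR, RR.

    Constructed from alternating runs: with the first and last run of the same letter
    there are 46 runs of that letter (91 letters) and 45 of the other (90 letters),
    giving exactly 45 within-letter repeats each and 45 transitions each way.  Run
    lengths are randomized by a multinomial split of the surplus letters, rejected
    until no run exceeds ``md_run_cap``.
    """
    first = "L" if rng.integers(2) == 0 else "R"
    other = "R" if first == "L" else "L"
    for _ in range(_MAX_TRIES):
        extra_first = rng.multinomial(45, np.full(46, 1 / 46))
        extra_other = rng.multinomial(45, np.full(45, 1 / 45))
        if extra_first.max() + 1 > md_run_cap or extra_other.max() + 1 > md_run_cap:
            continue
        seq: list[str] = []
        for i in range(46):
            seq.extend([first] * (1 + int(extra_first[i])))
            if i < 45:
                seq.extend([other] * (1 + int(extra_other[i])))
        return seq
    raise GenerationError("could not build a pair-balanced mass-distribution sequence")


def _pair_combinations(mds: Sequence[str]) -> list[str]:
    return [a + b for a, b in zip(mds, mds[1:])]


def build_exp1_sequence(
    seed: int = 0,
    lead_in: bool = True,
    grid: IntensityGrid = DEFAULT_GRID,
    session: str = "none",
    max_intensity_run: int = DEFAULT_MAX_INTENSITY_RUN,
    start_id: int = 1,
) -> SequenceDesign:
    """Experiment 1 mixed grasping block.

    180 analyzed trials; each consecutive-mass combination (LL, RL, LR, RR) occurs 45
    times — 30 with a probe (five per intensity level) and 15 catch — and each object
    position 90 times.  With ``lead_in=True`` a flagged extra first trial is prepended
    so that every analyzed trial has a classifiable predecessor.
    """
    rng = np.random.default_rng(seed)
    mds = _md_sequence_balanced_pairs(rng)
    combos = _pair_combinations(mds)  # combos[i] classifies trial i+1 (0-based)

    # Probe intensities per combination class: 5 x each level + 15 catch, identical to
    # one baseline block; rejection-sampled so no intensity repeats more than the cap.
    per_class = list(grid.levels) * 5 + [grid.catch_level] * 15
    class_positions = {c: [i + 1 for i, cc in enumerate(combos) if cc == c] for c in ("LL", "RL", "LR", "RR")}
    intensities = np.empty(len(mds), dtype=float)
    for _ in range(_MAX_TRIES):
        intensities[0] = rng.choice(list(grid.levels) + [grid.catch_level])  # lead-in probe
        for c, idx in class_positions.items():
            assignment = [per_class[j] for j in rng.permutation(len(per_class))]
            intensities[idx] = assignment
        if _max_run(list(intensities)) <= max_intensity_run:
            break
    else:
        raise GenerationError("could not satisfy the intensity run cap for the Exp1 sequence")

    positions = _permute_with_run_cap(["left"] * 90 + ["right"] * 90, rng, max_run=180)
    positions.insert(0, "left" if rng.integers(2) == 0 else "right")

    trials = []
    for i, md in enumerate(mds):
        trials.append(
            TrialSpec(
                trial_id=start_id + i,
                block="grasping",
                mass_distribution=md,
                object_position=positions[i],
                intensity_um=float(intensities[i]),
                part="mixed",
                session=session,
                lead_in=(i == 0),
            )
        )
    if not lead_in:
        trials = trials[1:]
    return SequenceDesign(trials=trials, experiment="exp1", seed=seed)


def build_exp2_sequence(
    seed: int = 0,
    first_constant_md: str = "L",
    grid: IntensityGrid = DEFAULT_GRID,
    session: str = "none",
    max_intensity_run: int = DEFAULT_MAX_INTENSITY_RUN,
    start_id: int = 1,
) -> SequenceDesign:
    """Experiment 2 grasping block: 216 trials alternating mixed(9) and constant(27) parts.

    Starts with a mixed part; six constant parts alternate mass distribution starting
    with ``first_constant_md`` (counterbalanced across participants), giving three left
    and three right constant parts.  Object position still varies within constant parts.
    """
    if first_constant_md not in ("L", "R"):
        raise ValueError("first_constant_md must be 'L' or 'R'")
    rng = np.random.default_rng(seed)
    other = "R" if first_constant_md == "L" else "L"
    constant_mds = [first_constant_md, other] * 3

    part_plan: list[tuple[str, int, str | None]] = []
    for k in range(6):
        part_plan.append(("mixed", 9, None))
        part_plan.append(("constant", 27, constant_mds[k]))

    mds: list[str] = []
    parts: list[str] = []
    intensities: list[float] = []
    for part, length, md in part_plan:
        if part == "mixed":
            n_l = 5 if rng.integers(2) == 0 else 4
            part_mds = _permute_with_run_cap(["L"] * n_l + ["R"] * (9 - n_l), rng, max_run=4)
            part_int = _permute_with_run_cap(
                list(grid.levels) + [grid.catch_level] * 3, rng, max_intensity_run
            )
        else:
            part_mds = [md] * length
            part_int = _permute_with_run_cap(
                list(grid.levels) * 3 + [grid.catch_level] * 9, rng, max_intensity_run
            )
        mds.extend(part_mds)
        parts.extend([part] * length)
        intensities.extend(part_int)

    positions = _permute_with_run_cap(["left"] * 108 + ["right"] * 108, rng, max_run=216)

    trials = [
        TrialSpec(
            trial_id=start_id + i,
            block="grasping",
            mass_distribution=mds[i],
            object_position=positions[i],
            intensity_um=float(intensities[i]),
            part=parts[i],
            session=session,
        )
        for i in range(216)
    ]
    return SequenceDesign(trials=trials, experiment="exp2", seed=seed)
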