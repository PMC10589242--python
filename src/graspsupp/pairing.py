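"""Previous-trial classification and condition aggregates.

Each grasping trial n is classified by the mass distribution (MD) of trial n - 1:
the ordered pair prev+curr gives the combination (LL, RL, LR, RR) and hence the
configuration — MD_same (LL, RR) when the mass side repeats, MD_different (RL, LR)
when it changes.  Example: the sequence R,R,L,L labels trial 2 as RR/MD_same,
trial 3 as RL/MD_different and trial 4 as LL/MD_same.

The digit-separation index subtracts the mean separation after a left-mass trial
from that after a right-mass trial, separately per configuration:
index_same = mean(RR) - mean(LL), index_different = mean(LR) - mean(RL).  Under
predictive placement from sensorimotor memory (thumb higher after a left mass),
index_same is negative and index_different positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError

__all__ = [
    "PairLabel",
    "SeparationIndex",
    "classify_pairs",
    "separation_index",
    "aggregate_exp1",
    "aggregate_exp2",
]

COMBINATIONS = ("LL", "RL", "LR", "RR")
SAME_COMBOS = ("LL", "RR")
DIFFERENT_COMBOS = ("RL", "LR")


@dataclass(frozen=True)
class PairLabel:
    trial_id: int
    prev_md: str
    curr_md: str

    @property
    def combination(self) -> str:
        return self.prev_md + self.curr_md

    @property
    def configuration(self) -> str:
        return "MD_same" if self.prev_md == self.curr_md else "MD_different"


@dataclass(frozen=True)
class SeparationIndex:
    participant_id: str | int
    index_same: float  # cm, RR - LL
    index_different: float  # cm, LR - RL


def classify_pairs(
    trial_ids,
    mds,
    lead_in=None,
) -> list[PairLabel]:
    """Label every trial that has a predecessor by the ordered MD pair.

    ``lead_in`` optionally flags trials that only serve as predecessors (they are
    never labeled themselves).  The central practice MD is not allowed here.
    """
    trial_ids = list(trial_ids)
    mds = list(mds)
    if len(trial_ids) != len(mds):
        raise ValueError("trial_ids and mds must have equal length")
    lead = list(lead_in) if lead_in is not None else [False] * len(mds)
    for md in mds:
        if md not in ("L", "R"):
            raise ValueError(f"pair classification requires L/R mass distributions, got {md!r}")
    labels = []
    for i in range(1, len(mds)):
        if lead[i]:
            continue
        labels.append(PairLabel(trial_id=trial_ids[i], prev_md=mds[i - 1], curr_md=mds[i]))
    return labels


def _combo_means(values_by_trial: dict, labels: list[PairLabel]) -> dict:
    groups: dict[str, list[float]] = {c: [] for c in COMBINATIONS}
    for lab in labels:
        v = values_by_trial.get(lab.trial_id, np.nan)
        if np.isfinite(v):
            groups[lab.combination].append(float(v))
    return groups


def separation_index(
    separations_by_trial: dict,
    labels: list[PairLabel],
    participant_id: str | int = 0,
) -> SeparationIndex:
    """Per-participant separation indices: mean(RR) - mean(LL) and mean(LR) - mean(RL)."""
    groups = _combo_means(separations_by_trial, labels)
    for combo in COMBINATIONS:
        if not groups[combo]:
            raise MissingDataError(f"no valid separation values for combination {combo}")
    return SeparationIndex(
        participant_id=participant_id,
        index_same=float(np.mean(groups["RR"]) - np.mean(groups["LL"])),
        index_different=float(np.mean(groups["LR"]) - np.mean(groups["RL"])),
    )


def aggregate_exp1(
    values_by_trial: dict,
    labels: list[PairLabel],
) -> dict:
    """Per-participant cell means of a kinematic variable over the two configurations.

    Returns ``{"MD_same": (mean, n), "MD_different": (mean, n)}``; invalid (NaN)
    trials are dropped listwise for the variable.
    """
    groups = _combo_means(values_by_trial, labels)
    out = {}
    for config, combos in (("MD_same", SAME_COMBOS), ("MD_different", DIFFERENT_COMBOS)):
        vals = [v for c in combos for v in groups[c]]
        if not vals:
            raise MissingDataError(f"no valid trials in configuration {config}")
        out[config] = (float(np.mean(vals)), len(vals))
    return out


def _cell_index(groups: dict, part: str) -> float:
    """Separation index for one sequence-part cell.

    Constant parts consist (beyond the inherited boundary trial) of repeats only, so
    their cell index uses the RR-LL contrast; mixed parts average the RR-LL and
    LR-RL contrasts with equal weight.
    """
    contrasts = []
    if groups["RR"] and groups["LL"]:
        contrasts.append(np.mean(groups["RR"]) - np.mean(groups["LL"]))
    if part == "mixed" and groups["LR"] and groups["RL"]:
        contrasts.append(np.mean(groups["LR"]) - np.mean(groups["RL"]))
    if not contrasts:
        raise MissingDataError(f"no classifiable pairs for part {part!r}")
    return float(np.mean(contrasts))


def aggregate_exp2(
    trials: pd.DataFrame,
    variable: str,
) -> dict:
    """2 x 2 cell values per participant-session table: {(part, session): value}.

    ``trials`` must carry columns trial_id, md, part, session and the variable; rows
    are one grasping sequence per session in presentation order.  For ``variable =
    'separation'`` the cell value is the within-part separation index (trial n
    classified by trial n - 1, part boundaries inheriting the predecessor from the
    previous part); for other variables it is the plain cell mean.
    """
    sessions = [s for s in ("implicit", "explicit") if s in set(trials["session"])]
    if len(sessions) < 2:
        raise MissingDataError("both implicit and explicit sessions are required")
    out = {}
    for session in sessions:
        sub = trials[trials["session"] == session].sort_values("trial_id")
        labels = classify_pairs(sub["trial_id"], sub["md"])
        part_of = dict(zip(sub["trial_id"], sub["part"]))
        values = dict(zip(sub["trial_id"], sub[variable]))
        for part in ("mixed", "constant"):
            if variable == "separation":
                groups: dict[str, list[float]] = {c: [] for c in COMBINATIONS}
                for lab in labels:
                    if part_of[lab.trial_id] != part:
                        continue
                    v = values.get(lab.trial_id, np.nan)
                    if np.isfinite(v):
                        groups[lab.combination].append(float(v))
                out[(part, session)] = _cell_index(groups, part)
            else:
                vals = sub.loc[sub["part"] == part, variable].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                if vals.size == 0:
                    raise MissingDataError(f"no valid trials in cell ({part}, {session})")
                out[(part, session)] = float(np.mean(vals))
    return out
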