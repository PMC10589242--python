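"""Yes/no psychometric fitting, detection thresholds, suppression scores, exclusion.

Detection data per condition are binomial counts at each probe intensity (including
the 0-µm catch row).  The model is a logistic core scaled between a guess rate gamma
and a lapse rate lambda:

    Psi(x) = gamma + (1 - gamma - lambda) * F((x - m) / s),   F = logistic,

with location m (µm) and width w = x(0.95) - x(0.05) of the core, so s = w/(2 ln 19).
Fitting is box-constrained binomial maximum likelihood with multi-start (quantile
heuristics), honest convergence reporting, and explicit degenerate-data errors for
all-yes/all-no or perfectly separable step data (where the ML width is zero).

The detection threshold is the intensity at 50% of the function — by default the
midpoint of the fitted core (which equals m for the symmetric logistic); an
absolute-probability criterion Psi(x) = 0.5 is available.  The suppression score is
the grasp-condition threshold minus the baseline threshold (positive = suppression).
Participants whose baseline false-alarm rate is not strictly below 30% are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logit

from .errors import DegenerateFitError, MissingDataError

__all__ = [
    "DetectionTable",
    "PsychometricFit",
    "SuppressionScore",
    "tabulate_responses",
    "fit_psychometric",
    "threshold",
    "suppression_score",
    "false_alarm_rate",
    "apply_exclusion",
    "psychometric_function",
]

WIDTH_SCALE = 2.0 * math.log(19.0)  # core width w = s * 2 ln 19

GAMMA_MAX = 0.30
LAPSE_MAX = 0.05
N_STARTS = 5


@dataclass(frozen=True)
class DetectionTable:
    """Binomial yes/no counts per probe intensity for one condition."""

    condition: str
    intensity_um: np.ndarray
    n_yes: np.ndarray
    n_total: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.intensity_um, dtype=float)
        k = np.asarray(self.n_yes, dtype=int)
        n = np.asarray(self.n_total, dtype=int)
        if not (x.shape == k.shape == n.shape):
            raise ValueError("columns must have equal length")
        if np.any(k > n) or np.any(k < 0) or np.any(n <= 0):
            raise ValueError("need 0 <= n_yes <= n_total and n_total > 0")
        if np.any(np.diff(np.sort(x)) == 0):
            raise ValueError("intensities must be unique per condition")
        object.__setattr__(self, "intensity_um", x)
        object.__setattr__(self, "n_yes", k)
        object.__setattr__(self, "n_total", n)

    @property
    def has_catch(self) -> bool:
        return bool(np.any(self.intensity_um == 0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "intensity_um": self.intensity_um,
                "n_yes": self.n_yes,
                "n_total": self.n_total,
            }
        )


@dataclass(frozen=True)
class PsychometricFit:
    guess: float
    lapse: float
    location: float  # m, µm
    width: float  # w, µm (95%-5% span of the core)
    loglik: float
    converged: bool
    condition: str = ""

    def predict(self, x) -> np.ndarray:
        return psychometric_function(np.asarray(x, dtype=float), self.guess, self.lapse, self.location, self.width)


@dataclass(frozen=True)
class SuppressionScore:
    participant_id: str | int
    condition: str
    value_um: float  # grasp threshold - baseline threshold; positive = suppression


def psychometric_function(x, guess, lapse, location, width):
    s = width / WIDTH_SCALE
    core = 1.0 / (1.0 + np.exp(-(np.asarray(x, dtype=float) - location) / s))
    return guess + (1.0 - guess - lapse) * core


def tabulate_responses(
    trials: pd.DataFrame,
    condition_col: str = "condition",
    merge_baselines: bool = True,
) -> dict:
    """Count yes/no responses per (condition, intensity).

    ``trials`` needs columns ``intensity_um``, ``response`` and ``condition_col``.
    The two rest blocks are merged into one ``baseline`` condition by default.
    Returns ``{condition: DetectionTable}``.
    """
    df = trials.copy()
    if df["response"].isna().any():
        bad = df.loc[df["response"].isna(), "trial_id"].tolist() if "trial_id" in df else "?"
        raise ValueError(f"trials without a response: {bad}")
    cond = df[condition_col].astype(str)
    if merge_baselines:
        cond = cond.replace({"baseline_pre": "baseline", "baseline_post": "baseline"})
    df = df.assign(_cond=cond)
    out = {}
    for c, grp in df.groupby("_cond", sort=True):
        counts = (
            grp.assign(_yes=grp["response"].astype(bool))
            .groupby("intensity_um")["_yes"]
            .agg(["sum", "count"])
            .reset_index()
            .sort_values("intensity_um")
        )
        out[str(c)] = DetectionTable(
            condition=str(c),
            intensity_um=counts["intensity_um"].to_numpy(),
            n_yes=counts["sum"].to_numpy(),
            n_total=counts["count"].to_numpy(),
        )
    return out


def _check_degenerate(table: DetectionTable) -> None:
    k, n = table.n_yes, table.n_total
    if np.all(k == 0):
        raise DegenerateFitError("all responses 'no': threshold undefined (location above range)")
    if np.all(k == n):
        raise DegenerateFitError("all responses 'yes': threshold undefined (location below range)")
    rates = k / n
    order = np.argsort(table.intensity_um)
    r = rates[order]
    if np.all((r == 0) | (r == 1)) and np.all(np.diff(r) >= 0):
        raise DegenerateFitError("perfectly separable step data: ML width is zero")


def _nll(params, x, k, n):
    g, lam, m, w = params
    p = psychometric_function(x, g, lam, m, w)
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))


def _start_points(table: DetectionTable, w_lo, w_hi, m_lo, m_hi):
    """Quantile-based heuristics for (gamma, lambda, m, w) multi-start."""
    x, k, n = table.intensity_um, table.n_yes, table.n_total
    rates = k / n
    g0 = float(rates[x == 0][0]) if table.has_catch else float(rates.min())
    g0 = min(max(g0, 0.01), GAMMA_MAX - 0.01)
    pos = x > 0
    xs, rs = x[pos], rates[pos]
    order = np.argsort(xs)
    xs, rs = xs[order], rs[order]
    m0 = float(np.interp(0.5, np.maximum.accumulate(rs), xs)) if rs.size else float(np.median(x))
    m0 = min(max(m0, m_lo), m_hi)
    span = float(xs.max() - xs.min()) if xs.size > 1 else w_hi / 2
    starts = []
    for m_mult, w0 in ((1.0, span), (0.7, span / 2), (1.3, span / 2), (1.0, span * 1.5), (1.0, span / 4)):
        starts.append(
            [
                g0,
                0.02,
                min(max(m0 * m_mult, m_lo), m_hi),
                min(max(w0, w_lo), w_hi),
            ]
        )
    return starts[:N_STARTS]


def fit_psychometric(
    table: DetectionTable,
    gamma_max: float = GAMMA_MAX,
    lapse_max: float = LAPSE_MAX,
) -> PsychometricFit:
    """Box-constrained binomial ML fit of (gamma, lambda, m, w) with multi-start."""
    if np.count_nonzero(table.intensity_um > 0) < 3:
        raise ValueError("need at least 3 distinct non-zero intensities to fit")
    _check_degenerate(table)
    x, k, n = table.intensity_um, table.n_yes, table.n_total
    xmax = float(x.max())
    span = float(x[x > 0].max() - x[x > 0].min())
    m_lo, m_hi = 1e-3, 2.0 * xmax
    w_lo, w_hi = max(span / 50.0, 1e-2), 5.0 * span
    bounds = [(0.0, gamma_max), (0.0, lapse_max), (m_lo, m_hi), (w_lo, w_hi)]

    best = None
    any_success = False
    for p0 in _start_points(table, w_lo, w_hi, m_lo, m_hi):
        res = minimize(_nll, p0, args=(x, k, n), method="L-BFGS-B", bounds=bounds)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    g, lam, m, w = (float(v) for v in best.x)
    return PsychometricFit(
        guess=g,
        lapse=lam,
        location=m,
        width=w,
        loglik=float(-best.fun),
        converged=any_success,
        condition=table.condition,
    )


def threshold(fit: PsychometricFit, criterion: str = "midpoint") -> float:
    """Detection threshold (µm): the intensity at 50% of the function.

    ``midpoint`` (default) — the 50% point of the logistic core, i.e. the location m
    of the guess/lapse-corrected function.  ``absolute`` — the x where the raw
    probability Psi(x) = 0.5 (undefined when the asymptotes straddle it).
    """
    if not fit.converged:
        raise DegenerateFitError("threshold requested from a non-converged fit")
    if criterion == "midpoint":
        return fit.location
    if criterion == "absolute":
        target = (0.5 - fit.guess) / (1.0 - fit.guess - fit.lapse)
        if not 0.0 < target < 1.0:
            raise ValueError(
                f"absolute 50% criterion unreachable with guess={fit.guess:.3f}, lapse={fit.lapse:.3f}"
            )
        s = fit.width / WIDTH_SCALE
        return float(fit.location + s * logit(target))
    raise ValueError(f"unknown criterion {criterion!r}")


def suppression_score(
    grasp_fit: PsychometricFit,
    baseline_fit: PsychometricFit,
    participant_id: str | int = 0,
    criterion: str = "midpoint",
) -> SuppressionScore:
    """Grasp-condition threshold minus baseline threshold (µm)."""
    return SuppressionScore(
        participant_id=participant_id,
        condition=grasp_fit.condition,
        value_um=threshold(grasp_fit, criterion) - threshold(baseline_fit, criterion),
    )


def false_alarm_rate(table: DetectionTable) -> float:
    """Yes-rate on the 0-µm catch row."""
    catch = table.intensity_um == 0.0
    if not catch.any():
        raise MissingDataError(f"no catch trials in condition {table.condition!r}")
    return float(table.n_yes[catch][0] / table.n_total[catch][0])


def apply_exclusion(rate: float, cutoff: float = 0.30) -> bool:
    """True = keep the participant; the rule is *strictly below* the cutoff."""
    return rate < cutoff
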