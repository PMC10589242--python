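"""Group-level inference: t-tests with Cohen's d and 2x2 repeated-measures ANOVA.

The analysis aggregates to one value per participant (and condition cell) before
inference, so the toolbox is small: two-sided one-sample and paired t-tests with
exact Student p-values and Cohen's d, a 2x2 within-subject ANOVA reporting F with
(1, n-1) degrees of freedom and partial eta squared = SS_effect / (SS_effect +
SS_error), and Bonferroni correction for post-hoc contrasts.  For a 2x2
within-subject design each effect's F equals the square of the paired t on the
corresponding contrast — used as a built-in cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ZeroVarianceError

__all__ = ["TTestResult", "AnovaResult", "one_sample_t", "paired_t", "rm_anova_2x2", "bonferroni"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float  # two-sided
    d: float  # Cohen's d
    n: int
    mean: float

    def summary(self) -> str:
        return f"t({self.df}) = {self.t:.2f}, p = {self.p:.3f}, d = {self.d:.2f}"


@dataclass(frozen=True)
class EffectResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float

    def summary(self) -> str:
        return f"F({self.df1}, {self.df2}) = {self.F:.2f}, p = {self.p:.3f}, eta_p^2 = {self.partial_eta_sq:.2f}"


@dataclass(frozen=True)
class AnovaResult:
    """Effects keyed 'A', 'B', 'AxB' plus the factor names they stand for."""

    effects: dict
    factor_a: str = "A"
    factor_b: str = "B"
    n: int = 0


def one_sample_t(values, mu: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test against ``mu`` with Cohen's d = (mean - mu)/sd."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ZeroVarianceError("one-sample t undefined: zero variance")
    res = sps.ttest_1samp(x, popmean=mu)
    mean = float(np.mean(x))
    return TTestResult(
        t=float(res.statistic),
        df=int(x.size - 1),
        p=float(res.pvalue),
        d=(mean - mu) / sd,
        n=int(x.size),
        mean=mean,
    )


def paired_t(a, b) -> TTestResult:
    """Two-sided paired t-test; t and d are computed on the difference scores."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return one_sample_t(a - b, mu=0.0)


def rm_anova_2x2(cells, factor_a: str = "A", factor_b: str = "B") -> AnovaResult:
    """2x2 repeated-measures ANOVA on per-participant cell means.

    ``cells`` is an array-like of shape (n, 2, 2): participants x levels of factor A
    x levels of factor B, with no missing cells.  Each effect is tested against its
    own effect-by-subject interaction (df = 1, n - 1).
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValueError(f"cells must have shape (n, 2, 2), got {y.shape}")
    if np.isnan(y).any():
        raise ValueError("missing cells are not allowed")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")

    grand = y.mean()
    subj = y.mean(axis=(1, 2))  # (n,)
    mean_a = y.mean(axis=(0, 2))  # (2,)
    mean_b = y.mean(axis=(0, 1))  # (2,)
    mean_ab = y.mean(axis=0)  # (2, 2)
    mean_as = y.mean(axis=2)  # (n, 2)
    mean_bs = y.mean(axis=1)  # (n, 2)

    ss_a = n * 2 * np.sum((mean_a - grand) ** 2)
    ss_b = n * 2 * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_as = 2 * np.sum((mean_as - subj[:, None] - mean_a[None, :] + grand) ** 2)
    ss_bs = 2 * np.sum((mean_bs - subj[:, None] - mean_b[None, :] + grand) ** 2)
    resid = (
        y
        - mean_as[:, :, None]
        - mean_bs[:, None, :]
        - mean_ab[None, :, :]
        + subj[:, None, None]
        + mean_a[None, :, None]
        + mean_b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    df_err = n - 1
    effects = {}
    for key, ss_eff, ss_err in (("A", ss_a, ss_as), ("B", ss_b, ss_bs), ("AxB", ss_ab, ss_abs)):
        if ss_err == 0.0:
            raise ZeroVarianceError(f"effect {key}: zero error variance, F undefined")
        F = float((ss_eff / 1.0) / (ss_err / df_err))
        effects[key] = EffectResult(
            F=F,
            df1=1,
            df2=df_err,
            p=float(sps.f.sf(F, 1, df_err)),
            partial_eta_sq=float(ss_eff / (ss_eff + ss_err)),
        )
    return AnovaResult(effects=effects, factor_a=factor_a, factor_b=factor_b, n=n)


def bonferroni(p_values, m: int | None = None):
    """Bonferroni-adjusted p-values: min(1, p * m); m defaults to the number of tests."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    adj = np.minimum(1.0, p * m)
    return float(adj[0]) if np.isscalar(p_values) else adj
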