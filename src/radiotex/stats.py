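"""Univariate association statistics: Pearson correlations with survival and
histology markers, two-group comparisons (Student t, Cohen's d), and
Kaplan-Meier survival with a log-rank test.

Cohen's d is reported as an absolute standardized difference.  When only
summary statistics (means and SDs, unknown n) are available the equal-weight
pooled SD ``sqrt((s1^2 + s2^2)/2)`` is used; with full data the
sample-size-weighted pooled SD is used.  Multiple testing across a feature
screen is reported uncorrected by default, with an optional
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .errors import DegenerateInputError, UndefinedCorrelationError


@dataclass
class AssociationResult:
    feature: str
    target: str
    r: float
    t_stat: float
    p: float
    n: int


@dataclass
class GroupComparison:
    feature: str
    mean_1: float
    sd_1: float
    mean_2: float
    sd_2: float
    t_stat: float
    p: float
    cohens_d: float


@dataclass
class KMEstimate:
    """Per-group product-limit curves plus the two-group log-rank test."""

    curves: dict[str, pd.DataFrame]  # group -> columns [time, survival_prob]
    logrank_chi2: float | None
    logrank_p: float | None

    def to_dict(self) -> dict:
        return {
            "curves": {
                g: {"time": df["time"].tolist(), "survival_prob": df["survival_prob"].tolist()}
                for g, df in self.curves.items()
            },
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
        }


def pearson_assoc(x, y, feature: str = "x", target: str = "y") -> AssociationResult:
    """Sample Pearson r with the two-sided t-test p (n-2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError(f"pearson needs equal-length vectors with n >= 3, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DegenerateInputError("non-finite values in correlation input")
    if x.std() == 0.0 or y.std() == 0.0:
        raise UndefinedCorrelationError(
            f"zero variance in '{feature if x.std() == 0 else target}'"
        )
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t, p = np.inf if r > 0 else -np.inf, 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return AssociationResult(feature=feature, target=target, r=r, t_stat=float(t), p=p, n=n)


def cohens_d_summary(mean_1: float, sd_1: float, mean_2: float, sd_2: float) -> float:
    """|d| from printed summary statistics, equal-weight pooled SD."""
    pooled = np.sqrt((sd_1**2 + sd_2**2) / 2.0)
    if pooled == 0.0:
        if mean_1 == mean_2:
            return 0.0
        raise DegenerateInputError("zero pooled SD with unequal means: d is infinite")
    return float(abs(mean_1 - mean_2) / pooled)


def group_compare(values_1, values_2, feature: str = "") -> GroupComparison:
    """Pooled-variance Student t (two-sided) and absolute Cohen's d."""
    a = np.asarray(values_1, dtype=np.float64)
    b = np.asarray(values_2, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("need >= 2 values per group")
    n1, n2 = a.size, b.size
    s1, s2 = a.std(ddof=1), b.std(ddof=1)
    pooled_var = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return GroupComparison(feature, a.mean(), 0.0, b.mean(), 0.0, 0.0, 1.0, 0.0)
        raise DegenerateInputError("zero pooled variance with unequal means: d is infinite")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    d = abs(a.mean() - b.mean()) / np.sqrt(pooled_var)
    return GroupComparison(
        feature=feature,
        mean_1=float(a.mean()),
        sd_1=float(s1),
        mean_2=float(b.mean()),
        sd_2=float(s2),
        t_stat=float(t),
        p=float(p),
        cohens_d=float(d),
    )


def km_estimate(times, events, groups=None) -> KMEstimate:
    """Kaplan-Meier curves per group and, for two groups, the log-rank test."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(bool)
    if times.size == 0 or np.any(times <= 0):
        raise DegenerateInputError("survival times must be positive and non-empty")
    if groups is None:
        groups = np.array(["all"] * times.size)
    groups = np.asarray(groups)
    curves: dict[str, pd.DataFrame] = {}
    for g in np.unique(groups):
        sel = groups == g
        if not sel.any():
            raise DegenerateInputError(f"empty group '{g}'")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], event_observed=events[sel])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival_prob"]
        curves[str(g)] = sf
    chi2 = p = None
    labels = np.unique(groups)
    if labels.size == 2:
        s0, s1 = groups == labels[0], groups == labels[1]
        res = logrank_test(times[s0], times[s1], event_observed_A=events[s0],
                           event_observed_B=events[s1])
        chi2, p = float(res.test_statistic), float(res.p_value)
    return KMEstimate(curves=curves, logrank_chi2=chi2, logrank_p=p)


def feature_survival_screen(
    table: pd.DataFrame, survival, target: str = "survival_days", alpha: float = 0.05,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Pearson-correlate every feature with survival; rank by |r|.

    Returns a DataFrame with columns feature, r, t_stat, p, n, significant
    (p < alpha, uncorrected by default), and q when ``bh_adjust`` is on.
    """
    survival = np.asarray(survival, dtype=np.float64)
    rows = []
    for col in table.columns:
        res = pearson_assoc(table[col].to_numpy(), survival, feature=col, target=target)
        rows.append({"feature": col, "r": res.r, "t_stat": res.t_stat, "p": res.p, "n": res.n})
    out = pd.DataFrame(rows)
    if bh_adjust:
        out["q"] = sps.false_discovery_control(out["p"].to_numpy(), method="bh")
        out["significant"] = out["q"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    out = out.reindex(out["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)
    return out
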