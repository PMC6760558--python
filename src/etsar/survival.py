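"""Median-split Kaplan–Meier / log-rank analysis of biochemical recurrence.

Samples are split at the median of a signature score (high = strictly
above the median, ties to low), curves come from the product-limit
estimator, and the two groups are compared with the standard two-group
log-rank test on 1 df.  Estimation and testing are delegated to
lifelines; curves are re-expressed at distinct event times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .core import validate_survival


@dataclass
class KMCurve:
    """Product-limit survival at distinct event times (S starts at 1)."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_months": self.times, "survival": self.survival,
             "at_risk": self.at_risk, "events": self.events}
        )


@dataclass
class LogRankResult:
    chi2: float
    p: float
    df: int = 1
    n_per_group: tuple[int, int] = (0, 0)


def median_split(scores: pd.Series) -> pd.Series:
    """Label samples 'high' (score > median) or 'low' (score <= median)."""
    scores = pd.Series(scores)
    if len(scores) < 4:
        raise ValueError("need >=4 samples for a median split")
    med = float(scores.median())
    if float(scores.max()) == float(scores.min()):
        raise ValueError("all scores equal; median split is degenerate")
    return pd.Series(np.where(scores.to_numpy() > med, "high", "low"), index=scores.index)


def km_estimate(surv: pd.DataFrame) -> KMCurve:
    """Kaplan–Meier curve for one survival table (sample_id, time_months, event)."""
    surv = validate_survival(surv)
    if len(surv) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(surv["time_months"], event_observed=surv["event"].astype(int))
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    if len(times):
        survival = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    else:
        survival = np.array([], dtype=float)
    return KMCurve(
        times=times,
        survival=survival,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        events=ev["observed"].to_numpy(dtype=int),
    )


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> LogRankResult:
    """Two-group log-rank test (chi-square on 1 df)."""
    a, b = validate_survival(group_a), validate_survival(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if int(a["event"].sum()) + int(b["event"].sum()) == 0:
        raise ValueError("log-rank test needs at least one event overall")
    res = _ll_logrank(
        a["time_months"], b["time_months"],
        event_observed_A=a["event"].astype(int), event_observed_B=b["event"].astype(int),
    )
    return LogRankResult(
        chi2=float(res.test_statistic), p=float(res.p_value), df=1,
        n_per_group=(len(a), len(b)),
    )


def bcr_by_median_score(scores: pd.Series, surv: pd.DataFrame):
    """Median-split a score over the samples with survival data, then KM + log-rank.

    Returns (labels, {'high': KMCurve, 'low': KMCurve}, LogRankResult).
    """
    surv = validate_survival(surv)
    common = [s for s in surv["sample_id"] if s in scores.index]
    if len(common) < 4:
        raise ValueError("need >=4 samples with both scores and survival data")
    surv = surv.set_index("sample_id").loc[common].reset_index()
    labels = median_split(scores.loc[common])
    groups = {
        lab: surv[surv["sample_id"].map(labels) == lab].reset_index(drop=True)
        for lab in ("high", "low")
    }
    curves = {lab: km_estimate(df) for lab, df in groups.items()}
    result = logrank_test(groups["high"], groups["low"])
    return labels, curves, result
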