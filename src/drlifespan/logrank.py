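"""Two-group log-rank test from first principles.

At each distinct death time the observed deaths in group 1 are compared with
their conditional hypergeometric expectation given the risk sets; the summed
(O - E) over its summed variance gives a 1-df chi-square statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["LogRankResult", "logrank_test"]


@dataclass(frozen=True)
class LogRankResult:
    """Accumulated O/E/V sums and the resulting chi-square test.

    ``degenerate`` marks inputs with zero total variance (e.g. every subject
    in one group by the only death time); the statistic is then defined as 0
    with p = 1 rather than raising.
    """

    observed: float
    expected: float
    variance: float
    statistic: float
    p_value: float
    degenerate: bool = False


def logrank_test(time1, event1, time2, event2) -> LogRankResult:
    """Standard two-group log-rank test.

    Parameters are the observation times and death indicators (1 = death,
    0 = censored) of the two groups. Requires both groups non-empty and at
    least one death overall.
    """
    t1 = np.asarray(time1, dtype=float)
    t2 = np.asarray(time2, dtype=float)
    e1 = np.asarray(event1).astype(int)
    e2 = np.asarray(event2).astype(int)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    for e in (e1, e2):
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event indicators must be binary (0/1)")
    if e1.sum() + e2.sum() == 0:
        raise ValueError("log-rank test requires at least one death")

    t_all = np.sort(np.concatenate([t1, t2]))
    t1_sorted = np.sort(t1)
    dt_pooled = np.sort(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    dt1_sorted = np.sort(t1[e1 == 1])

    # per distinct death time: risk-set sizes and death counts, vectorised
    death_times, d = np.unique(dt_pooled, return_counts=True)
    n = t_all.size - np.searchsorted(t_all, death_times, side="left")
    n1 = t1_sorted.size - np.searchsorted(t1_sorted, death_times, side="left")
    d1 = np.searchsorted(dt1_sorted, death_times, side="right") - np.searchsorted(
        dt1_sorted, death_times, side="left"
    )

    o_sum = float(d1.sum())
    e_sum = float(np.sum(d * n1 / n))
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    v_sum = float(np.sum(np.where(n > 1, v, 0.0)))

    if v_sum <= 0:
        return LogRankResult(o_sum, e_sum, v_sum, 0.0, 1.0, degenerate=True)
    statistic = (o_sum - e_sum) ** 2 / v_sum
    p = float(stats.chi2.sf(statistic, df=1))
    return LogRankResult(o_sum, e_sum, v_sum, float(statistic), p)
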