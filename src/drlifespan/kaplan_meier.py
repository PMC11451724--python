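"""Kaplan-Meier product-limit estimation with Greenwood variance.

The median confidence interval follows the Brookmeyer-Crowley construction on
the log(-log) scale: the interval is the set of times whose pointwise 95%
confidence band for S(t) still contains 0.5, the convention behind median CIs
reported by standard survival software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["KMEstimate", "km_estimate"]


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve over the distinct event times.

    Attributes
    ----------
    times : ndarray
        Sorted distinct times at which at least one death occurred.
    survival : ndarray
        S(t) immediately after each event time (step function, constant
        between events, S(0) = 1 before the first).
    greenwood_var : ndarray
        Greenwood variance estimate of S(t) at each event time.
    n_risk, n_event : ndarray
        Subjects at risk and deaths at each event time.
    median : float
        Smallest event time with S(t) <= 0.5; NaN if S never reaches 0.5.
    median_ci : tuple of float
        95% confidence interval for the median (entries may be NaN when the
        corresponding band never crosses 0.5).
    n : int
        Number of subjects.
    all_censored : bool
        True when the input contained no deaths (degenerate curve S == 1).
    """

    times: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    median: float
    median_ci: tuple
    n: int
    all_censored: bool = False

    def survival_at(self, t) -> np.ndarray | float:
        """S(t) for arbitrary times (right-continuous step function)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return out if np.ndim(t) else float(out)

    def restricted_mean(self, tau: float | None = None) -> float:
        """Area under S(t) from 0 to ``tau`` (default: last event time)."""
        if self.times.size == 0:
            return float("nan")
        if tau is None:
            tau = float(self.times[-1])
        grid = np.concatenate([[0.0], self.times[self.times <= tau], [tau]])
        s = np.concatenate([[1.0], self.survival])[: grid.size - 1]
        return float(np.sum(s * np.diff(grid)))


def _median_ci(times, survival, greenwood_var, conf_level=0.95):
    """Invert the log(-log) pointwise band at S = 0.5."""
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(survival)
        se_cll = np.sqrt(greenwood_var) / (survival * np.abs(logs))
        cll = np.log(-logs)
        upper_s = np.exp(-np.exp(cll - z * se_cll))  # upper confidence curve
        lower_s = np.exp(-np.exp(cll + z * se_cll))  # lower confidence curve
    # S == 0 or 1 makes the transform degenerate; treat the band as pinned.
    upper_s = np.where(survival >= 1.0, 1.0, upper_s)
    lower_s = np.where(survival >= 1.0, 1.0, lower_s)
    upper_s = np.where(survival <= 0.0, 0.0, upper_s)
    lower_s = np.where(survival <= 0.0, 0.0, lower_s)

    def first_crossing(curve):
        hit = np.nonzero(curve <= 0.5)[0]
        return float(times[hit[0]]) if hit.size else float("nan")

    return (first_crossing(lower_s), first_crossing(upper_s))


def km_estimate(time, event, conf_level: float = 0.95) -> KMEstimate:
    """Kaplan-Meier estimate from right-censored data.

    Parameters
    ----------
    time : array-like
        Nonnegative observation times (days).
    event : array-like
        1 for an observed death, 0 for right censoring. Deaths and censorings
        sharing a time follow the standard convention: censored subjects at t
        are still at risk for deaths at t.

    An input with no deaths is not an error: it yields a flat curve with
    ``all_censored=True`` and an undefined (NaN) median.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or time.shape != event.shape:
        raise ValueError("time and event must be one-dimensional and equal length")
    if time.size == 0:
        raise ValueError("empty input")
    if np.any(time < 0):
        raise ValueError("negative times are not valid survival data")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event must be binary (0/1)")
    event = event.astype(int)

    n = time.size
    if event.sum() == 0:
        empty = np.array([])
        return KMEstimate(
            times=empty,
            survival=empty,
            greenwood_var=empty,
            n_risk=np.array([], dtype=int),
            n_event=np.array([], dtype=int),
            median=float("nan"),
            median_ci=(float("nan"), float("nan")),
            n=n,
            all_censored=True,
        )

    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    death_times = np.unique(t_s[e_s == 1])
    # at-risk counts: everyone with observed time >= t
    n_risk = n - np.searchsorted(t_s, death_times, side="left")
    n_event = np.array([int(((t_s == t) & (e_s == 1)).sum()) for t in death_times])

    frac = 1.0 - n_event / n_risk
    survival = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = n_event / (n_risk * (n_risk - n_event))
        gw_terms = np.where(n_risk == n_event, 0.0, gw_terms)  # S hits 0; var pinned
    greenwood_var = survival**2 * np.cumsum(gw_terms)

    below = np.nonzero(survival <= 0.5)[0]
    median = float(death_times[below[0]]) if below.size else float("nan")
    ci = _median_ci(death_times, survival, greenwood_var, conf_level)

    return KMEstimate(
        times=death_times,
        survival=survival,
        greenwood_var=greenwood_var,
        n_risk=n_risk,
        n_event=n_event,
        median=median,
        median_ci=ci,
        n=n,
    )
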