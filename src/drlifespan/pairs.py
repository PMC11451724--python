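"""Per-replicate DR-vs-AL comparisons and cross-laboratory reproducibility.

Every (lab, cohort, genotype, sex) stratum contributes one DR/AL pair: a
two-group log-rank test, Kaplan-Meier medians for both arms, a direction call
for the longer-lived arm, and the median difference ``delta_l = median(DR) -
median(AL)``. Familywise error over the grid is controlled by Bonferroni
(alpha / number of pairs). Reproducibility between the two labs is summarised
by Spearman rank correlations of per-stratum median (or mean) longevities and
of the delta_l values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kaplan_meier import KMEstimate, km_estimate
from .logrank import logrank_test

__all__ = [
    "PairResult",
    "PairSummary",
    "CorrelationResult",
    "bonferroni_threshold",
    "pair_grid",
    "summarize_pairs",
    "cross_lab_correlation",
    "delta_correlation",
    "lab_summary_correlation",
    "DietPairAnalysis",
    "PairAnalysisResults",
]

logger = logging.getLogger(__name__)

STRATUM_KEYS = ("lab", "cohort", "genotype", "sex")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Familywise threshold ``alpha / m`` for ``m`` comparisons."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    if not m >= 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m!r}")
    return alpha / m


@dataclass(frozen=True)
class PairResult:
    """One DR/AL comparison within a (lab, cohort, genotype, sex) stratum."""

    lab: str
    cohort: str
    genotype: str
    sex: str
    p_value: float  # NaN when not computable (e.g. an all-censored arm)
    direction: str  # "DR", "AL" or "none" — the longer-lived arm
    median_dr: float = float("nan")
    median_al: float = float("nan")
    delta_l: float = float("nan")

    @property
    def stratum(self) -> tuple:
        return (self.lab, self.cohort, self.genotype, self.sex)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with a two-sided p-value."""

    rho: float
    p_value: float
    n: int


def _rollup(results, predicate, key) -> dict:
    out: dict = {}
    for r in results:
        out.setdefault(getattr(r, key), 0)
        if predicate(r):
            out[getattr(r, key)] += 1
    return out


@dataclass(frozen=True)
class PairSummary:
    """Significance tallies over a grid of DR/AL pairs."""

    n_pairs: int
    alpha_family: float
    bonferroni_threshold: float
    n_significant_dr: int
    n_significant_al: int
    per_genotype: dict
    per_sex: dict
    per_lab: dict
    per_cohort: dict
    nominal_alpha: float
    nominal_counts: dict  # same rollups at unadjusted p < nominal_alpha

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "alpha_family": self.alpha_family,
            "bonferroni_threshold": self.bonferroni_threshold,
            "n_significant_dr": self.n_significant_dr,
            "n_significant_al": self.n_significant_al,
            "per_genotype": self.per_genotype,
            "per_sex": self.per_sex,
            "per_lab": self.per_lab,
            "per_cohort": self.per_cohort,
            "nominal_alpha": self.nominal_alpha,
            "nominal_counts": self.nominal_counts,
        }


def _direction(km_dr: KMEstimate, km_al: KMEstimate) -> tuple[str, float]:
    """Longer-lived arm by KM median, restricted-mean tiebreak."""
    m_dr, m_al = km_dr.median, km_al.median
    delta = m_dr - m_al if np.isfinite(m_dr) and np.isfinite(m_al) else float("nan")
    if np.isnan(m_dr) and np.isnan(m_al):
        pass  # both curves stay above 0.5 — fall through to restricted mean
    elif np.isnan(m_dr):
        return "DR", delta  # DR survival never reached 0.5: longer-lived
    elif np.isnan(m_al):
        return "AL", delta
    elif m_dr > m_al:
        return "DR", delta
    elif m_al > m_dr:
        return "AL", delta
    tau = min(
        km_dr.times[-1] if km_dr.times.size else np.inf,
        km_al.times[-1] if km_al.times.size else np.inf,
    )
    if not np.isfinite(tau):
        return "none", delta
    rm_dr, rm_al = km_dr.restricted_mean(tau), km_al.restricted_mean(tau)
    if rm_dr > rm_al:
        return "DR", delta
    if rm_al > rm_dr:
        return "AL", delta
    return "none", delta


def pair_grid(
    data: pd.DataFrame,
    duration_col: str = "time_days",
    event_col: str = "event",
) -> list[PairResult]:
    """One :class:`PairResult` per (lab, cohort, genotype, sex) stratum.

    Strata missing one of the two diet arms are skipped with a logged
    warning; strata where an arm has no deaths get ``p_value = NaN`` and
    direction ``none`` (the log-rank test is not computable there).
    """
    results: list[PairResult] = []
    for keys, grp in data.groupby(list(STRATUM_KEYS), sort=True, observed=True):
        lab, cohort, genotype, sex = (str(k) for k in keys)
        dr = grp[grp["diet"] == "DR"]
        al = grp[grp["diet"] == "AL"]
        if dr.empty or al.empty:
            logger.warning(
                "stratum %s missing a diet arm (DR n=%d, AL n=%d); skipped",
                keys, len(dr), len(al),
            )
            continue
        km_dr = km_estimate(dr[duration_col], dr[event_col])
        km_al = km_estimate(al[duration_col], al[event_col])
        if km_dr.all_censored or km_al.all_censored:
            results.append(
                PairResult(lab, cohort, genotype, sex, float("nan"), "none",
                           km_dr.median, km_al.median)
            )
            continue
        lr = logrank_test(
            dr[duration_col], dr[event_col], al[duration_col], al[event_col]
        )
        direction, delta = _direction(km_dr, km_al)
        results.append(
            PairResult(
                lab, cohort, genotype, sex,
                p_value=lr.p_value,
                direction=direction,
                median_dr=km_dr.median,
                median_al=km_al.median,
                delta_l=delta,
            )
        )
    return results


def summarize_pairs(
    results: list[PairResult],
    alpha: float = 0.05,
    nominal_alpha: float = 0.05,
) -> PairSummary:
    """Bonferroni-corrected and nominal significance tallies over the grid."""
    if not results:
        raise ValueError("empty pair results")
    m = len(results)
    thr = bonferroni_threshold(alpha, m)

    def sig(r: PairResult, direction: str) -> bool:
        return (
            np.isfinite(r.p_value)
            and r.p_value <= thr
            and r.direction == direction
        )

    def sig_any(r: PairResult) -> bool:
        return sig(r, "DR") or sig(r, "AL")

    def nominal(r: PairResult) -> bool:
        return np.isfinite(r.p_value) and r.p_value < nominal_alpha

    def rollups(pred) -> dict:
        return {
            "genotype": _rollup(results, pred, "genotype"),
            "sex": _rollup(results, pred, "sex"),
            "lab": _rollup(results, pred, "lab"),
            "cohort": _rollup(results, pred, "cohort"),
        }

    per = rollups(sig_any)
    return PairSummary(
        n_pairs=m,
        alpha_family=alpha,
        bonferroni_threshold=thr,
        n_significant_dr=sum(sig(r, "DR") for r in results),
        n_significant_al=sum(sig(r, "AL") for r in results),
        per_genotype=per["genotype"],
        per_sex=per["sex"],
        per_lab=per["lab"],
        per_cohort=per["cohort"],
        nominal_alpha=nominal_alpha,
        nominal_counts=rollups(nominal),
    )


def cross_lab_correlation(x, y) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties, t-approx p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be matched one-dimensional vectors")
    if x.size < 3:
        raise ValueError("need at least 3 matched pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=int(x.size))


def lab_summary_correlation(
    data: pd.DataFrame,
    labs: tuple[str, str] | None = None,
    summary: str = "median",
    duration_col: str = "time_days",
    event_col: str = "event",
) -> CorrelationResult:
    """Correlate per-stratum longevities between two labs.

    Each matched (cohort, genotype, sex, diet) cell contributes one point:
    the KM median (default) or restricted-mean longevity in each lab.
    """
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    if labs is None:
        found = sorted(data["lab"].astype(str).unique())
        if len(found) != 2:
            raise ValueError(f"expected exactly 2 labs, found {found}")
        labs = (found[0], found[1])

    def cell_value(grp) -> float:
        km = km_estimate(grp[duration_col], grp[event_col])
        return km.median if summary == "median" else km.restricted_mean()

    keys = ["cohort", "genotype", "sex", "diet"]
    values: dict[str, dict] = {lab: {} for lab in labs}
    for (lab, *rest), grp in data.groupby(["lab"] + keys, sort=True, observed=True):
        if str(lab) in values and len(grp):
            values[str(lab)][tuple(map(str, rest))] = cell_value(grp)
    common = sorted(set(values[labs[0]]) & set(values[labs[1]]))
    a = [values[labs[0]][k] for k in common]
    b = [values[labs[1]][k] for k in common]
    mask = np.isfinite(a) & np.isfinite(b)
    return cross_lab_correlation(np.asarray(a)[mask], np.asarray(b)[mask])


def delta_correlation(
    results_lab_a: list[PairResult], results_lab_b: list[PairResult]
) -> CorrelationResult:
    """Spearman correlation of DR-minus-AL median differences across labs.

    Pairs are matched on (cohort, genotype, sex); unmatched strata are
    dropped with a logged warning.
    """
    key = lambda r: (r.cohort, r.genotype, r.sex)
    a = {key(r): r.delta_l for r in results_lab_a}
    b = {key(r): r.delta_l for r in results_lab_b}
    common = sorted(set(a) & set(b))
    dropped = (set(a) | set(b)) - set(common)
    if dropped:
        logger.warning("dropping %d unmatched strata: %s", len(dropped), sorted(dropped))
    xs = np.array([a[k] for k in common])
    ys = np.array([b[k] for k in common])
    mask = np.isfinite(xs) & np.isfinite(ys)
    return cross_lab_correlation(xs[mask], ys[mask])


# ----------------------------------------------------------- model-style API


@dataclass
class PairAnalysisResults:
    """Pair grid, tallies and cross-lab correlations for one event table."""

    pairs: list[PairResult]
    pair_summary: PairSummary
    lab_correlation: CorrelationResult | None
    delta_corr: CorrelationResult | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lab": [r.lab for r in self.pairs],
                "cohort": [r.cohort for r in self.pairs],
                "genotype": [r.genotype for r in self.pairs],
                "sex": [r.sex for r in self.pairs],
                "p_value": [r.p_value for r in self.pairs],
                "direction": [r.direction for r in self.pairs],
                "median_dr": [r.median_dr for r in self.pairs],
                "median_al": [r.median_al for r in self.pairs],
                "delta_l": [r.delta_l for r in self.pairs],
            }
        )

    def summary(self) -> str:
        s = self.pair_summary
        lines = [
            f"DR/AL pair grid: {s.n_pairs} pairs, Bonferroni threshold "
            f"{s.bonferroni_threshold:.6g} (familywise alpha {s.alpha_family})",
            f"significant pairs: {s.n_significant_dr} favor DR, "
            f"{s.n_significant_al} favor AL",
        ]
        if self.lab_correlation is not None:
            c = self.lab_correlation
            lines.append(
                f"cross-lab longevity correlation: Spearman rho = {c.rho:.3f}, "
                f"p = {c.p_value:.3g} (n = {c.n})"
            )
        if self.delta_corr is not None:
            c = self.delta_corr
            lines.append(
                f"cross-lab delta-L correlation: Spearman rho = {c.rho:.3f}, "
                f"p = {c.p_value:.3g} (n = {c.n})"
            )
        return "\n".join(lines)


class DietPairAnalysis:
    """Model-style wrapper running the full DR/AL pair analysis on a table."""

    def __init__(
        self,
        data: pd.DataFrame,
        alpha: float = 0.05,
        duration_col: str = "time_days",
        event_col: str = "event",
    ):
        self.data = data
        self.alpha = alpha
        self.duration_col = duration_col
        self.event_col = event_col

    def fit(self) -> PairAnalysisResults:
        pairs = pair_grid(self.data, self.duration_col, self.event_col)
        summary = summarize_pairs(pairs, alpha=self.alpha)
        labs = sorted(self.data["lab"].astype(str).unique())
        lab_corr = None
        delta_corr_res = None
        if len(labs) == 2:
            try:
                lab_corr = lab_summary_correlation(
                    self.data, (labs[0], labs[1]),
                    duration_col=self.duration_col, event_col=self.event_col,
                )
            except ValueError as exc:
                logger.warning("lab correlation unavailable: %s", exc)
            by_lab = {
                lab: [r for r in pairs if r.lab == lab] for lab in labs
            }
            try:
                delta_corr_res = delta_correlation(by_lab[labs[0]], by_lab[labs[1]])
            except ValueError as exc:
                logger.warning("delta correlation unavailable: %s", exc)
        return PairAnalysisResults(
            pairs=pairs,
            pair_summary=summary,
            lab_correlation=lab_corr,
            delta_corr=delta_corr_res,
        )
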