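"""Likelihood-based covariate-contribution statistic over nested Cox fits.

A full Cox model with all declared covariates is compared against reduced
models that drop one covariate at a time. The drop in maximised log partial
likelihood attributable to covariate X_j, normalised by the sum of all drops,

    contribution(X_j) = (ll_full - ll_reduced,j) / sum_i (ll_full - ll_reduced,i),

apportions the model's explanatory power among the covariates. Cox-Snell
pseudo-R-squared, ``1 - exp((2/n) * (ll_0 - ll))``, is reported for the full
and every reduced model against a common null (beta = 0) so the values are
directly comparable. "Log-likelihood" throughout means the maximised log
PARTIAL likelihood of the Cox fit; ``n`` is the number of subjects (not
events), both configurable conventions documented in docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import CoxPH, CoxPHResults, PHTestResult

__all__ = [
    "cox_snell_r2",
    "contribution",
    "orderings_match",
    "VariancePartition",
    "VariancePartitionResults",
]

#: reduced-model drops more negative than this are treated as fit failures
NEGATIVE_DROP_TOLERANCE = -1e-6


def cox_snell_r2(loglik_null: float, loglik_model: float, n: int) -> float:
    """Cox-Snell pseudo-R-squared, ``1 - exp((2/n)(ll_null - ll_model))``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_model < loglik_null - 1e-8:
        raise ValueError(
            f"loglik_model ({loglik_model}) below loglik_null ({loglik_null}): "
            "models are not nested or a fit failed"
        )
    return float(1.0 - np.exp((2.0 / n) * (loglik_null - max(loglik_model, loglik_null))))


def contribution(drops: dict) -> dict:
    """Normalise per-covariate log-likelihood drops to fractions summing to 1."""
    if not drops:
        raise ValueError("empty drops mapping")
    vals = {k: float(v) for k, v in drops.items()}
    if any(v < 0 for v in vals.values()):
        bad = {k: v for k, v in vals.items() if v < 0}
        raise ValueError(f"drops must be nonnegative, got {bad}")
    total = sum(vals.values())
    if total <= 0:
        raise ValueError(
            "no covariate carries likelihood information (all drops zero)"
        )
    return {k: v / total for k, v in vals.items()}


def orderings_match(recovered, generating, interchangeable=("cohort", "sex")) -> bool:
    """Compare a recovered contribution ordering with a generating one.

    Covariates listed in ``interchangeable`` are treated as swappable: the
    default simulator calibrates the cohort and sex components to comparable
    magnitudes, so their relative order carries no signal and recovery is not
    judged on it.
    """
    swap = set(interchangeable)
    canon = lambda seq: ["~" if c in swap else c for c in seq]
    return canon(list(recovered)) == canon(list(generating))


def _clamp_drop(name: str, drop: float) -> float:
    if drop >= 0:
        return drop
    if drop >= NEGATIVE_DROP_TOLERANCE:
        warnings.warn(
            f"negative log-likelihood drop {drop:.2e} for {name!r} clamped to 0 "
            "(floating-point slack)",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    raise ValueError(
        f"reduced model for {name!r} has HIGHER log-likelihood than the full "
        f"model (drop {drop:.3g}); fits are inconsistent"
    )


@dataclass
class VariancePartitionResults:
    """Per-covariate log-likelihood drops, contributions and pseudo-R2."""

    covariates: list
    loglik_full: float
    loglik_null: float
    loglik_reduced: dict
    drops: dict
    contributions: dict
    r2_full: float
    r2_reduced: dict
    n: int
    n_events: int
    ties: str
    full_fit: CoxPHResults
    ph_diagnostic: PHTestResult | None = None

    def as_frame(self) -> pd.DataFrame:
        """Tabular view, one row per covariate, contributions in percent."""
        return pd.DataFrame(
            {
                "loglik_reduced": [self.loglik_reduced[c] for c in self.covariates],
                "loglik_drop": [self.drops[c] for c in self.covariates],
                "contribution_pct": [
                    100.0 * self.contributions[c] for c in self.covariates
                ],
                "r2_reduced": [self.r2_reduced[c] for c in self.covariates],
            },
            index=pd.Index(self.covariates, name="covariate"),
        )

    def ranking(self) -> list:
        """Covariates sorted by descending contribution."""
        return sorted(self.covariates, key=lambda c: -self.contributions[c])

    def summary(self) -> str:
        frame = self.as_frame()
        lines = [
            "Likelihood-based variance partition (Cox partial likelihood, "
            f"{self.ties} ties)",
            f"n = {self.n}, events = {self.n_events}",
            f"full-model loglik = {self.loglik_full:.3f}, null = {self.loglik_null:.3f}, "
            f"Cox-Snell R2 = {self.r2_full:.4f}",
            "",
            frame.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        if self.ph_diagnostic is not None:
            lines += [
                "",
                "Proportional-hazards diagnostic (full model, "
                f"{self.ph_diagnostic.time_transform} transform): global chi2 = "
                f"{self.ph_diagnostic.global_statistic:.2f} on "
                f"{self.ph_diagnostic.global_df} df, p = {self.ph_diagnostic.global_p:.3g}",
            ]
        return "\n".join(lines)


class VariancePartition:
    """Partition lifespan variance among covariates via nested Cox fits.

    Parameters
    ----------
    data : DataFrame
        Event table (one row per subject).
    covariates : sequence of str
        Covariate columns of the full model; each reduced model drops one.
    ties : {"efron", "breslow"}
    subset : callable or None
        Optional row filter (e.g. restrict to certain cohorts) applied before
        any fitting.
    run_ph_test : bool
        Attach the Schoenfeld-residual diagnostic of the full fit.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        covariates=("lab", "sex", "cohort", "genotype", "diet"),
        duration_col: str = "time_days",
        event_col: str = "event",
        ties: str = "efron",
        subset=None,
        run_ph_test: bool = True,
    ):
        if subset is not None:
            data = data[subset(data)]
        self.data = data.reset_index(drop=True)
        self.covariates = list(covariates)
        if len(self.covariates) < 2:
            raise ValueError("need at least two covariates to partition")
        self.duration_col = duration_col
        self.event_col = event_col
        self.ties = ties
        self.run_ph_test = run_ph_test

    def _fit_one(self, terms, label: str) -> CoxPHResults:
        res = CoxPH(
            self.data,
            terms,
            duration_col=self.duration_col,
            event_col=self.event_col,
            ties=self.ties,
        ).fit()
        if not res.converged:
            raise RuntimeError(f"Cox fit failed to converge for model {label!r}: {res.message}")
        return res

    def fit(self) -> VariancePartitionResults:
        full = self._fit_one(self.covariates, "full")
        n = full.n
        ll_full = full.loglik
        ll_null = full.loglik_null

        ll_red: dict = {}
        drops: dict = {}
        r2_red: dict = {}
        for cov in self.covariates:
            reduced_terms = [c for c in self.covariates if c != cov]
            res = self._fit_one(reduced_terms, f"reduced(-{cov})")
            ll_red[cov] = res.loglik
            drops[cov] = _clamp_drop(cov, ll_full - res.loglik)
            r2_red[cov] = cox_snell_r2(ll_null, res.loglik, n)

        diag = full.test_proportional_hazards() if self.run_ph_test else None
        return VariancePartitionResults(
            covariates=self.covariates,
            loglik_full=ll_full,
            loglik_null=ll_null,
            loglik_reduced=ll_red,
            drops=drops,
            contributions=contribution(drops),
            r2_full=cox_snell_r2(ll_null, ll_full, n),
            r2_reduced=r2_red,
            n=n,
            n_events=full.n_events,
            ties=self.ties,
            full_fit=full,
            ph_diagnostic=diag,
        )
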