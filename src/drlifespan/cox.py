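"""Cox proportional-hazards regression by Newton-Raphson partial likelihood.

The model is semiparametric: covariates act multiplicatively on an unspecified
baseline hazard, ``h(t | x) = h0(t) * exp(x' beta)``, and ``beta`` maximises
the partial likelihood over the risk sets at each death time. Tied death
times are handled by the Efron approximation (default, matching mainstream
survival software) or Breslow's; the two coincide exactly on tie-free data.

The fitting core is fully vectorised: subjects are sorted by time, risk-set
sums of ``w = exp(x'beta)``, ``x*w`` and ``x x' w`` are reverse cumulative
sums, and Efron's within-tie corrections are gathered per death from its tie
group, so datasets of tens of thousands of subjects fit in well under a
second.

Also here: the Grambsch-Therneau proportional-hazards diagnostic — per-term
and global score tests of zero correlation between Schoenfeld residuals and a
transform of event time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kaplan_meier import km_estimate

__all__ = [
    "CoxPH",
    "CoxPHResults",
    "PHTestResult",
    "CollinearityError",
    "cox_fit",
    "ph_test",
]


class CollinearityError(np.linalg.LinAlgError):
    """Raised when the design matrix is rank-deficient, naming the terms."""


@dataclass(frozen=True)
class PHTestResult:
    """Schoenfeld-residual proportional-hazards test.

    ``per_covariate`` is a DataFrame indexed by design column with the score
    statistic (1 df each) and p-value; the global row tests all terms jointly
    with df equal to the number of design columns.
    """

    per_covariate: pd.DataFrame
    global_statistic: float
    global_df: int
    global_p: float
    time_transform: str


class CoxPH:
    """Cox proportional-hazards model on an event table.

    Parameters
    ----------
    data : DataFrame
        One row per subject, containing the duration, event indicator, and
        every model term.
    terms : sequence of str
        Covariate columns. Object/categorical columns are expanded to
        treatment-coded indicators against a reference level (first level in
        sorted order unless overridden); numeric columns enter as-is.
    duration_col, event_col : str
        Column names for time and the 0/1 death indicator.
    ties : {"efron", "breslow"}
        Tied-death handling in the partial likelihood.
    reference_levels : mapping, optional
        ``{term: level}`` overriding the reference level of categorical terms.

    Examples
    --------
    >>> res = CoxPH(df, terms=["lab", "sex", "cohort", "genotype", "diet"]).fit()
    >>> res.params["diet[DR]"]          # doctest: +SKIP
    """

    def __init__(
        self,
        data: pd.DataFrame,
        terms,
        duration_col: str = "time_days",
        event_col: str = "event",
        ties: str = "efron",
        reference_levels=None,
    ):
        if ties not in ("efron", "breslow"):
            raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
        self.terms = list(terms)
        self.duration_col = duration_col
        self.event_col = event_col
        self.ties = ties

        time = np.asarray(data[duration_col], dtype=float)
        event = np.asarray(data[event_col])
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event column must be binary (0/1)")
        event = event.astype(int)
        if np.any(time < 0) or np.any(~np.isfinite(time)):
            raise ValueError("durations must be finite and nonnegative")
        if event.sum() < 1:
            raise ValueError("Cox regression requires at least one death")

        refs = dict(reference_levels or {})
        cols: list[np.ndarray] = []
        names: list[str] = []
        col_term: list[str] = []
        for term in self.terms:
            col = data[term]
            if col.dtype.kind in "OUS" or isinstance(col.dtype, pd.CategoricalDtype):
                levels = sorted(map(str, pd.unique(col.astype(str))))
                if len(levels) < 2:
                    raise ValueError(f"term {term!r} is constant ({levels})")
                ref = str(refs.get(term, levels[0]))
                if ref not in levels:
                    raise ValueError(f"reference level {ref!r} not observed for {term!r}")
                vals = col.astype(str).to_numpy()
                for lev in levels:
                    if lev == ref:
                        continue
                    cols.append((vals == lev).astype(float))
                    names.append(f"{term}[{lev}]")
                    col_term.append(term)
            else:
                v = np.asarray(col, dtype=float)
                if np.ptp(v) == 0:
                    raise ValueError(f"term {term!r} is constant")
                cols.append(v)
                names.append(term)
                col_term.append(term)
        if not cols:
            raise ValueError("no usable model terms")

        X = np.column_stack(cols)
        self.exog_names = names
        self._col_term = col_term

        # sort once by time; risk set at death time t = {i : t_i >= t}
        order = np.argsort(time, kind="stable")
        self._t = time[order]
        self._e = event[order]
        self._X = X[order]
        self.n = time.size
        self.n_events = int(event.sum())
        self._check_rank()
        self._prepare_ties()

    # ------------------------------------------------------------------ setup

    def _check_rank(self) -> None:
        Xc = self._X - self._X.mean(axis=0)
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xc.shape[1]:
            # identify dependent columns via pivoted QR
            from scipy.linalg import qr

            _, r, piv = qr(Xc, mode="economic", pivoting=True)
            diag = np.abs(np.diag(r))
            tol = diag.max() * max(Xc.shape) * np.finfo(float).eps
            bad = [self.exog_names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
            bad += [self.exog_names[p] for p in piv[len(diag):]]
            bad_terms = sorted({self._col_term[self.exog_names.index(b)] for b in bad})
            raise CollinearityError(
                f"design matrix is singular; collinear term(s): {bad_terms} "
                f"(columns {sorted(bad)})"
            )

    def _prepare_ties(self) -> None:
        e = self._e.astype(bool)
        dt = self._t[e]
        uniq, first, counts = np.unique(dt, return_index=True, return_counts=True)
        gid = np.repeat(np.arange(uniq.size), counts)
        self._death_idx = np.nonzero(e)[0]
        self._gid = gid
        self._group_first = first
        self._group_counts = counts
        # fractional Efron weights l/d per death within its tie group
        ranks = np.arange(dt.size) - first[gid]
        self._frac = (
            ranks / counts[gid] if self.ties == "efron" else np.zeros(dt.size)
        )
        # first sorted index belonging to each risk set
        self._risk_start = np.searchsorted(self._t, uniq, side="left")

    # ------------------------------------------------------- likelihood parts

    def _loglik_parts(self, beta: np.ndarray, need_hess: bool = True):
        """Log partial likelihood, score vector and information matrix."""
        X, e = self._X, self._e
        eta = X @ beta
        eta = eta - eta.max()  # guard overflow; cancels in all ratios and in ll via offset
        shift = (X @ beta).max()
        w = np.exp(eta)
        W_rev = np.cumsum(w[::-1])[::-1]
        Xw_rev = np.cumsum((X * w[:, None])[::-1], axis=0)[::-1]

        didx = self._death_idx
        gid = self._gid
        xd = X[didx]
        wd = w[didx]

        # risk-set sums gathered per tie group, then broadcast per death
        RW = W_rev[self._risk_start][gid]
        RXw = Xw_rev[self._risk_start][gid]
        # tie-group sums
        WD = np.add.reduceat(wd, self._group_first)[gid]
        XwD = np.add.reduceat(xd * wd[:, None], self._group_first, axis=0)[gid]

        frac = self._frac
        denom = RW - frac * WD
        num1 = RXw - frac[:, None] * XwD

        ll = float(np.sum(X[didx] @ beta) - np.sum(np.log(denom)) - didx.size * shift)
        # note: log(denom) is in shifted units; add back shift per death
        m = num1 / denom[:, None]
        grad = xd.sum(axis=0) - m.sum(axis=0)

        info = None
        if need_hess:
            XXw = w[:, None, None] * X[:, :, None] * X[:, None, :]
            XXw_rev = np.cumsum(XXw[::-1], axis=0)[::-1]
            RXXw = XXw_rev[self._risk_start][gid]
            XXwD = np.add.reduceat(
                wd[:, None, None] * xd[:, :, None] * xd[:, None, :],
                self._group_first,
                axis=0,
            )[gid]
            num2 = RXXw - frac[:, None, None] * XXwD
            info = np.einsum("kij,k->ij", num2, 1.0 / denom) - np.einsum(
                "ki,kj->ij", m, m
            )
        return ll, grad, info

    def loglik(self, beta) -> float:
        """Log partial likelihood at an arbitrary coefficient vector."""
        beta = np.asarray(beta, dtype=float)
        ll, _, _ = self._loglik_parts(beta, need_hess=False)
        return ll

    # ---------------------------------------------------------------- fitting

    def fit(
        self,
        max_iter: int = 50,
        grad_tol: float = 1e-9,
        loglik_tol: float = 1e-12,
    ) -> "CoxPHResults":
        """Maximise the partial likelihood by Newton-Raphson with step-halving.

        Convergence is declared when the gradient max-norm drops below
        ``grad_tol`` or the relative log-likelihood change falls below
        ``loglik_tol``. Monotone likelihood (perfect separation) is reported
        via ``converged=False`` and a diagnostic message, never silently.
        """
        p = self._X.shape[1]
        beta = np.zeros(p)
        ll, grad, info = self._loglik_parts(beta)
        loglik_null = ll
        converged = False
        message = "did not converge"
        it = 0
        for it in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded earlier
                raise CollinearityError(
                    f"information matrix singular at iteration {it}: {exc}"
                ) from exc
            # step halving until the likelihood does not decrease
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new, grad_new, info_new = self._loglik_parts(cand)
                if ll_new >= ll - 1e-12:
                    break
                scale /= 2.0
            beta, grad, info = cand, grad_new, info_new
            rel_change = abs(ll_new - ll) / (abs(ll) + 1.0)
            ll = ll_new
            if np.max(np.abs(grad)) < grad_tol or rel_change < loglik_tol:
                if np.max(np.abs(beta)) > 10:
                    message = (
                        "monotone partial likelihood suspected (coefficient "
                        f"max |beta| = {np.max(np.abs(beta)):.1f}); estimates "
                        "diverge — check for perfect separation"
                    )
                else:
                    converged = True
                    message = "converged"
                break
        else:
            if np.max(np.abs(beta)) > 10:
                message = (
                    "monotone partial likelihood suspected (perfect separation); "
                    "coefficients diverging after max_iter iterations"
                )
        cov = np.linalg.inv(info)
        return CoxPHResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
            loglik=ll,
            loglik_null=loglik_null,
            converged=converged,
            n_iter=it,
            message=message,
            final_gradient=grad,
        )

    def score_test(self):
        """Score (Rao) test of ``beta = 0``; returns (statistic, df, p).

        With a single binary covariate and Breslow ties this is algebraically
        the two-group log-rank test.
        """
        beta = np.zeros(self._X.shape[1])
        _, grad, info = self._loglik_parts(beta)
        stat = float(grad @ np.linalg.solve(info, grad))
        df = self._X.shape[1]
        return stat, df, float(stats.chi2.sf(stat, df))


class CoxPHResults:
    """Fitted Cox model: coefficients, uncertainty, and diagnostics."""

    def __init__(
        self, model, params, cov_params, loglik, loglik_null, converged, n_iter,
        message, final_gradient,
    ):
        self.model = model
        self.params = params
        self.cov_params = cov_params
        self.loglik = float(loglik)
        self.loglik_null = float(loglik_null)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.message = message
        self.final_gradient = final_gradient
        self.ties = model.ties
        self.n = model.n
        self.n_events = model.n_events

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    def lr_test(self):
        """Likelihood-ratio test of the full model against beta = 0."""
        stat = 2 * (self.loglik - self.loglik_null)
        df = len(self.params)
        return stat, df, float(stats.chi2.sf(stat, df))

    def test_proportional_hazards(self, time_transform: str = "km") -> PHTestResult:
        return ph_test(self, time_transform=time_transform)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Cox proportional hazards (partial likelihood, %s ties)" % self.ties,
            f"n = {self.n}, events = {self.n_events}, "
            f"log-likelihood = {self.loglik:.3f} (null {self.loglik_null:.3f})",
            f"converged: {self.converged} in {self.n_iter} iterations",
            "",
            f"{'term':<22}{'coef':>10}{'exp(coef)':>11}{'se':>9}{'z':>8}"
            f"{'p':>10}{'[0.025':>9}{'0.975]':>9}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<22}{self.params[name]:>10.4f}{np.exp(self.params[name]):>11.4f}"
                f"{self.bse[name]:>9.4f}{self.zvalues[name]:>8.2f}"
                f"{self.pvalues[name]:>10.2g}{ci.loc[name, 'lower']:>9.4f}"
                f"{ci.loc[name, 'upper']:>9.4f}"
            )
        return "\n".join(lines)


def cox_fit(
    data: pd.DataFrame,
    terms,
    duration_col: str = "time_days",
    event_col: str = "event",
    ties: str = "efron",
    reference_levels=None,
    **fit_kwargs,
) -> CoxPHResults:
    """Convenience wrapper: build a :class:`CoxPH` and fit it."""
    return CoxPH(
        data,
        terms,
        duration_col=duration_col,
        event_col=event_col,
        ties=ties,
        reference_levels=reference_levels,
    ).fit(**fit_kwargs)


# --------------------------------------------------------------------- PH test


def _time_transform(model: CoxPH, kind: str) -> np.ndarray:
    death_times = model._t[model._death_idx]
    if kind == "km":
        km = km_estimate(model._t, model._e)
        return 1.0 - km.survival_at(death_times)
    if kind == "identity":
        return death_times.astype(float)
    if kind == "rank":
        return stats.rankdata(death_times)
    raise ValueError(f"unknown time transform {kind!r}")


def ph_test(results: CoxPHResults, time_transform: str = "km") -> PHTestResult:
    """Grambsch-Therneau test of the proportional-hazards assumption.

    Schoenfeld residuals (observed covariate at each death minus the
    risk-set-weighted mean) are correlated against a transform of event time;
    a nonzero correlation indicates a time-varying coefficient. Per-term
    statistics use the scaled residuals; the global statistic pools all terms.
    The Kaplan-Meier transform ``g(t) = 1 - S_KM(t)`` is the default, with
    identity and rank transforms available.
    """
    model = results.model
    p = len(results.params)
    d = model.n_events
    if d <= p:
        raise ValueError(
            f"proportional-hazards test undefined: {d} events for {p} model columns"
        )

    beta = results.params.to_numpy()
    X, w_eta = model._X, np.exp(model._X @ beta - (model._X @ beta).max())
    W_rev = np.cumsum(w_eta[::-1])[::-1]
    Xw_rev = np.cumsum((X * w_eta[:, None])[::-1], axis=0)[::-1]
    gid = model._gid
    # Breslow risk-set mean at each death time (tie-rank-free, well-defined)
    mean = Xw_rev[model._risk_start][gid] / W_rev[model._risk_start][gid][:, None]
    resid = X[model._death_idx] - mean  # Schoenfeld residuals, one per death

    g = _time_transform(model, time_transform)
    g = g - g.mean()
    gg = float(np.sum(g * g))
    if gg <= 0:
        raise ValueError("degenerate time transform (all event times identical)")

    info = np.linalg.inv(results.cov_params.to_numpy())
    u = resid.T @ g  # p-vector
    inv_info_u = results.cov_params.to_numpy() @ u

    global_stat = float(d * (u @ inv_info_u) / gg)
    global_p = float(stats.chi2.sf(global_stat, df=p))

    diag_inv = np.diag(results.cov_params.to_numpy())
    per_stat = d * inv_info_u**2 / (diag_inv * gg)
    per = pd.DataFrame(
        {
            "statistic": per_stat,
            "df": 1,
            "p": stats.chi2.sf(per_stat, df=1),
        },
        index=results.params.index,
    )
    return PHTestResult(
        per_covariate=per,
        global_statistic=global_stat,
        global_df=p,
        global_p=global_p,
        time_transform=time_transform,
    )
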