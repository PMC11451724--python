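"""Cox partial-likelihood fitting: brute-force oracle, ties, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from drlifespan import CollinearityError, CoxPH, cox_fit, simulate_dataset
from tests.conftest import make_survival_frame


def oracle_partial_loglik(beta, time, event, x, ties="efron"):
    """Explicit partial likelihood for one numeric covariate, plain loops."""
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        tied = [i for i in range(len(time)) if time[i] == t and event[i] == 1]
        risk = [i for i in range(len(time)) if time[i] >= t]
        d = len(tied)
        wD = sum(np.exp(beta * x[i]) for i in tied)
        wR = sum(np.exp(beta * x[i]) for i in risk)
        ll += sum(beta * x[i] for i in tied)
        for l in range(d):
            f = l / d if ties == "efron" else 0.0
            ll -= np.log(wR - f * wD)
    return ll


@pytest.fixture
def six_subjects():
    # distinct times, binary covariate
    return make_survival_frame(
        [2.0, 3.0, 5.0, 7.0, 11.0, 13.0],
        [1, 1, 1, 1, 1, 1],
        x=[1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
    )


class TestAgainstBruteForce:
    def test_matches_grid_search_maximum(self, six_subjects):
        df = six_subjects
        res = CoxPH(df, ["x"]).fit()
        grid = np.arange(-4, 4, 1e-4)
        lls = [
            oracle_partial_loglik(b, df.time_days.values, df.event.values, df.x.values)
            for b in grid
        ]
        assert res.params["x"] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)
        assert res.loglik == pytest.approx(max(lls), abs=1e-6)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_loglik_function_matches_oracle_with_ties(self, ties):
        rng = np.random.default_rng(1)
        t = np.array([1.0, 1.0, 2.0, 2.0, 2.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        x = rng.integers(0, 2, 8).astype(float)
        df = make_survival_frame(t, e, x=x)
        model = CoxPH(df, ["x"], ties=ties)
        for beta in (-1.0, -0.3, 0.0, 0.5, 1.7):
            assert model.loglik([beta]) == pytest.approx(
                oracle_partial_loglik(beta, t, e, x, ties), abs=1e-10
            )

    def test_concave_along_line_through_estimate(self, six_subjects):
        model = CoxPH(six_subjects, ["x"])
        bhat = model.fit().params.to_numpy()
        offsets = np.linspace(-2, 2, 41)
        lls = [model.loglik(bhat + o) for o in offsets]
        assert np.argmax(lls) == 20
        assert (np.diff(lls, 2) < 1e-9).all()  # concavity of the 1-d section


class TestProperties:
    def test_identical_groups_force_beta_zero(self):
        # covariate exchangeable by construction -> maximum at exactly 0
        t = [1.0, 4.0, 9.0, 1.0, 4.0, 9.0]
        df = make_survival_frame(t, [1] * 6, g=["a", "a", "a", "b", "b", "b"])
        res = CoxPH(df, ["g"]).fit()
        assert res.params["g[b]"] == pytest.approx(0.0, abs=1e-10)

    def test_loglik_not_below_null(self, small_sim):
        res = cox_fit(small_sim, ["genotype", "diet"])
        assert res.loglik >= res.loglik_null
        assert res.converged
        assert np.max(np.abs(res.final_gradient)) < 1e-9

    def test_efron_equals_breslow_without_ties(self, small_sim):
        sub = small_sim.iloc[:600]
        assert sub["time_days"].nunique() == len(sub)  # continuous times
        ef = cox_fit(sub, ["genotype", "sex"], ties="efron")
        br = cox_fit(sub, ["genotype", "sex"], ties="breslow")
        np.testing.assert_allclose(ef.params, br.params, atol=1e-10)
        assert ef.loglik == pytest.approx(br.loglik, abs=1e-10)

    def test_reference_level_change_preserves_loglik(self, small_sim):
        a = cox_fit(small_sim, ["genotype", "diet"])
        b = cox_fit(
            small_sim,
            ["genotype", "diet"],
            reference_levels={"genotype": "w1118", "diet": "DR"},
        )
        assert a.loglik == pytest.approx(b.loglik, abs=1e-8)
        # hazard ratio between two genotypes is reparameterization-invariant
        hr_a = a.params["genotype[wDahomey]"] - a.params["genotype[Oregon-R]"]
        hr_b = b.params["genotype[wDahomey]"] - b.params["genotype[Oregon-R]"]
        assert hr_a == pytest.approx(hr_b, abs=1e-6)

    def test_perfect_separation_flagged_not_silent(self):
        # group a always dies first: monotone likelihood, beta -> -inf
        df = make_survival_frame(
            [1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0],
            [1] * 8,
            g=["a"] * 4 + ["b"] * 4,
        )
        res = CoxPH(df, ["g"]).fit()
        assert not res.converged
        assert "separation" in res.message or "monotone" in res.message

    def test_collinear_terms_raise_naming_terms(self, small_sim):
        df = small_sim.copy()
        df["diet_copy"] = df["diet"]
        with pytest.raises(CollinearityError, match="diet"):
            CoxPH(df, ["diet", "diet_copy"])

    def test_constant_term_rejected(self, small_sim):
        df = small_sim[small_sim.diet == "DR"]
        with pytest.raises(ValueError, match="constant"):
            CoxPH(df, ["diet"])


class TestAgainstLifelines:
    def test_coefficients_standard_errors_and_loglik(self, small_sim):
        from lifelines import CoxPHFitter

        terms = ["lab", "sex", "cohort", "genotype", "diet"]
        res = cox_fit(small_sim, terms)
        X = pd.get_dummies(small_sim[terms], drop_first=True).astype(float)
        X.columns = [c.replace("_", "[", 1) + "]" for c in X.columns]
        X["T"], X["E"] = small_sim.time_days, small_sim.event
        cph = CoxPHFitter().fit(X, "T", "E")
        assert res.loglik == pytest.approx(cph.log_likelihood_, rel=1e-9)
        np.testing.assert_allclose(
            res.params[cph.params_.index], cph.params_, atol=1e-5
        )
        np.testing.assert_allclose(
            res.bse[cph.standard_errors_.index], cph.standard_errors_, atol=1e-5
        )

    def test_efron_ties_match_lifelines_on_tied_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(6)
        t = np.ceil(rng.exponential(15, 150))  # heavy ties on an integer grid
        e = rng.integers(0, 2, 150)
        e[:5] = 1
        x = rng.normal(size=150)
        df = make_survival_frame(t, e, x=x)
        res = CoxPH(df, ["x"], ties="efron").fit()
        cph = CoxPHFitter().fit(df.rename(columns={"time_days": "T", "event": "E"}), "T", "E")
        assert res.params["x"] == pytest.approx(cph.params_["x"], abs=1e-7)
        assert res.loglik == pytest.approx(cph.log_likelihood_, rel=1e-10)


def test_diet_effect_recovery_across_seeds():
    """Known diet log-hazard recovered within 3 SE in >=90% of seeds."""
    hits = 0
    n_seeds = 40
    for seed in range(n_seeds):
        df = simulate_dataset(
            seed=seed,
            flies_per_cell=31,  # ~4,000 flies
            cohort_frailty_sd=0.0,
            beta={"diet": {"AL": 0.0, "DR": 0.3}},
        )
        res = cox_fit(df, ["diet"])
        hits += abs(res.params["diet[DR]"] - 0.3) < 3 * res.bse["diet[DR]"]
    assert hits >= 0.9 * n_seeds


def test_summary_renders_all_terms(small_sim):
    res = cox_fit(small_sim, ["genotype", "diet"])
    text = res.summary()
    assert "diet[DR]" in text and "genotype[wDahomey]" in text
    assert "converged: True" in text
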