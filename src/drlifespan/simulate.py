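"""Synthetic right-censored lifespan data with a two-lab factorial design.

The generator emulates the structure of a multi-laboratory dietary-restriction
(DR) experiment in *Drosophila melanogaster*: two labs each run four cohorts of
four genotypes, both sexes, with flies randomised onto a restricted (DR) or a
high-nutrient ("AL") medium, ~25 flies per vial. Individual lifespans follow a
Gompertz mortality law — hazard ``a * exp(b*t)`` — with covariates acting
multiplicatively on the baseline scale ``a`` (i.e. additively on the log
hazard), cohort-level random "stochasticity" frailty, and sporadic
covariate-independent right censoring (food-quality losses).

The cohort frailty has two components: a normal intercept drawn once per
cohort and SHARED between labs (cohorts differ by protocol and mating diet,
attributes common to both labs — which is also why a real two-lab study can
see large cohort variance alongside tiny lab variance), plus an optional
independent per-(lab, cohort) run effect for within-lab repeat variability
(default off). Ground truth for recovery tests is exposed by
:func:`realized_frailty` and :func:`realized_variance_components`.

Default effect sizes encode the hierarchy the downstream variance partition is
meant to recover: genotype effects dominate (spanning ~0.85 on the log
hazard), cohort frailty and sex are intermediate, lab is small and diet is
smallest (~0.07, i.e. a percent-scale shift in median lifespan).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationParams",
    "sample_gompertz",
    "simulate_dataset",
    "realized_frailty",
    "realized_variance_components",
]

#: Column order of the event table every stage of the pipeline consumes.
EVENT_COLUMNS = [
    "fly_id",
    "lab",
    "cohort",
    "genotype",
    "sex",
    "diet",
    "vial",
    "time_days",
    "event",
]

DEFAULT_GENOTYPES = ("Canton-S", "Oregon-R", "w1118", "wDahomey")


def _default_beta() -> dict:
    # log-hazard offsets per covariate level; reference levels carry 0.0.
    # Positive values shorten life (higher hazard).
    return {
        "genotype": {
            "Canton-S": -0.30,
            "Oregon-R": -0.40,
            "w1118": 0.35,
            "wDahomey": 0.45,
        },
        "sex": {"F": 0.0, "M": 0.25},
        "lab": {"lab1": 0.0, "lab2": 0.14},
        "diet": {"AL": 0.0, "DR": -0.07},
    }


@dataclass
class SimulationParams:
    """Design and mortality parameters of one simulated experiment.

    Parameters
    ----------
    n_labs, n_cohorts : int
        Factorial design dimensions; labs are labelled ``lab1..labN`` and
        cohorts ``1..M``.
    genotypes, sexes, diets : sequence of str
        Remaining design factors.
    flies_per_cell : int
        Flies per lab x cohort x genotype x sex x diet cell. The default 125
        gives 2*4*4*2*2*125 = 16,000 flies, matching the scale of a two-lab
        study with ~300 flies per genotype/sex/lab arm split over two diets.
    vial_size : int
        Flies per vial; vial ids are assigned round-robin within a cell and
        carry no simulated effect.
    gompertz_a, gompertz_b : float
        Baseline Gompertz hazard ``a * exp(b*t)`` (per day). The defaults put
        the baseline median near 54 days so that, with covariate effects, all
        stratum medians fall in a 40-70 day envelope.
    beta : mapping
        ``{term: {level: log-hazard offset}}``. Missing levels default to 0.
    cohort_frailty_sd : float
        Standard deviation of the normal log-hazard intercept drawn once per
        cohort and shared between labs (cohort "stochasticity"). See
        docs/methods.md for sizing rationale.
    lab_cohort_frailty_sd : float
        Standard deviation of an additional independent normal intercept per
        (lab, cohort), modelling within-lab run-to-run variation. Default 0:
        a nonzero value leaks cohort randomness into the lab contrast, which
        is realistic but makes the lab contribution itself stochastic.
    censor_rate : float
        Per-fly probability of independent right censoring; a censored fly's
        recorded time is uniform on (0, its latent death time).
    seed : int
        Root RNG seed; every (lab, cohort, ...) cell uses a deterministic
        substream so cell draws are stable under design changes elsewhere.
    """

    n_labs: int = 2
    n_cohorts: int = 4
    genotypes: Sequence[str] = DEFAULT_GENOTYPES
    sexes: Sequence[str] = ("F", "M")
    diets: Sequence[str] = ("DR", "AL")
    flies_per_cell: int = 125
    vial_size: int = 25
    gompertz_a: float = 3.0e-4
    gompertz_b: float = 0.1
    beta: Mapping[str, Mapping[str, float]] = field(default_factory=_default_beta)
    cohort_frailty_sd: float = 0.25
    lab_cohort_frailty_sd: float = 0.0
    censor_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_labs", "n_cohorts", "flies_per_cell", "vial_size"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not self.gompertz_a > 0:
            raise ValueError(f"gompertz_a must be > 0, got {self.gompertz_a!r}")
        if not self.gompertz_b > 0:
            raise ValueError(f"gompertz_b must be > 0, got {self.gompertz_b!r}")
        if not 0 <= self.censor_rate < 1:
            raise ValueError(f"censor_rate must be in [0, 1), got {self.censor_rate!r}")
        if self.cohort_frailty_sd < 0:
            raise ValueError("cohort_frailty_sd must be >= 0")
        if self.lab_cohort_frailty_sd < 0:
            raise ValueError("lab_cohort_frailty_sd must be >= 0")
        for name in ("genotypes", "sexes", "diets"):
            levels = list(getattr(self, name))
            if not levels:
                raise ValueError(f"{name} must be non-empty")
            if len(set(levels)) != len(levels):
                raise ValueError(f"{name} contains duplicate labels")
        unknown = set(self.beta) - {"genotype", "sex", "lab", "diet"}
        if unknown:
            raise ValueError(f"beta keys must be design terms, got extras {sorted(unknown)}")

    @property
    def labs(self) -> list[str]:
        return [f"lab{i + 1}" for i in range(self.n_labs)]

    @property
    def cohorts(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_cohorts)]

    @property
    def n_records(self) -> int:
        return (
            self.n_labs
            * self.n_cohorts
            * len(self.genotypes)
            * len(self.sexes)
            * len(self.diets)
            * self.flies_per_cell
        )

    def effect(self, term: str, level: str) -> float:
        return float(self.beta.get(term, {}).get(level, 0.0))

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation parameter(s): {sorted(unknown)}")
        return cls(**dict(d))


def sample_gompertz(a: float, b: float, u) -> np.ndarray | float:
    """Inverse-CDF draw(s) from a Gompertz lifetime with hazard ``a*exp(b*t)``.

    The survival function is ``S(t) = exp(-(a/b) * (exp(b*t) - 1))``; setting
    ``S(t) = u`` and solving gives ``t = (1/b) * log(1 - (b/a) * log(u))``.

    Parameters
    ----------
    a, b : float
        Hazard scale and exponential rate, both strictly positive.
    u : float or array
        Uniform variate(s) in the open interval (0, 1), interpreted as the
        survival probability at the returned time.
    """
    if not (a > 0 and b > 0):
        raise ValueError(f"Gompertz parameters must be positive, got a={a!r}, b={b!r}")
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0) or np.any(u_arr >= 1):
        raise ValueError("u must lie strictly inside (0, 1)")
    t = np.log1p(-(b / a) * np.log(u_arr)) / b
    return t if np.ndim(u) else float(t)


def _cell_rng(seed: int, *key: int) -> np.random.Generator:
    # Deterministic substream per design cell: stable when other cells change.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def realized_frailty(params: SimulationParams) -> dict:
    """The frailty intercepts a given parameter set actually draws.

    Returns ``{(lab, cohort): value}`` where each value is the shared cohort
    intercept plus the (lab, cohort) run effect. Deterministic in the seed —
    this is the generator's ground truth, usable by recovery tests.
    """
    out: dict = {}
    for ci, cohort in enumerate(params.cohorts):
        u = (
            _cell_rng(params.seed, 0, ci).normal(0.0, params.cohort_frailty_sd)
            if params.cohort_frailty_sd > 0
            else 0.0
        )
        for li, lab in enumerate(params.labs):
            v = (
                _cell_rng(params.seed, 2, li, ci).normal(
                    0.0, params.lab_cohort_frailty_sd
                )
                if params.lab_cohort_frailty_sd > 0
                else 0.0
            )
            out[(lab, cohort)] = u + v
    return out


def realized_variance_components(params: SimulationParams) -> dict:
    """Population log-hazard variance each covariate induces, given the seed.

    For the balanced factorial design, each main effect contributes the
    population variance of its level values (equal level weights). The lab
    component includes the lab-mean of the realised frailty (a run effect
    shared by every fly in a lab biases the lab contrast); the cohort
    component is the variance of cohort-mean frailty. Normalising these
    variances gives the generating analogue of the fitted contribution
    statistic, so the realised ordering — not just the expected one — is
    available as ground truth.
    """
    frailty = realized_frailty(params)

    def level_var(values) -> float:
        v = np.asarray(values, dtype=float)
        return float(np.mean((v - v.mean()) ** 2))

    lab_effects = [
        params.effect("lab", lab)
        + np.mean([frailty[(lab, c)] for c in params.cohorts])
        for lab in params.labs
    ]
    cohort_effects = [
        np.mean([frailty[(lab, c)] for lab in params.labs]) for c in params.cohorts
    ]
    return {
        "genotype": level_var([params.effect("genotype", g) for g in params.genotypes]),
        "sex": level_var([params.effect("sex", s) for s in params.sexes]),
        "diet": level_var([params.effect("diet", d) for d in params.diets]),
        "lab": level_var(lab_effects),
        "cohort": level_var(cohort_effects),
    }


def simulate_dataset(params: SimulationParams | None = None, **overrides) -> pd.DataFrame:
    """Simulate one full factorial lifespan experiment.

    Returns a :class:`pandas.DataFrame` with one row per fly and columns
    ``fly_id, lab, cohort, genotype, sex, diet, vial, time_days, event``
    (event 1 = observed death, 0 = right-censored). Identical parameters
    (including the seed) produce a bit-identical frame.
    """
    if params is None:
        params = SimulationParams(**overrides)
    elif overrides:
        params = params.replace(**overrides)

    log_a = np.log(params.gompertz_a)
    b = params.gompertz_b
    frailty_map = realized_frailty(params)
    frames: list[pd.DataFrame] = []

    for li, lab in enumerate(params.labs):
        for ci, cohort in enumerate(params.cohorts):
            frailty = frailty_map[(lab, cohort)]
            for gi, genotype in enumerate(params.genotypes):
                for si, sex in enumerate(params.sexes):
                    for di, diet in enumerate(params.diets):
                        rng = _cell_rng(params.seed, 1, li, ci, gi, si, di)
                        eta = (
                            params.effect("genotype", genotype)
                            + params.effect("sex", sex)
                            + params.effect("lab", lab)
                            + params.effect("diet", diet)
                            + frailty
                        )
                        a_cell = np.exp(log_a + eta)
                        n = params.flies_per_cell
                        u = rng.uniform(size=n)
                        # uniform() is [0,1); reflect to (0,1] and keep off 1
                        s = np.clip(1.0 - u, None, 1.0 - 1e-16)
                        t = sample_gompertz(a_cell, b, s)
                        censored = rng.uniform(size=n) < params.censor_rate
                        obs = np.where(censored, rng.uniform(size=n) * t, t)
                        prefix = f"{lab}-c{cohort}-{genotype}-{sex}-{diet}"
                        idx = np.arange(n)
                        frames.append(
                            pd.DataFrame(
                                {
                                    "fly_id": [f"{prefix}-{i:04d}" for i in idx],
                                    "lab": lab,
                                    "cohort": cohort,
                                    "genotype": genotype,
                                    "sex": sex,
                                    "diet": diet,
                                    "vial": [
                                        f"{prefix}-v{i // params.vial_size:02d}" for i in idx
                                    ],
                                    "time_days": obs,
                                    "event": np.where(censored, 0, 1).astype(np.int64),
                                }
                            )
                        )

    out = pd.concat(frames, ignore_index=True)
    return out[EVENT_COLUMNS]
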