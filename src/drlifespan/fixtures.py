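"""Packaged reference data.

``table3_logrank.csv`` transcribes the published per-pair log-rank grid of a
two-laboratory *Drosophila* dietary-restriction study (the study design this
package's simulator emulates): 64 (lab, cohort, genotype, sex) strata, each
with the log-rank p-value of its DR-vs-AL comparison and, for pairs passing
the Bonferroni threshold 0.05/64, the longer-lived arm. Labs are anonymised
to ``lab1``/``lab2``. The fixture lets the significance-counting machinery be
exercised against published tallies without any raw survival data.

The study-scale constants record the published per-lab fly counts.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .pairs import PairResult

__all__ = [
    "load_table3",
    "table3_pair_results",
    "STUDY_FLIES_PER_LAB",
    "STUDY_N_PAIRS",
]

#: published number of flies contributed by each laboratory
STUDY_FLIES_PER_LAB = {"lab1": 8475, "lab2": 7460}
#: published number of DR/AL comparison pairs (survival-curve pairs / 2)
STUDY_N_PAIRS = 64


def load_table3() -> pd.DataFrame:
    """The 64-entry log-rank grid as a DataFrame.

    Columns: lab, cohort, genotype, sex, p_value, direction (empty string for
    pairs the study did not flag as significant).
    """
    ref = resources.files("drlifespan.data").joinpath("table3_logrank.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["p_value"] = df["p_value"].astype(float)
    if len(df) != STUDY_N_PAIRS:
        raise RuntimeError(f"fixture corrupted: expected {STUDY_N_PAIRS} rows, got {len(df)}")
    if not ((df["p_value"] > 0) & (df["p_value"] <= 1)).all():
        raise RuntimeError("fixture corrupted: p-values outside (0, 1]")
    if not df["direction"].isin(["", "DR", "AL"]).all():
        raise RuntimeError("fixture corrupted: bad direction labels")
    return df


def table3_pair_results() -> list[PairResult]:
    """The fixture as :class:`~drlifespan.pairs.PairResult` objects.

    Medians are unavailable in the published grid, so ``median_dr``,
    ``median_al`` and ``delta_l`` are NaN and the direction comes from the
    published longer-lived labels ("none" where no label was printed).
    """
    df = load_table3()
    return [
        PairResult(
            lab=row.lab,
            cohort=row.cohort,
            genotype=row.genotype,
            sex=row.sex,
            p_value=float(row.p_value),
            direction=row.direction if row.direction else "none",
        )
        for row in df.itertuples()
    ]
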