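"""End-to-end report bundle: variance partition + DR/AL pair grid.

``run_report`` orchestrates the full analysis on one event table and writes a
deterministic bundle: a variance-partition table per cohort subset (all
cohorts; cohorts 1-3; cohorts 1 and 3 — the protocol-controlled subsets of
the emulated design), the pair grid as a wide TSV, JSON summaries, and a run
log recording every threshold, tolerance and tie-method used, sufficient to
reproduce the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EventTable
from .pairs import DietPairAnalysis
from .partition import VariancePartition, VariancePartitionResults

__all__ = ["ReportConfig", "run_report", "DEFAULT_SUBSETS"]

DEFAULT_SUBSETS = {
    "all": None,
    "c123": ("1", "2", "3"),
    "c13": ("1", "3"),
}


@dataclass
class ReportConfig:
    covariates: tuple = ("lab", "sex", "cohort", "genotype", "diet")
    subsets: dict = field(default_factory=lambda: dict(DEFAULT_SUBSETS))
    alpha: float = 0.05
    ties: str = "efron"
    run_ph_test: bool = True

    @classmethod
    def from_dict(cls, d: dict | None) -> "ReportConfig":
        if not d:
            return cls()
        known = {"covariates", "subsets", "alpha", "ties", "run_ph_test"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown report config key(s): {sorted(unknown)}")
        d = dict(d)
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(obj), sort_keys=True, indent=2) + "\n")


def _partition_json(res: VariancePartitionResults) -> dict:
    return {
        "covariates": list(res.covariates),
        "loglik_full": res.loglik_full,
        "loglik_null": res.loglik_null,
        "loglik_reduced": res.loglik_reduced,
        "drops": res.drops,
        "contribution_pct": {c: 100.0 * v for c, v in res.contributions.items()},
        "r2_full": res.r2_full,
        "r2_reduced": res.r2_reduced,
        "n": res.n,
        "n_events": res.n_events,
        "ph_global_p": None if res.ph_diagnostic is None else res.ph_diagnostic.global_p,
    }


def _pairs_wide(pair_frame: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Wide layout: rows genotype x sex, columns lab x cohort."""
    df = pair_frame.copy()

    def cell(row):
        p = row.p_value
        if not np.isfinite(p):
            return "NA"
        txt = f"{p:.3g}"
        if p <= threshold and row.direction in ("DR", "AL"):
            txt += f" ({row.direction})"
        return txt

    df["cell"] = [cell(r) for r in df.itertuples()]
    wide = df.pivot_table(
        index=["genotype", "sex"],
        columns=["lab", "cohort"],
        values="cell",
        aggfunc="first",
    ).sort_index()
    wide.columns = [f"{lab}_c{cohort}" for lab, cohort in wide.columns]
    return wide


def run_report(
    table: EventTable | pd.DataFrame,
    out_dir,
    config: ReportConfig | dict | None = None,
) -> dict:
    """Run the full pipeline and write the report bundle to ``out_dir``.

    Returns a dict of output paths keyed by artifact name. Running twice on
    identical input produces byte-identical files.
    """
    cfg = config if isinstance(config, ReportConfig) else ReportConfig.from_dict(config)
    data = table.data if isinstance(table, EventTable) else table
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {}

    # --- variance partition per cohort subset
    partition_json: dict = {}
    pct_cols: dict = {}
    for name, cohorts in cfg.subsets.items():
        subset = None if cohorts is None else (
            lambda df, c=tuple(map(str, cohorts)): df["cohort"].astype(str).isin(c)
        )
        sub_data = data if subset is None else data[subset(data)]
        present = set(sub_data["cohort"].astype(str).unique())
        covs = [
            c for c in cfg.covariates
            if sub_data[c].astype(str).nunique() > 1
        ]
        res = VariancePartition(
            sub_data, covariates=covs, ties=cfg.ties, run_ph_test=cfg.run_ph_test
        ).fit()
        partition_json[name] = _partition_json(res)
        pct_cols[name] = {
            c: 100.0 * res.contributions.get(c, np.nan) for c in cfg.covariates
        }

    combined = pd.DataFrame(pct_cols).reindex(list(cfg.covariates))
    combined.index.name = "covariate"
    p = out / "partition.tsv"
    combined.to_csv(p, sep="\t", float_format="%.4f")
    paths["partition_tsv"] = p
    p = out / "partition.json"
    _dump_json(partition_json, p)
    paths["partition_json"] = p

    # --- pair grid
    pair_res = DietPairAnalysis(data, alpha=cfg.alpha).fit()
    frame = pair_res.as_frame()
    wide = _pairs_wide(frame, pair_res.pair_summary.bonferroni_threshold)
    p = out / "pairs.tsv"
    wide.to_csv(p, sep="\t")
    paths["pairs_tsv"] = p
    p = out / "pairs_long.tsv"
    frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths["pairs_long_tsv"] = p

    summary = pair_res.pair_summary.to_dict()
    if pair_res.lab_correlation is not None:
        summary["lab_correlation"] = vars(pair_res.lab_correlation)
    if pair_res.delta_corr is not None:
        summary["delta_correlation"] = vars(pair_res.delta_corr)
    p = out / "pair_summary.json"
    _dump_json(summary, p)
    paths["pair_summary_json"] = p

    # --- run log: everything needed to reproduce the run
    meta = table.metadata if isinstance(table, EventTable) else {}
    log = {
        "n_records": int(len(data)),
        "covariates": list(cfg.covariates),
        "subsets": {k: (None if v is None else list(v)) for k, v in cfg.subsets.items()},
        "alpha_family": cfg.alpha,
        "bonferroni_threshold": pair_res.pair_summary.bonferroni_threshold,
        "n_pairs": pair_res.pair_summary.n_pairs,
        "ties_method": cfg.ties,
        "cox_convergence": {"max_iter": 50, "grad_tol": 1e-9, "loglik_tol": 1e-12},
        "ph_time_transform": "km",
        "input_metadata": _jsonable(meta),
    }
    p = out / "run_log.json"
    _dump_json(log, p)
    paths["run_log_json"] = p
    return paths
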