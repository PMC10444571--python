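"""Experiment orchestration and descriptive reporting.

Reproduces the figure-level comparisons of the study design: paired
baseline/condition simulations on matched networks, per-network feature
tables (NBR, NBD, PSIB, MFR), features normalized against the matched-seed
baseline, and mean ± SEM summaries per condition.  Inferential statistics are
deliberately out of scope — the report is descriptive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import (
    ConditionSpec,
    SimulationConfig,
    SimulationResult,
    run_simulation,
)
from .mea_analysis import AnalysisParams, analyze_result
from .params import RateModifier

FEATURES = ("NBR", "NBD", "PSIB", "MFR")


@dataclass
class ExperimentReport:
    """Per-network features, matched-baseline normalization and summaries."""

    table: pd.DataFrame        # condition, network, seed, NBR, NBD, PSIB, MFR
    normalized: pd.DataFrame   # condition, network, norm_NBR, norm_NBD, norm_PSIB, norm_MFR
    summary: pd.DataFrame      # per condition: mean and SEM of each feature

    def to_json_summary(self) -> str:
        out: dict = {}
        for cond, grp in self.summary.groupby("condition"):
            row = grp.iloc[0].to_dict()
            row.pop("condition", None)
            out[cond] = {
                k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in row.items()
            }
        return json.dumps(out, indent=2)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "features.csv", index=False)
        self.normalized.to_csv(out / "normalized.csv", index=False)
        (out / "summary.json").write_text(self.to_json_summary())


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def feature_row(result: SimulationResult,
                params: AnalysisParams = AnalysisParams()) -> dict:
    fv = analyze_result(result, params)
    return {
        "condition": result.condition,
        "network": result.network_id,
        "seed": result.seed,
        "NBR": fv.NBR,
        "NBD": fv.NBD,
        "PSIB": fv.PSIB,
        "MFR": fv.MFR,
        "n_spikes": int(len(result.spike_times)),  # simulator ground truth
    }


def feature_table(results, params: AnalysisParams = AnalysisParams()) -> pd.DataFrame:
    """One row of burst features per simulation result."""
    return pd.DataFrame([feature_row(r, params) for r in results])


def normalize_to_baseline(table: pd.DataFrame) -> pd.DataFrame:
    """Per-network features divided by the matched-seed control features.

    Rows lacking a matched control network are dropped; divisions by zero or
    by a missing baseline value yield NaN.
    """
    base = table[table["condition"] == "control"].set_index("network")
    rows = []
    for _, r in table[table["condition"] != "control"].iterrows():
        if r["network"] not in base.index:
            continue
        b = base.loc[r["network"]]
        row = {"condition": r["condition"], "network": r["network"]}
        for f in FEATURES:
            denom = b[f]
            row[f"norm_{f}"] = (
                r[f] / denom if np.isfinite(denom) and denom != 0 else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM per condition (SEM is NaN for single-network conditions)."""
    rows = []
    for cond, grp in table.groupby("condition", sort=False):
        row = {"condition": cond, "n": len(grp)}
        for f in FEATURES:
            vals = grp[f].to_numpy(dtype=float)
            good = vals[~np.isnan(vals)]
            row[f"{f}_mean"] = float(np.mean(good)) if len(good) else float("nan")
            row[f"{f}_sem"] = _sem(vals)
        rows.append(row)
    return pd.DataFrame(rows)


def run_experiment(
    config: SimulationConfig,
    conditions: list[str],
    n_networks: int | None = None,
    modifier: RateModifier | None = None,
    ds_overrides: dict | None = None,
    analysis: AnalysisParams = AnalysisParams(),
    keep_results: bool = False,
) -> ExperimentReport | tuple[ExperimentReport, dict]:
    """Paired baseline + condition experiment on matched networks.

    Every condition (plus the implicit ``control`` baseline) is simulated on
    the same ``n_networks`` network realizations; features are normalized
    network-by-network against the control run.
    """
    n = n_networks if n_networks is not None else config.n_networks
    names = ["control"] + [c for c in conditions if c != "control"]
    results: dict[str, list[SimulationResult]] = {}
    for name in names:
        cond = ConditionSpec.from_name(name, modifier=modifier, ds_overrides=ds_overrides)
        cfg = replace(config, condition=cond)
        results[name] = [run_simulation(cfg, network_id=i) for i in range(n)]

    table = feature_table([r for rs in results.values() for r in rs], analysis)
    report = ExperimentReport(
        table=table,
        normalized=normalize_to_baseline(table),
        summary=summarize(table),
    )
    if keep_results:
        return report, results
    return report
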