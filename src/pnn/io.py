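"""Dataset, score-table and model readers/writers plus run configuration.

CSV is the canonical tabular format and JSON the model/solve-log format.
Every artifact written embeds the configuration and seed that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counterfactual import CounterfactualTable
from .network import ObservationalDataset, TreatmentSet
from .simulate import SimulatedDataset

__all__ = [
    "load_dataset",
    "write_dataset",
    "write_simulated",
    "load_simulated",
    "write_table",
    "load_table",
    "load_run_config",
]


def load_dataset(
    path,
    feature_cols: list[str] | None = None,
    treatment_col: str = "treatment",
    outcome_col: str = "outcome",
    direction: str = "maximize",
    treatment_order: list | None = None,
) -> ObservationalDataset:
    """Read a delimited observational dataset with validation.

    When ``feature_cols`` is omitted, every column other than the treatment
    and outcome columns is treated as a numeric feature.  Rows with missing
    values are rejected with their row numbers reported.
    """
    frame = pd.read_csv(path)
    for col in (treatment_col, outcome_col):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    if feature_cols is None:
        feature_cols = [c for c in frame.columns if c not in (treatment_col, outcome_col)]
    missing = [c for c in feature_cols if c not in frame.columns]
    if missing:
        raise ValueError(f"missing feature column(s) {missing} in {path}")
    if not feature_cols:
        raise ValueError("no feature columns found")
    bad_rows = frame.index[frame[feature_cols + [outcome_col]].isna().any(axis=1)
                           | frame[treatment_col].isna()]
    if len(bad_rows):
        raise ValueError(
            f"rows with missing values (0-based): {bad_rows.tolist()[:20]}"
        )
    feats = frame[feature_cols]
    non_numeric = [c for c in feature_cols
                   if not np.issubdtype(feats[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric feature column(s): {non_numeric}")
    ts = TreatmentSet(tuple(treatment_order)) if treatment_order is not None else None
    return ObservationalDataset(
        covariates=feats.to_numpy(dtype=float),
        treatments=frame[treatment_col].to_numpy(),
        outcomes=frame[outcome_col].to_numpy(dtype=float),
        direction=direction,
        treatment_set=ts,
    )


def _frame_of(data: ObservationalDataset) -> pd.DataFrame:
    cols = {f"feature_{d + 1}": data.covariates[:, d] for d in range(data.n_features)}
    cols["treatment"] = data.treatments
    cols["outcome"] = data.outcomes
    return pd.DataFrame(cols)


def write_dataset(data: ObservationalDataset, path) -> None:
    _frame_of(data).to_csv(path, index=False)


def write_simulated(sim: SimulatedDataset, path, sidecar_path) -> None:
    """Write observational rows plus the counterfactual side-car CSV."""
    write_dataset(sim.data, path)
    pd.DataFrame(
        {
            "outcome_t0": sim.potential_outcomes[:, 0],
            "outcome_t1": sim.potential_outcomes[:, 1],
            "optimal_treatment": sim.optimal_treatment,
        }
    ).to_csv(sidecar_path, index=False)


def load_simulated(path, sidecar_path) -> SimulatedDataset:
    data = load_dataset(path, treatment_order=[0, 1])
    side = pd.read_csv(sidecar_path)
    return SimulatedDataset(
        data=data,
        potential_outcomes=side[["outcome_t0", "outcome_t1"]].to_numpy(dtype=float),
        optimal_treatment=side["optimal_treatment"].to_numpy(dtype=np.intp),
    )


def write_table(table: CounterfactualTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def load_table(path, method: str = "dr", clip_floor: float = 0.01) -> CounterfactualTable:
    return CounterfactualTable.from_frame(pd.read_csv(path), method=method, clip_floor=clip_floor)


def load_run_config(path) -> dict:
    """Load a YAML or JSON run configuration into a flat dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a mapping")
    return cfg
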