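"""Readers and writers for the delimited-text interchange formats.

Two table shapes travel between stages: a parameter table (one row per
genotype × day condition, one column per kinetic parameter, canonical
names in the header) and an observation table in long format
(condition, measure, value, dispersion, unit). Both have JSON
equivalents. All delimited text is UTF-8, comma-separated, '.' decimal.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .calibration import ConditionObservations
from .kinetic_model import (
    PARAMETER_NAMES,
    STATE_NAMES,
    ConditionRealization,
    KineticParameters,
    ValidationError,
    find_steady_state,
)

_META_COLS = ("genotype", "day")


def write_parameter_table(realizations_or_df, path) -> None:
    """Write a parameter table (CSV or .json by extension)."""
    if isinstance(realizations_or_df, pd.DataFrame):
        df = realizations_or_df
    else:
        df = pd.DataFrame(
            [{"genotype": r.genotype, "day": r.day, **r.params.as_dict()}
             for r in realizations_or_df]
        )
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        df.to_csv(path, index=False)


def read_parameter_table(path) -> pd.DataFrame:
    """Read and validate a parameter table; raises on missing columns
    or out-of-range values, naming the offending column."""
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    missing = [c for c in (*_META_COLS, *PARAMETER_NAMES) if c not in df.columns]
    if missing:
        raise ValidationError(f"parameter table missing column(s): {missing}")
    for _, row in df.iterrows():
        KineticParameters(**{p: float(row[p]) for p in PARAMETER_NAMES})
    return df


def realizations_from_table(
    df: pd.DataFrame,
    mode: str = "scheme-consistent",
    tol: float = 1e-9,
) -> list[ConditionRealization]:
    """Solve each table row to steady state, returning condition
    realizations in row order."""
    out = []
    for _, row in df.iterrows():
        params = KineticParameters(**{p: float(row[p]) for p in PARAMETER_NAMES})
        ss = find_steady_state(params, mode=mode, tol=tol)
        out.append(ConditionRealization(
            genotype=str(row["genotype"]), day=int(row["day"]),
            params=params, steady_state=ss, mode=mode,
        ))
    return out


def write_observation_table(observations: dict[str, ConditionObservations], path) -> None:
    rows = []
    for cond, obs in observations.items():
        for name, (v, s) in obs.concentrations.items():
            rows.append({"condition": cond, "measure": name, "value": v,
                         "dispersion": s, "unit": "umol_gDW-1"})
        for name, (v, s) in obs.flux_targets.items():
            rows.append({"condition": cond, "measure": name, "value": v,
                         "dispersion": s, "unit": "umol_gDW-1_h-1"})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_observation_table(path) -> dict[str, ConditionObservations]:
    df = pd.read_csv(path)
    required = {"condition", "measure", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"observation table missing column(s): {sorted(missing)}")
    if "dispersion" not in df.columns:
        df["dispersion"] = 0.1
    out = {}
    for cond, grp in df.groupby("condition", sort=False):
        conc, fluxes = {}, {}
        for _, row in grp.iterrows():
            name = str(row["measure"])
            entry = (float(row["value"]), float(row["dispersion"]))
            if name in STATE_NAMES:
                conc[name] = entry
            else:
                fluxes[name] = entry
        out[str(cond)] = ConditionObservations(
            condition=str(cond), concentrations=conc, flux_targets=fluxes,
        )
    return out


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must contain a mapping")
    return cfg
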