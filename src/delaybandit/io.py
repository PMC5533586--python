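"""File formats and pipeline configuration.

Trial logs are plain CSV with header
``agent_id,session,phase_label,phase_type,trial,option,delay_s,omission``;
delays are written with 3 decimals (millisecond precision, matching the
simulator's own resolution, so a write/read round trip is exact), and the
option/delay fields are empty on omitted trials. Cohorts additionally get
a ``provenance.json`` sidecar naming the generating model, parameters and
every seed, from which any output can be regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    LOG_COLUMNS,
    CohortSpec,
    TrialLog,
    default_group_parameters,
    sample_cohort_parameters,
)
from .fitting import DEFAULT_BOUNDS, FitSettings
from .models import ModelId, PARAM_NAMES, ParameterSet
from .task import ScheduleConfig

logger = logging.getLogger(__name__)

__all__ = [
    "write_trial_log",
    "read_trial_log",
    "write_cohort",
    "PipelineConfig",
    "load_config",
]

CSV_HEADER = "agent_id," + ",".join(LOG_COLUMNS)


def write_trial_log(log: TrialLog, path: str | Path) -> None:
    """Write one trial log as CSV with the canonical schema."""
    path = Path(path)
    out = log.df.copy()
    out.insert(0, "agent_id", log.agent_id)
    out["delay_s"] = out["delay_s"].map(
        lambda v: "" if pd.isna(v) else f"{v:.3f}"
    )
    out.to_csv(path, index=False)


def read_trial_log(path: str | Path) -> TrialLog:
    """Read and validate a trial-log CSV.

    Raises ValueError naming the offending row (1-based data row, as in
    the file minus the header) on schema or invariant violations.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={
            "agent_id": str, "session": "Int64", "phase_label": str,
            "phase_type": str, "trial": "Int64", "option": str,
            "delay_s": float, "omission": str,
        },
        keep_default_na=False,
        na_values={"delay_s": [""]},
    )
    expected = CSV_HEADER.split(",")
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: bad header {list(df.columns)}, expected {expected}"
        )
    if df.empty:
        return TrialLog(agent_id=path.stem, df=df[list(LOG_COLUMNS)])
    agents = df["agent_id"].unique()
    if len(agents) != 1:
        raise ValueError(f"{path}: multiple agent_ids {list(agents)}")

    def _fail(mask: pd.Series, msg: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise ValueError(f"{path}: row {row}: {msg}")

    comp = df["omission"] == "none"
    _fail(~df["omission"].isin(["none", "initiation", "choice"]),
          "invalid omission token")
    _fail(comp & ~df["option"].isin(["HV", "LV"]), "invalid option token")
    _fail(comp & df["delay_s"].isna(), "completed trial without delay")
    _fail(df["delay_s"] < 0, "negative delay")
    _fail(~comp & df["delay_s"].notna(), "omitted trial with delay")
    _fail(~comp & (df["option"] != ""), "omitted trial with option")
    dup = df.duplicated(subset=["session", "trial"], keep="first")
    _fail(dup, "duplicated (session, trial)")
    for s, grp in df.groupby("session", sort=True):
        trials = grp["trial"].to_numpy(dtype=int)
        if trials[0] != 1 or (np.diff(trials) != 1).any():
            bad = grp.index[0] + 1
            raise ValueError(
                f"{path}: row {int(bad)}: non-contiguous trial indices "
                f"in session {s}"
            )
    body = df[list(LOG_COLUMNS)].copy()
    body["session"] = body["session"].astype(int)
    body["trial"] = body["trial"].astype(int)
    log = TrialLog(agent_id=str(agents[0]), df=body)
    log.validate()
    return log


def write_cohort(
    logs: Sequence[TrialLog], provenance: Mapping, out_dir: str | Path
) -> list[Path]:
    """Write one CSV per agent plus a provenance.json sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for log in logs:
        p = out_dir / f"{log.agent_id}.csv"
        write_trial_log(log, p)
        paths.append(p)
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(dict(provenance), fh, indent=2)
    return paths


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    schedule: ScheduleConfig
    cohorts: tuple[CohortSpec, ...]
    fitting: FitSettings
    output_dir: str
    master_seed: int
    log_level: str = "INFO"


def _check_keys(block: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def _parse_cohort(block: Mapping, master_seed: int, index: int) -> CohortSpec:
    allowed = {
        "group", "label", "n_agents", "model", "params",
        "heterogeneous", "omission_rates",
    }
    _check_keys(block, allowed, f"cohorts[{index}]")
    n_agents = int(block.get("n_agents", 8))
    omission_rates = block.get("omission_rates")
    if "group" in block:
        group = block["group"]
        model, params = default_group_parameters(group)
        label = block.get("label", group)
        if block.get("heterogeneous", False):
            params = sample_cohort_parameters(
                group, n_agents, seed=master_seed + index
            )
    else:
        model = ModelId(block["model"])
        params = ParameterSet(
            **{k: float(v) for k, v in block["params"].items()}
        )
        params.require(model)
        label = block.get("label", f"cohort{index}")
    return CohortSpec(
        group_label=label,
        n_agents=n_agents,
        model=model,
        params=params,
        master_seed=master_seed + index,
        omission_rates=omission_rates,
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline config (YAML or JSON by extension).

    Top-level keys: schedule, cohorts, fitting, output_dir, master_seed,
    log_level. Unknown keys anywhere are rejected before any computation.
    """
    path = Path(path)
    with open(path) as fh:
        raw: dict[str, Any] = (
            json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        )
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    _check_keys(
        raw,
        {"schedule", "cohorts", "fitting", "output_dir", "master_seed",
         "log_level"},
        "config",
    )
    sched_block = raw.get("schedule", {}) or {}
    _check_keys(
        sched_block,
        {f.name for f in dataclasses.fields(ScheduleConfig)},
        "schedule",
    )
    schedule = ScheduleConfig(**sched_block)

    master_seed = int(raw.get("master_seed", 0))
    cohorts = tuple(
        _parse_cohort(b, master_seed, i)
        for i, b in enumerate(raw.get("cohorts", []))
    )

    fit_block = dict(raw.get("fitting", {}) or {})
    _check_keys(fit_block, {"bounds", "n_starts", "tol", "seed"}, "fitting")
    if "bounds" in fit_block:
        bounds = dict(DEFAULT_BOUNDS)
        for name, pair in fit_block["bounds"].items():
            if name not in bounds:
                raise ValueError(f"unknown parameter {name!r} in bounds")
            bounds[name] = (float(pair[0]), float(pair[1]))
        fit_block["bounds"] = bounds
    fit_block.setdefault("seed", master_seed)
    fitting = FitSettings(**fit_block)

    return PipelineConfig(
        schedule=schedule,
        cohorts=cohorts,
        fitting=fitting,
        output_dir=str(raw.get("output_dir", "out")),
        master_seed=master_seed,
        log_level=str(raw.get("log_level", "INFO")),
    )
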