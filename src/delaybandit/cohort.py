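"""Synthetic cohorts: model-driven agents performing the delay task.

Stands in for undeposited rat trial-by-trial data. Each agent runs a full
schedule, choosing between the HV and LV options by softmax over its
current learned values and experiencing delays drawn from the active
phase's distributions; its learning model is one of the four in
:mod:`delaybandit.models`. Group defaults reproduce the published
best-fitting model and mean parameters of the sham, BLA-lesion and
OFC-lesion groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    AgentState,
    ModelId,
    PARAM_NAMES,
    ParameterSet,
    softmax_choice_prob,
    step_agent,
)
from .task import (
    OPTIONS,
    PhaseType,
    ScheduleConfig,
    TaskSchedule,
    build_schedule,
    latin_square_orders,
    sample_delay,
)

__all__ = [
    "LOG_COLUMNS",
    "TrialLog",
    "CohortSpec",
    "GROUPS",
    "default_group_parameters",
    "group_parameter_sems",
    "sample_cohort_parameters",
    "agent_seed",
    "simulate_agent",
    "simulate_cohort",
]

#: Canonical column order of a trial log.
LOG_COLUMNS = (
    "session",
    "phase_label",
    "phase_type",
    "trial",
    "option",
    "delay_s",
    "omission",
)


@dataclass
class TrialLog:
    """Per-trial record of one agent: simulator output and fitting input.

    ``df`` columns: session, phase_label, phase_type, trial (1-based within
    session, contiguous over all records including omissions), option
    ("HV"/"LV", empty on omitted trials), delay_s (NaN on omitted trials),
    omission ("none", "initiation" or "choice").
    """

    agent_id: str
    df: pd.DataFrame

    def completed(self) -> pd.DataFrame:
        """Completed choice trials only."""
        return self.df[self.df["omission"] == "none"]

    @property
    def n_completed(self) -> int:
        return int((self.df["omission"] == "none").sum())

    def validate(self, schedule: TaskSchedule | None = None) -> None:
        df = self.df
        missing = [c for c in LOG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"log missing columns {missing}")
        comp = df["omission"] == "none"
        if not df.loc[comp, "option"].isin(OPTIONS).all():
            raise ValueError("completed trials must have option HV or LV")
        if df.loc[comp, "delay_s"].isna().any():
            raise ValueError("completed trials must have a delay")
        if (df.loc[comp, "delay_s"] < 0).any():
            raise ValueError("delays must be non-negative")
        if not df.loc[~comp, "delay_s"].isna().all():
            raise ValueError("omitted trials must not carry a delay")
        if (df.loc[~comp, "option"] != "").any():
            raise ValueError("omitted trials must not carry an option")
        if not df["omission"].isin(["none", "initiation", "choice"]).all():
            raise ValueError("invalid omission token")
        sessions = df["session"].to_numpy()
        if len(sessions) and (
            sessions[0] != 1 or (np.diff(np.unique(sessions)) != 1).any()
        ):
            raise ValueError("sessions must be contiguous and 1-based")
        for s, grp in df.groupby("session"):
            trials = grp["trial"].to_numpy()
            if trials[0] != 1 or (np.diff(trials) != 1).any():
                raise ValueError(
                    f"trial indices in session {s} must be contiguous 1-based"
                )
        if schedule is not None:
            expected = {
                i: phase for i, phase in schedule.sessions()
            }
            got_sessions = set(df["session"].unique().tolist())
            if got_sessions != set(expected):
                raise ValueError("log sessions do not match the schedule")
            for s, grp in df.groupby("session"):
                phase = expected[int(s)]
                labels = set(grp["phase_label"].unique().tolist())
                if labels != {phase.label}:
                    raise ValueError(
                        f"session {s} carries labels {labels}, "
                        f"expected {phase.label!r}"
                    )
                n_comp = int((grp["omission"] == "none").sum())
                if n_comp != phase.trials_per_session:
                    raise ValueError(
                        f"session {s} has {n_comp} completed trials, "
                        f"expected {phase.trials_per_session}"
                    )


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one synthetic group of agents."""

    group_label: str
    n_agents: int
    model: ModelId
    params: ParameterSet | tuple[ParameterSet, ...]
    master_seed: int
    omission_rates: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.omission_rates is not None:
            for cond, p in self.omission_rates.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"omission rate for {cond!r} not in [0,1]")

    def agent_params(self, i: int) -> ParameterSet:
        if isinstance(self.params, ParameterSet):
            return self.params
        return self.params[i]


# Published group results: best-fitting model and mean parameters +- SEM
# (n = 8 animals per group).
GROUPS: dict[str, tuple[ModelId, ParameterSet]] = {
    "sham": (
        ModelId.FULL,
        ParameterSet(k=0.29, alpha0=0.09, beta=14.1, eta=0.33,
                     alpha_risk=0.56, omega=3.04),
    ),
    "BLA": (
        ModelId.RW_EU,
        ParameterSet(k=0.32, alpha0=0.07, beta=7.4,
                     alpha_risk=0.58, omega=3.40),
    ),
    "OFC": (
        ModelId.PH,
        ParameterSet(k=0.3, alpha0=0.05, beta=5.5, eta=0.32),
    ),
}

_GROUP_SEMS: dict[str, dict[str, float]] = {
    "sham": {"k": 0.03, "alpha0": 0.01, "beta": 0.99, "eta": 0.04,
             "alpha_risk": 0.08, "omega": 0.11},
    "BLA": {"k": 0.02, "alpha0": 0.01, "beta": 0.6,
            "alpha_risk": 0.06, "omega": 0.4},
    "OFC": {"k": 0.05, "alpha0": 0.01, "beta": 0.68, "eta": 0.05},
}


def default_group_parameters(group: str) -> tuple[ModelId, ParameterSet]:
    """Best-fitting model and mean parameters for a study group.

    sham -> FULL, BLA -> RW_EU (no eta), OFC -> PH (no alpha_risk, omega).
    """
    try:
        return GROUPS[group]
    except KeyError:
        raise ValueError(
            f"unknown group {group!r}; expected one of {sorted(GROUPS)}"
        ) from None


def group_parameter_sems(group: str) -> dict[str, float]:
    """Published cross-animal SEMs of the group's fitted parameters."""
    if group not in _GROUP_SEMS:
        raise ValueError(f"unknown group {group!r}")
    return dict(_GROUP_SEMS[group])


def sample_cohort_parameters(
    group: str, n_agents: int, seed: int
) -> tuple[ParameterSet, ...]:
    """Per-agent parameters for a heterogeneous cohort.

    Only group means +- SEM are published; each parameter is drawn from a
    Normal centred on the mean with sd = SEM * sqrt(8) (undoing the
    standard-error scaling of the published n = 8 cohorts), truncated by
    rejection to the parameter's legal range.
    """
    model, means = default_group_parameters(group)
    sems = group_parameter_sems(group)
    from .models import _PARAM_RANGES  # validation ranges

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_agents):
        values = {}
        for name in PARAM_NAMES[model]:
            mu = getattr(means, name)
            sd = sems[name] * np.sqrt(8.0)
            lo, hi = _PARAM_RANGES[name]
            while True:
                v = rng.normal(mu, sd)
                if v >= lo and (hi is None or v <= hi):
                    break
            values[name] = float(v)
        out.append(ParameterSet(**values))
    return tuple(out)


def agent_seed(master_seed: int, agent_index: int) -> int:
    """Deterministic per-agent seed derived from the cohort master seed."""
    ss = np.random.SeedSequence((int(master_seed), int(agent_index)))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def simulate_agent(
    model: ModelId,
    params: ParameterSet,
    schedule: TaskSchedule,
    seed: int,
    agent_id: str = "agent",
    omission_rates: Mapping[str, float] | None = None,
) -> TrialLog:
    """Simulate one agent through a full schedule.

    Each completed trial: the choice is drawn from the softmax over the
    current Q values, the delay from the active phase's distribution for
    the chosen option, and the agent's state advances by one model step.
    Learning is contiguous across sessions and phases (state never resets).

    With ``omission_rates`` (mapping condition in {stable, upshift,
    downshift} to a probability), initiation-omission records are
    interleaved before completed trials; every session still contains
    exactly ``trials_per_session`` completed trials, mirroring sessions
    that end after a fixed number of rewards.
    """
    model = ModelId(model)
    params.require(model)
    rng = np.random.default_rng(seed)
    state = AgentState.initial(params)
    rows: list[tuple] = []
    for session, phase in schedule.sessions():
        trial = 0
        cond = phase.phase_type.condition
        p_omit = (omission_rates or {}).get(cond, 0.0)
        for _ in range(phase.trials_per_session):
            while p_omit > 0 and rng.random() < p_omit:
                trial += 1
                rows.append(
                    (session, phase.label, phase.phase_type.value, trial,
                     "", np.nan, "initiation")
                )
            trial += 1
            p_hv, _ = softmax_choice_prob(
                state.q["HV"], state.q["LV"], params.beta
            )
            choice = "HV" if rng.random() < p_hv else "LV"
            delay = sample_delay(phase.delays[choice], rng)
            state, _ = step_agent(model, params, state, choice, delay)
            rows.append(
                (session, phase.label, phase.phase_type.value, trial,
                 choice, delay, "none")
            )
    df = pd.DataFrame(rows, columns=list(LOG_COLUMNS))
    log = TrialLog(agent_id=agent_id, df=df)
    log.validate(schedule)
    return log


def simulate_cohort(
    spec: CohortSpec, config: ScheduleConfig | None = None
) -> tuple[list[TrialLog], dict]:
    """Simulate a cohort; returns (logs, provenance record).

    Shift orders are counterbalanced by a cyclic Latin square; per-agent
    seeds derive deterministically from the master seed, so identical specs
    yield identical cohorts. The provenance record names the generating
    model, per-agent parameters, seeds and shift orders.
    """
    config = config or ScheduleConfig()
    orders = latin_square_orders(spec.n_agents)
    logs: list[TrialLog] = []
    agents_prov = []
    for i in range(spec.n_agents):
        params = spec.agent_params(i)
        seed = agent_seed(spec.master_seed, i)
        schedule = build_schedule(config, orders[i])
        aid = f"{spec.group_label}_{i:02d}"
        log = simulate_agent(
            spec.model, params, schedule, seed,
            agent_id=aid, omission_rates=spec.omission_rates,
        )
        logs.append(log)
        agents_prov.append(
            {
                "agent_id": aid,
                "seed": seed,
                "shift_order": [p.value for p in orders[i]],
                "params": {
                    n: getattr(params, n) for n in PARAM_NAMES[spec.model]
                },
            }
        )
    provenance = {
        "group_label": spec.group_label,
        "model": spec.model.value,
        "n_agents": spec.n_agents,
        "master_seed": spec.master_seed,
        "omission_rates": dict(spec.omission_rates or {}),
        "schedule_config": {
            k: getattr(config, k) for k in (
                "baseline_mu", "sigma_hv", "sigma_lv", "upshift_mu",
                "downshift_mu", "sessions_per_phase",
                "initial_baseline_sessions", "trials_per_session",
            )
        },
        "agents": agents_prov,
    }
    return logs, provenance
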