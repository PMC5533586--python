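"""Two-option delay task: phase schedule and delay sampling.

The task offers two visually cued options whose rewards arrive after a
delay drawn from a Normal distribution. At baseline both options share the
same mean delay but differ in spread: a high-variability (HV) and a
low-variability (LV) option. Value shifts change the mean delay of exactly
one option (upshift: shorter wait; downshift: longer wait) while keeping
its spread fixed, and each shift is followed by a return to baseline.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "OPTIONS",
    "DelayDistribution",
    "PhaseType",
    "SHIFT_TYPES",
    "PhaseSpec",
    "TaskSchedule",
    "ScheduleConfig",
    "build_schedule",
    "sample_delay",
    "latin_square_orders",
]

#: The two response options: high- and low-variability delay distributions.
OPTIONS = ("HV", "LV")


@dataclass(frozen=True)
class DelayDistribution:
    """Normal delay distribution (seconds), truncated at zero when sampled.

    Parameters
    ----------
    mu : float
        Mean delay in seconds; must be positive.
    sigma : float
        Standard deviation in seconds; must be non-negative.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


class PhaseType(str, Enum):
    """Phase kinds: stable baseline or a directional shift of one option."""

    BASELINE = "baseline"
    UPSHIFT_HV = "upshift_HV"
    DOWNSHIFT_HV = "downshift_HV"
    UPSHIFT_LV = "upshift_LV"
    DOWNSHIFT_LV = "downshift_LV"

    @property
    def is_shift(self) -> bool:
        return self is not PhaseType.BASELINE

    @property
    def shifted_option(self) -> str | None:
        """Option whose mean delay this phase changes (None for baseline)."""
        if self is PhaseType.BASELINE:
            return None
        return self.value.split("_")[1]

    @property
    def condition(self) -> str:
        """Reward condition label: stable, upshift or downshift."""
        if self is PhaseType.BASELINE:
            return "stable"
        return self.value.split("_")[0]


#: The four shift phases, in canonical order.
SHIFT_TYPES = (
    PhaseType.UPSHIFT_HV,
    PhaseType.DOWNSHIFT_HV,
    PhaseType.UPSHIFT_LV,
    PhaseType.DOWNSHIFT_LV,
)


@dataclass(frozen=True)
class PhaseSpec:
    """One contiguous block of sessions with fixed delay distributions."""

    label: str
    phase_type: PhaseType
    delays: Mapping[str, DelayDistribution]
    n_sessions: int
    trials_per_session: int

    def __post_init__(self) -> None:
        missing = [o for o in OPTIONS if o not in self.delays]
        if missing:
            raise ValueError(f"phase {self.label!r} missing options {missing}")
        if self.n_sessions <= 0 or self.trials_per_session <= 0:
            raise ValueError("session and trial counts must be positive")


@dataclass(frozen=True)
class TaskSchedule:
    """Ordered phases an agent experiences, plus its assigned shift order."""

    phases: tuple[PhaseSpec, ...]
    shift_order: tuple[PhaseType, ...]

    @property
    def n_sessions(self) -> int:
        return sum(p.n_sessions for p in self.phases)

    def sessions(self) -> Iterator[tuple[int, PhaseSpec]]:
        """Yield (1-based session index, phase) across the whole schedule."""
        idx = 0
        for phase in self.phases:
            for _ in range(phase.n_sessions):
                idx += 1
                yield idx, phase

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        if not self.phases:
            raise ValueError("schedule has no phases")
        if self.phases[0].phase_type is not PhaseType.BASELINE:
            raise ValueError("first phase must be baseline")
        base = self.phases[0].delays
        if base["HV"].mu != base["LV"].mu:
            raise ValueError("baseline means must be equal across options")
        for i, phase in enumerate(self.phases):
            if phase.phase_type is PhaseType.BASELINE:
                for o in OPTIONS:
                    if phase.delays[o] != base[o]:
                        raise ValueError(
                            f"baseline phase {phase.label!r} deviates from "
                            f"the initial baseline for option {o}"
                        )
                continue
            shifted = phase.phase_type.shifted_option
            other = "LV" if shifted == "HV" else "HV"
            if phase.delays[other] != base[other]:
                raise ValueError(
                    f"shift phase {phase.label!r} changes the unshifted option"
                )
            if phase.delays[shifted].mu == base[shifted].mu:
                raise ValueError(
                    f"shift phase {phase.label!r} does not move the mean"
                )
            if phase.delays[shifted].sigma != base[shifted].sigma:
                raise ValueError(
                    f"shift phase {phase.label!r} changes sigma of {shifted}"
                )
            if i + 1 >= len(self.phases) or (
                self.phases[i + 1].phase_type is not PhaseType.BASELINE
            ):
                raise ValueError(
                    f"shift phase {phase.label!r} not followed by baseline"
                )

    def to_json(self) -> str:
        payload = {
            "shift_order": [p.value for p in self.shift_order],
            "phases": [
                {
                    "label": p.label,
                    "phase_type": p.phase_type.value,
                    "delays": {o: asdict(d) for o, d in p.delays.items()},
                    "n_sessions": p.n_sessions,
                    "trials_per_session": p.trials_per_session,
                }
                for p in self.phases
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TaskSchedule":
        payload = json.loads(text)
        phases = tuple(
            PhaseSpec(
                label=p["label"],
                phase_type=PhaseType(p["phase_type"]),
                delays={
                    o: DelayDistribution(**d) for o, d in p["delays"].items()
                },
                n_sessions=p["n_sessions"],
                trials_per_session=p["trials_per_session"],
            )
            for p in payload["phases"]
        )
        order = tuple(PhaseType(s) for s in payload["shift_order"])
        sched = cls(phases=phases, shift_order=order)
        sched.validate()
        return sched


@dataclass(frozen=True)
class ScheduleConfig:
    """Schedule block of the pipeline configuration.

    Defaults reproduce the study design: baseline delays N(10, 4) for HV and
    N(10, 1) for LV, shifts to mean 5 (upshift) or 20 (downshift) with the
    option's sigma unchanged, an initial 3-session baseline, then four
    5-session shift phases each followed by a 5-session baseline — 43
    sessions of 60 completed trials in total.
    """

    baseline_mu: float = 10.0
    sigma_hv: float = 4.0
    sigma_lv: float = 1.0
    upshift_mu: float = 5.0
    downshift_mu: float = 20.0
    sessions_per_phase: int = 5
    initial_baseline_sessions: int = 3
    trials_per_session: int = 60

    def __post_init__(self) -> None:
        for name in (
            "sessions_per_phase",
            "initial_baseline_sessions",
            "trials_per_session",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def baseline_delays(self) -> dict[str, DelayDistribution]:
        return {
            "HV": DelayDistribution(self.baseline_mu, self.sigma_hv),
            "LV": DelayDistribution(self.baseline_mu, self.sigma_lv),
        }

    def shift_delays(self, shift: PhaseType) -> dict[str, DelayDistribution]:
        delays = self.baseline_delays()
        mu = self.upshift_mu if shift.condition == "upshift" else self.downshift_mu
        opt = shift.shifted_option
        delays[opt] = DelayDistribution(mu, delays[opt].sigma)
        return delays


def build_schedule(
    config: ScheduleConfig, shift_order: Sequence[PhaseType]
) -> TaskSchedule:
    """Build an agent's full schedule from a config and its shift order.

    The schedule opens with the initial baseline, then walks ``shift_order``
    placing each shift phase followed by a return-to-baseline phase.

    Raises
    ------
    ValueError
        If ``shift_order`` is not a permutation of the four shift types.
    """
    order = tuple(PhaseType(s) for s in shift_order)
    if sorted(p.value for p in order) != sorted(p.value for p in SHIFT_TYPES):
        raise ValueError(
            f"shift_order must contain each of {[p.value for p in SHIFT_TYPES]}"
            f" exactly once, got {[p.value for p in order]}"
        )
    base = config.baseline_delays()
    phases = [
        PhaseSpec(
            label="baseline_0",
            phase_type=PhaseType.BASELINE,
            delays=base,
            n_sessions=config.initial_baseline_sessions,
            trials_per_session=config.trials_per_session,
        )
    ]
    for i, shift in enumerate(order, start=1):
        phases.append(
            PhaseSpec(
                label=shift.value,
                phase_type=shift,
                delays=config.shift_delays(shift),
                n_sessions=config.sessions_per_phase,
                trials_per_session=config.trials_per_session,
            )
        )
        phases.append(
            PhaseSpec(
                label=f"baseline_{i}",
                phase_type=PhaseType.BASELINE,
                delays=base,
                n_sessions=config.sessions_per_phase,
                trials_per_session=config.trials_per_session,
            )
        )
    schedule = TaskSchedule(phases=tuple(phases), shift_order=order)
    schedule.validate()
    return schedule


def sample_delay(dist: DelayDistribution, rng: np.random.Generator) -> float:
    """Draw one non-negative delay (seconds) from ``dist``.

    Negative Normal draws are rejected and redrawn, so the realized
    distribution is the Normal truncated at zero. Delays are recorded at
    millisecond precision.
    """
    if dist.sigma == 0:
        return float(dist.mu)
    while True:
        d = rng.normal(dist.mu, dist.sigma)
        if d >= 0:
            return round(float(d), 3)


def latin_square_orders(n_agents: int) -> list[tuple[PhaseType, ...]]:
    """Counterbalanced shift orders: a cyclic 4x4 Latin square over the
    shift types, cycled across the cohort (agent i gets row i mod 4)."""
    rows = [
        tuple(SHIFT_TYPES[(i + j) % 4] for j in range(4)) for i in range(4)
    ]
    return [rows[i % 4] for i in range(n_agents)]
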