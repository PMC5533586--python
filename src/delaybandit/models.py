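"""Reinforcement-learning model family for the delay task.

Four nested models of trial-by-trial choice between the HV and LV options:

* ``RW`` — Rescorla-Wagner: hyperbolically discounted outcome value
  V = 1/(1 + kD), delta-rule value update with a constant learning rate,
  softmax choice. Free parameters: k, alpha0, beta.
* ``PH`` — Pearce-Hall: as RW, but the learning rate tracks recent
  surprise, alpha <- eta*|delta| + (1-eta)*alpha. Adds eta.
* ``RW_EU`` — RW plus learned expected uncertainty: a second delta rule
  tracks sigma' (the running estimate of squared prediction errors), and
  value updates are damped by omega*exp(sigma'). Adds alpha_risk, omega.
* ``FULL`` — both mechanisms: the uncertainty term damps the value update
  and the surprise input to the Pearce-Hall learning-rate update. All six
  parameters.

Damping the impact of prediction errors by expected uncertainty lets an
agent discount outcome fluctuations that are ordinary for a noisy option
while still learning quickly from genuinely novel outcomes.

Note on the discounting curve: outcome value is V = 1/(1 + kD). This is
standard hyperbolic discounting; it is bounded in (0, 1] for k, D >= 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

__all__ = [
    "ModelId",
    "N_PARAMS",
    "PARAM_NAMES",
    "ParameterSet",
    "AgentState",
    "subjective_value",
    "compute_rpe",
    "softmax_choice_prob",
    "update_value",
    "update_alpha_ph",
    "update_expected_uncertainty",
    "step_agent",
]


class ModelId(str, Enum):
    RW = "RW"
    PH = "PH"
    RW_EU = "RW_EU"
    FULL = "FULL"


#: Free-parameter names per model, in canonical fitting order.
PARAM_NAMES: dict[ModelId, tuple[str, ...]] = {
    ModelId.RW: ("k", "alpha0", "beta"),
    ModelId.PH: ("k", "alpha0", "beta", "eta"),
    ModelId.RW_EU: ("k", "alpha0", "beta", "alpha_risk", "omega"),
    ModelId.FULL: ("k", "alpha0", "beta", "eta", "alpha_risk", "omega"),
}

#: Free-parameter counts: 3, 4, 5, 6 across RW, PH, RW_EU, FULL.
N_PARAMS: dict[ModelId, int] = {m: len(v) for m, v in PARAM_NAMES.items()}

# parameter bounds used for validation (lower, upper); None = unbounded
_PARAM_RANGES = {
    "k": (0.0, None),
    "alpha0": (0.0, 1.0),
    "beta": (0.0, None),
    "eta": (0.0, 1.0),
    "alpha_risk": (0.0, 1.0),
    "omega": (1.0, None),
}


@dataclass(frozen=True)
class ParameterSet:
    """Model parameters; fields irrelevant to a given model may be None.

    k : discounting steepness (1/s), >= 0
    alpha0 : initial learning rate, in [0, 1]
    beta : softmax inverse temperature, >= 0
    eta : learning-rate update rate (Pearce-Hall), in [0, 1]
    alpha_risk : expected-uncertainty learning rate, in [0, 1]
    omega : sensitivity to expected uncertainty (damping divisor), >= 1
    """

    k: float
    alpha0: float
    beta: float
    eta: float | None = None
    alpha_risk: float | None = None
    omega: float | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in _PARAM_RANGES.items():
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if v < lo or (hi is not None and v > hi):
                bound = f"[{lo}, {'inf' if hi is None else hi}]"
                raise ValueError(f"{name}={v} outside {bound}")

    def require(self, model: ModelId) -> None:
        """Raise if any parameter the model needs is missing."""
        missing = [n for n in PARAM_NAMES[model] if getattr(self, n) is None]
        if missing:
            raise ValueError(f"model {model.value} requires {missing}")

    def free_values(self, model: ModelId) -> tuple[float, ...]:
        """The model's free parameters in canonical order."""
        self.require(model)
        return tuple(getattr(self, n) for n in PARAM_NAMES[model])

    @classmethod
    def from_free_values(
        cls, model: ModelId, values: Mapping[str, float] | tuple[float, ...]
    ) -> "ParameterSet":
        if not isinstance(values, Mapping):
            values = dict(zip(PARAM_NAMES[model], values, strict=True))
        return cls(**values)


@dataclass
class AgentState:
    """Per-option learned quantities carried across contiguous trials.

    q : expected value Q per option, in [0, 1]
    alpha : current learning rate per option, in [0, 1]
    sigma_prime : expected uncertainty sigma' per option, in [0, 1]

    Both options start at the midpoint value Q0 = 0.5 with sigma' = 0 and a
    shared initial learning rate alpha0; options evolve independently
    thereafter and only the chosen option is touched by a trial.
    """

    q: dict[str, float]
    alpha: dict[str, float]
    sigma_prime: dict[str, float]

    @classmethod
    def initial(cls, params: ParameterSet) -> "AgentState":
        return cls(
            q={"HV": 0.5, "LV": 0.5},
            alpha={"HV": params.alpha0, "LV": params.alpha0},
            sigma_prime={"HV": 0.0, "LV": 0.0},
        )

    def copy(self) -> "AgentState":
        return AgentState(
            q=dict(self.q),
            alpha=dict(self.alpha),
            sigma_prime=dict(self.sigma_prime),
        )


def subjective_value(delay_s: float, k: float) -> float:
    """Hyperbolically discounted value of a reward after ``delay_s`` seconds.

    V = 1 / (1 + k*D); V in (0, 1], decreasing in both D and k.
    """
    if delay_s < 0:
        raise ValueError("delay must be non-negative")
    if k < 0:
        raise ValueError("k must be non-negative")
    return 1.0 / (1.0 + k * delay_s)


def compute_rpe(value: float, q: float) -> float:
    """Reward prediction error delta = V - Q."""
    return value - q


def softmax_choice_prob(
    q_hv: float, q_lv: float, beta: float
) -> tuple[float, float]:
    """Softmax choice probabilities (p_HV, p_LV), overflow-safe.

    p_HV = exp(beta*Q_HV) / (exp(beta*Q_HV) + exp(beta*Q_LV)), i.e. the
    logistic of beta*(Q_HV - Q_LV).
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    x = beta * (q_hv - q_lv)
    # each side as its own logistic so neither probability underflows to 0
    if x >= 0:
        ex = math.exp(-x)
        p_hv = 1.0 / (1.0 + ex)
        p_lv = ex / (1.0 + ex)
    else:
        ex = math.exp(x)
        p_hv = ex / (1.0 + ex)
        p_lv = 1.0 / (1.0 + ex)
    return p_hv, p_lv


def update_value(q: float, delta: float, alpha: float, divisor: float) -> float:
    """Delta-rule value update, optionally damped by expected uncertainty.

    q_new = q + alpha*delta/divisor, with divisor = 1 (RW, PH) or
    omega*exp(sigma') (RW_EU, FULL). With divisor >= 1 and alpha in [0, 1]
    the result is a convex combination of q and the outcome value, so Q
    stays in [0, 1] without clipping.
    """
    if divisor < 1:
        raise ValueError("divisor must be >= 1")
    return q + alpha * delta / divisor

def update_alpha_ph(
    alpha: float, abs_delta: float, eta: float, divisor: float
) -> float:
    """Pearce-Hall learning-rate update from the degree of surprise.

    alpha_new = eta*|delta|/divisor + (1-eta)*alpha; divisor = 1 for PH,
    omega*exp(sigma') for the FULL model.
    """
    if divisor < 1:
        raise ValueError("divisor must be >= 1")
    return eta * abs_delta / divisor + (1.0 - eta) * alpha


def update_expected_uncertainty(
    sigma_prime: float, delta: float, alpha_risk: float
) -> float:
    """Delta-rule update of expected uncertainty from the risk prediction
    error delta_risk = delta**2 - sigma'.

    sigma'_new = sigma' + alpha_risk*(delta**2 - sigma'), a convex
    combination of sigma' and delta**2, hence stays in [0, 1].
    """
    delta_risk = delta * delta - sigma_prime
    return sigma_prime + alpha_risk * delta_risk


def step_agent(
    model: ModelId,
    params: ParameterSet,
    state: AgentState,
    choice: str,
    delay_s: float,
) -> tuple[AgentState, float]:
    """Advance the agent one completed trial; returns (new state, delta).

    Only the chosen option's state is updated. Within a trial the order is
    fixed: the value update and (where applicable) the learning-rate update
    both use the pre-trial sigma'; sigma' itself is updated last.
    """
    model = ModelId(model)
    params.require(model)
    if choice not in state.q:
        raise ValueError(f"unknown option {choice!r}")
    new = state.copy()
    v = subjective_value(delay_s, params.k)
    delta = compute_rpe(v, state.q[choice])

    uses_uncertainty = model in (ModelId.RW_EU, ModelId.FULL)
    divisor = (
        params.omega * math.exp(state.sigma_prime[choice])
        if uses_uncertainty
        else 1.0
    )
    new.q[choice] = update_value(state.q[choice], delta, state.alpha[choice], divisor)
    if model is ModelId.PH:
        new.alpha[choice] = update_alpha_ph(
            state.alpha[choice], abs(delta), params.eta, 1.0
        )
    elif model is ModelId.FULL:
        new.alpha[choice] = update_alpha_ph(
            state.alpha[choice], abs(delta), params.eta, divisor
        )
    if uses_uncertainty:
        new.sigma_prime[choice] = update_expected_uncertainty(
            state.sigma_prime[choice], delta, params.alpha_risk
        )
    return new, delta
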