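"""Model-free behavioral statistics for delay-task trial logs.

Implements the study's bespoke metrics: classification of each experienced
delay as expected or unexpected (surprising) relative to the delays seen
for that option under baseline conditions so far; win/loss labeling
relative to the running baseline mean; win-stay/lose-shift probabilities
split by expectedness; per-session option preference; and maximal
preference change in response to a value shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import TrialLog
from .task import OPTIONS, PhaseType

__all__ = [
    "BaselineHistory",
    "WSLSTable",
    "classify_outcome",
    "classify_win_loss",
    "wsls_probabilities",
    "session_summary",
    "max_shift_change",
]


@dataclass
class _OptionHistory:
    n: int = 0
    min: float = float("inf")
    max: float = float("-inf")
    total: float = 0.0

    @property
    def mean(self) -> float:
        return self.total / self.n

    def add(self, delay: float) -> None:
        self.n += 1
        self.min = min(self.min, delay)
        self.max = max(self.max, delay)
        self.total += delay


@dataclass
class BaselineHistory:
    """Running per-option record of delays experienced at baseline.

    Strictly causal: when classifying trial t, the history reflects only
    baseline-phase trials that occurred before t. Shift-phase delays never
    enter the history.
    """

    options: dict[str, _OptionHistory] = field(
        default_factory=lambda: {o: _OptionHistory() for o in OPTIONS}
    )

    def add(self, option: str, delay: float) -> None:
        self.options[option].add(delay)

    def count(self, option: str) -> int:
        return self.options[option].n


def classify_outcome(
    delay_s: float, history: BaselineHistory, option: str
) -> str:
    """Classify a delay as ``expected``, ``unexpected`` or ``unclassifiable``.

    Expected iff min <= delay <= max of the option's prior baseline delays
    (closed interval: boundary delays count as expected); unexpected
    otherwise. With fewer than two prior baseline observations there is no
    interval to speak of and the trial is unclassifiable.
    """
    h = history.options[option]
    if h.n < 2:
        return "unclassifiable"
    return "expected" if h.min <= delay_s <= h.max else "unexpected"


def classify_win_loss(
    delay_s: float, history: BaselineHistory, option: str,
    win_rule: str = "short",
) -> str:
    """Label a delay ``win``, ``loss`` or ``excluded`` (equal to the mean).

    Default rule (``short``): a delay shorter than the option's running
    baseline mean is a win — a shorter wait is a better outcome. The
    inverted rule (``long``) is available for sensitivity analysis.
    """
    h = history.options[option]
    if h.n < 2:
        raise ValueError("need >= 2 prior baseline observations")
    if win_rule not in ("short", "long"):
        raise ValueError(f"unknown win_rule {win_rule!r}")
    if delay_s == h.mean:
        return "excluded"
    shorter = delay_s < h.mean
    return "win" if (shorter == (win_rule == "short")) else "loss"


@dataclass
class WSLSTable:
    """Win-stay/lose-shift scores split by outcome expectedness.

    Cells are (strategy, outcome class) with strategy in {win_stay,
    lose_shift} and class in {expected, unexpected}. A win trial followed
    by a repeat of the same option scores 1 for win-stay (a shift scores
    0); a loss followed by a switch scores 1 for lose-shift. The cell
    probability is the summary score divided by the number of trials.
    """

    score: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            (s, c): 0
            for s in ("win_stay", "lose_shift")
            for c in ("expected", "unexpected")
        }
    )
    count: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            (s, c): 0
            for s in ("win_stay", "lose_shift")
            for c in ("expected", "unexpected")
        }
    )

    def probability(self, strategy: str, outcome_class: str) -> float:
        key = (strategy, outcome_class)
        n = self.count[key]
        return self.score[key] / n if n else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "strategy": s,
                "outcome_class": c,
                "score_sum": self.score[(s, c)],
                "n": self.count[(s, c)],
                "probability": self.probability(s, c),
            }
            for (s, c) in self.score
        ]
        return pd.DataFrame(rows)


def wsls_probabilities(log: TrialLog, win_rule: str = "short") -> WSLSTable:
    """Win-stay/lose-shift probabilities by outcome expectedness.

    Walks the log in trial order, maintaining the per-option baseline
    history. Each completed trial t is classified (expectedness and
    win/loss) against the history before t, then paired with the next
    choice: a stay repeats t's option, a shift takes the other. Pairs whose
    next attempted choice ended in a choice omission are dropped, as are
    trials that are unclassifiable (cold start) or whose delay equals the
    running mean. Baseline-phase delays join the history after their trial
    is classified. All baseline and shift trials are considered.
    """
    table = WSLSTable()
    history = BaselineHistory()
    df = log.df
    records = list(
        zip(df["phase_type"], df["option"], df["delay_s"], df["omission"])
    )
    for i, (ptype, option, delay, omission) in enumerate(records):
        if omission != "none":
            continue
        # find the next choice; skip initiation omissions, a choice
        # omission breaks the pair
        next_option = None
        for ptype2, option2, _d2, om2 in records[i + 1:]:
            if om2 == "initiation":
                continue
            if om2 == "choice":
                break
            next_option = option2
            break
        cls = classify_outcome(delay, history, option)
        if cls != "unclassifiable" and next_option is not None:
            wl = classify_win_loss(delay, history, option, win_rule)
            if wl != "excluded":
                stayed = next_option == option
                if wl == "win":
                    table.count[("win_stay", cls)] += 1
                    table.score[("win_stay", cls)] += int(stayed)
                else:
                    table.count[("lose_shift", cls)] += 1
                    table.score[("lose_shift", cls)] += int(not stayed)
        if PhaseType(ptype) is PhaseType.BASELINE:
            history.add(option, float(delay))
    return table


def session_summary(log: TrialLog) -> pd.DataFrame:
    """Per-session preference and omission counts.

    Columns: session, phase_label, phase_type, condition, hv_fraction
    (HV choices / completed trials), n_completed, n_initiation_omissions,
    n_choice_omissions.
    """
    rows = []
    for session, grp in log.df.groupby("session", sort=True):
        comp = grp[grp["omission"] == "none"]
        n_comp = len(comp)
        rows.append(
            {
                "session": int(session),
                "phase_label": grp["phase_label"].iloc[0],
                "phase_type": grp["phase_type"].iloc[0],
                "condition": PhaseType(grp["phase_type"].iloc[0]).condition,
                "hv_fraction": (
                    float((comp["option"] == "HV").mean()) if n_comp else
                    float("nan")
                ),
                "n_completed": n_comp,
                "n_initiation_omissions": int(
                    (grp["omission"] == "initiation").sum()
                ),
                "n_choice_omissions": int((grp["omission"] == "choice").sum()),
            }
        )
    return pd.DataFrame(rows)


def max_shift_change(series: pd.DataFrame, shift_phase: str) -> float:
    """Maximal signed session-level preference change during a shift.

    The pre-shift reference is the mean preference for the shifted option
    over the sessions of the immediately preceding baseline phase; the
    return value is the session-minus-reference difference of largest
    absolute value within the shift phase (signed; ties go to the earliest
    session).
    """
    labels = series["phase_label"].tolist()
    if shift_phase not in labels:
        raise ValueError(f"phase {shift_phase!r} not in series")
    shift = series[series["phase_label"] == shift_phase]
    ptype = PhaseType(shift["phase_type"].iloc[0])
    if not ptype.is_shift:
        raise ValueError(f"{shift_phase!r} is not a shift phase")
    first_session = shift["session"].min()
    before = series[series["session"] < first_session]
    if before.empty:
        raise ValueError(f"no baseline precedes {shift_phase!r}")
    pre_label = before["phase_label"].iloc[-1]
    pre = before[before["phase_label"] == pre_label]
    if PhaseType(pre["phase_type"].iloc[0]) is not PhaseType.BASELINE:
        raise ValueError(f"phase before {shift_phase!r} is not baseline")

    option = ptype.shifted_option

    def pref(frame: pd.DataFrame) -> np.ndarray:
        hv = frame["hv_fraction"].to_numpy(dtype=float)
        return hv if option == "HV" else 1.0 - hv

    baseline_pref = float(np.mean(pref(pre)))
    diffs = pref(shift) - baseline_pref
    return float(diffs[int(np.argmax(np.abs(diffs)))])
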