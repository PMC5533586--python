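"""Behavioral statistics: outcome classification, WSLS, preference."""

import numpy as np
import pandas as pd
import pytest

from delaybandit import (
    BaselineHistory,
    TrialLog,
    classify_outcome,
    classify_win_loss,
    default_group_parameters,
    max_shift_change,
    session_summary,
    simulate_agent,
    wsls_probabilities,
)


def _history(delays, option="HV"):
    h = BaselineHistory()
    for d in delays:
        h.add(option, d)
    return h


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "delay,expected",
        [(10.0, "expected"), (20.0, "unexpected"), (14.0, "expected"),
         (6.0, "expected"), (5.9, "unexpected")],
    )
    def test_interval_rule_with_closed_boundaries(self, delay, expected):
        h = _history([6.0, 14.0])
        assert classify_outcome(delay, h, "HV") == expected

    def test_cold_start_is_unclassifiable(self):
        assert classify_outcome(10.0, _history([8.0]), "HV") == "unclassifiable"
        assert classify_outcome(10.0, _history([]), "HV") == "unclassifiable"

    def test_histories_are_per_option(self):
        h = _history([6.0, 14.0], option="HV")
        assert classify_outcome(10.0, h, "LV") == "unclassifiable"


class TestClassifyWinLoss:
    @pytest.mark.parametrize(
        "delay,expected",
        [(6.0, "win"), (20.0, "loss"), (10.0, "excluded")],
    )
    def test_default_rule_short_delay_wins(self, delay, expected):
        # history mean = 10
        h = _history([6.0, 14.0])
        assert classify_win_loss(delay, h, "HV") == expected

    def test_literal_rule_inverts_direction(self):
        h = _history([6.0, 14.0])
        assert classify_win_loss(6.0, h, "HV", win_rule="long") == "loss"
        assert classify_win_loss(20.0, h, "HV", win_rule="long") == "win"

    def test_cold_start_rejected(self):
        with pytest.raises(ValueError):
            classify_win_loss(5.0, _history([8.0]), "HV")


def _make_log(rows):
    df = pd.DataFrame(
        rows,
        columns=["session", "phase_label", "phase_type", "trial", "option",
                 "delay_s", "omission"],
    )
    return TrialLog(agent_id="hand", df=df)


class TestWSLS:
    def test_hand_enumerated_log(self):
        """Six baseline trials on one option with known delays.

        History seeding trials: 6 s then 14 s (unclassifiable; afterwards
        min=6, mean=10, max=14). Then: 8 s (win, expected) followed by a
        stay; 20 s (loss, unexpected) followed by a shift... back to HV;
        10 s (delay == running mean 12 -> ... recomputed) — enumerated
        below with the running history in mind.
        """
        rows = [
            # history after classification: (min, mean, max) over HV
            (1, "baseline_0", "baseline", 1, "HV", 6.0, "none"),
            (1, "baseline_0", "baseline", 2, "HV", 14.0, "none"),
            # t3: hist {6,14}: 8 in [6,14] -> expected; 8<10 -> win; next HV
            (1, "baseline_0", "baseline", 3, "HV", 8.0, "none"),
            # t4: hist {6,14,8}: 20>14 -> unexpected; 20>9.33 -> loss;
            # next LV -> shift
            (1, "baseline_0", "baseline", 4, "HV", 20.0, "none"),
            # t5 (LV): no LV history -> unclassifiable, dropped
            (1, "baseline_0", "baseline", 5, "LV", 10.0, "none"),
            # t6 (HV): hist {6,14,8,20}: mean 12 -> delay 12 excluded
            (1, "baseline_0", "baseline", 6, "HV", 12.0, "none"),
            # t7: terminal trial has no successor, dropped
            (1, "baseline_0", "baseline", 7, "HV", 9.0, "none"),
        ]
        table = wsls_probabilities(_make_log(rows))
        assert table.probability("win_stay", "expected") == 1.0
        assert table.count[("win_stay", "expected")] == 1
        assert table.probability("lose_shift", "unexpected") == 1.0
        assert table.count[("lose_shift", "unexpected")] == 1
        assert table.count[("win_stay", "unexpected")] == 0
        assert table.count[("lose_shift", "expected")] == 0

    def test_choice_omission_breaks_pair_initiation_does_not(self):
        rows = [
            (1, "baseline_0", "baseline", 1, "HV", 6.0, "none"),
            (1, "baseline_0", "baseline", 2, "HV", 14.0, "none"),
            # win trial whose successor is a choice omission: dropped
            (1, "baseline_0", "baseline", 3, "HV", 7.0, "none"),
            (1, "baseline_0", "baseline", 4, "", np.nan, "choice"),
            # win trial followed by an initiation omission then an HV
            # choice: the pair stands and scores a stay
            (1, "baseline_0", "baseline", 5, "HV", 7.5, "none"),
            (1, "baseline_0", "baseline", 6, "", np.nan, "initiation"),
            (1, "baseline_0", "baseline", 7, "HV", 9.0, "none"),
        ]
        table = wsls_probabilities(_make_log(rows))
        # only the post-initiation-omission pair is scored: the trial before
        # the choice omission is dropped, and the final trial has no
        # successor
        assert table.count[("win_stay", "expected")] == 1
        assert table.score[("win_stay", "expected")] == 1

    def test_matches_brute_force_oracle_on_random_small_logs(self):
        """Exact cell-by-cell agreement with a from-scratch enumeration
        that rebuilds the baseline history for every trial."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(10, 50))
            rows = []
            for t in range(1, n + 1):
                shift = rng.random() < 0.3
                rows.append(
                    (1, "p", "upshift_HV" if shift else "baseline", t,
                     "HV" if rng.random() < 0.5 else "LV",
                     float(np.round(rng.uniform(2, 20), 3)), "none")
                )
            log = _make_log(rows)
            table = wsls_probabilities(log)
            oracle = _brute_force_wsls(rows)
            for cell in table.score:
                assert table.score[cell] == oracle[0][cell], cell
                assert table.count[cell] == oracle[1][cell], cell

    def test_prefix_causality(self):
        """Appending future trials never changes earlier contributions:
        counts over a prefix equal counts from the full log restricted to
        pairs inside the prefix."""
        rng = np.random.default_rng(9)
        rows = [
            (1, "p", "baseline", t,
             "HV" if rng.random() < 0.5 else "LV",
             float(np.round(rng.uniform(2, 20), 3)), "none")
            for t in range(1, 41)
        ]
        full = _brute_force_wsls(rows)
        prefix = _brute_force_wsls(rows[:25])
        # recompute full-log scores but only for trials with index < 24
        limited = _brute_force_wsls(rows, last_scored=23)
        assert prefix[0] == limited[0] and prefix[1] == limited[1]

    def test_indifferent_agent_has_chance_level_stays(self, default_schedule):
        from delaybandit import ModelId, ParameterSet

        params = ParameterSet(k=0.3, alpha0=0.1, beta=0.0)
        log = simulate_agent(ModelId.RW, params, default_schedule, seed=17)
        table = wsls_probabilities(log)
        for cell, n in table.count.items():
            p = table.score[cell] / n
            assert abs(p - 0.5) < 3 * np.sqrt(0.25 / n), cell


def _brute_force_wsls(rows, last_scored=None):
    """Enumeration oracle: for each completed trial, rebuild the baseline
    history from scratch over all earlier rows, classify, and score
    against the next completed choice."""
    score = {(s, c): 0 for s in ("win_stay", "lose_shift")
             for c in ("expected", "unexpected")}
    count = {k: 0 for k in score}
    completed = [
        (i, r) for i, r in enumerate(rows) if r[6] == "none"
    ]
    for pos, (i, r) in enumerate(completed):
        if last_scored is not None and pos > last_scored:
            break
        # next record: initiation omissions skipped, choice omission breaks
        nxt = None
        for r2 in rows[i + 1:]:
            if r2[6] == "initiation":
                continue
            if r2[6] == "choice":
                break
            nxt = r2[4]
            break
        if nxt is None:
            continue
        option, delay = r[4], r[5]
        prior = [r2[5] for r2 in rows[:i]
                 if r2[6] == "none" and r2[4] == option
                 and r2[2] == "baseline"]
        if len(prior) < 2:
            continue
        lo, hi, mean = min(prior), max(prior), sum(prior) / len(prior)
        cls = "expected" if lo <= delay <= hi else "unexpected"
        if delay == mean:
            continue
        if delay < mean:
            count[("win_stay", cls)] += 1
            score[("win_stay", cls)] += int(nxt == option)
        else:
            count[("lose_shift", cls)] += 1
            score[("lose_shift", cls)] += int(nxt != option)
    return score, count


class TestSessionSummary:
    def test_fraction_examples(self):
        rows = []
        for t in range(1, 61):
            rows.append((1, "b", "baseline", t, "HV", 10.0, "none"))
        for t in range(1, 61):
            rows.append((2, "b", "baseline", t,
                         "HV" if t <= 30 else "LV", 10.0, "none"))
        s = session_summary(_make_log(rows))
        assert s.loc[s["session"] == 1, "hv_fraction"].item() == 1.0
        assert s.loc[s["session"] == 2, "hv_fraction"].item() == 0.5

    def test_omissions_counted_not_in_denominator(self):
        rows = [(1, "b", "baseline", t, "HV", 10.0, "none")
                for t in range(1, 41)]
        rows += [(1, "b", "baseline", t, "LV", 10.0, "none")
                 for t in range(41, 60)]
        rows += [(1, "b", "baseline", 60, "", np.nan, "choice")]
        s = session_summary(_make_log(rows))
        assert s["n_completed"].item() == 59
        assert s["n_choice_omissions"].item() == 1
        assert s["hv_fraction"].item() == pytest.approx(40 / 59)
        assert s["hv_fraction"].item() == pytest.approx(0.678, abs=5e-4)

    def test_round_trips_from_raw_log(self, sham_log):
        s = session_summary(sham_log)
        for _, row in s.sample(5, random_state=0).iterrows():
            grp = sham_log.df[sham_log.df["session"] == row["session"]]
            comp = grp[grp["omission"] == "none"]
            assert row["hv_fraction"] == pytest.approx(
                (comp["option"] == "HV").mean()
            )


class TestMaxShiftChange:
    def _series(self, prefs_by_phase):
        rows = []
        session = 0
        for label, ptype, prefs in prefs_by_phase:
            for p in prefs:
                session += 1
                rows.append(
                    {"session": session, "phase_label": label,
                     "phase_type": ptype, "condition": "x",
                     "hv_fraction": p, "n_completed": 60,
                     "n_initiation_omissions": 0, "n_choice_omissions": 0}
                )
        return pd.DataFrame(rows)

    def test_constant_preference_gives_zero(self):
        s = self._series([("b0", "baseline", [0.5] * 3),
                          ("up", "upshift_HV", [0.5] * 5)])
        assert max_shift_change(s, "up") == 0.0

    def test_signed_max_against_preceding_baseline(self):
        s = self._series([
            ("b0", "baseline", [0.5, 0.5, 0.5]),
            ("up", "upshift_HV", [0.55, 0.70, 0.65, 0.68, 0.66]),
        ])
        assert max_shift_change(s, "up") == pytest.approx(0.20)

    def test_negative_change_keeps_sign(self):
        s = self._series([("b0", "baseline", [0.6] * 3),
                          ("down", "downshift_HV", [0.4] * 5)])
        assert max_shift_change(s, "down") == pytest.approx(-0.20)

    def test_lv_shift_uses_lv_preference(self):
        # HV fraction rises, so LV preference falls during an LV downshift
        s = self._series([("b0", "baseline", [0.5] * 3),
                          ("down", "downshift_LV", [0.7] * 5)])
        assert max_shift_change(s, "down") == pytest.approx(-0.20)

    def test_missing_baseline_rejected(self):
        s = self._series([("up", "upshift_HV", [0.6] * 5)])
        with pytest.raises(ValueError):
            max_shift_change(s, "up")
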