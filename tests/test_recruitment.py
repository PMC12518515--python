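"""Recruitment curves, selectivity index and configuration sweeps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eesim.recruitment import (
    NOT_REACHED,
    RecruitmentCurve,
    frequency_comparison,
    max_selectivity,
    motor_unit_thresholds,
    recruitment_from_thresholds,
    selectivity_index,
    si_profile,
    sweep_selections,
    threshold_saturation,
)

GRID = np.arange(25.0, 1000.0 + 1e-9, 25.0)


def _fiber_table(rows):
    return pd.DataFrame(
        rows, columns=["muscle", "motor_unit_id", "fiber_class", "threshold_ua"]
    )


class TestUnitThresholds:
    def test_min_rule_takes_lower_fiber(self):
        df = _fiber_table(
            [("TA", "TA-00", "sensory", 75.0), ("TA", "TA-00", "motor", 300.0)]
        )
        out = motor_unit_thresholds(df)
        assert out.loc[0, "threshold_ua"] == 75.0

    def test_unrecruited_unit_stays_infinite(self):
        df = _fiber_table(
            [("TA", "TA-00", "sensory", np.inf), ("TA", "TA-00", "motor", np.inf)]
        )
        assert np.isinf(motor_unit_thresholds(df).loc[0, "threshold_ua"])

    def test_matches_bruteforce_min_over_classes(self):
        rng = np.random.default_rng(5)
        rows = []
        expect = {}
        for u in range(40):
            s, m = rng.uniform(25, 1000, 2)
            uid = f"GC-{u:02d}"
            rows += [("GC", uid, "sensory", s), ("GC", uid, "motor", m)]
            expect[uid] = min(s, m)
        out = motor_unit_thresholds(_fiber_table(rows))
        got = dict(zip(out["motor_unit_id"], out["threshold_ua"]))
        assert got == pytest.approx(expect)

    def test_class_specific_rule(self):
        df = _fiber_table(
            [("TA", "TA-00", "sensory", 75.0), ("TA", "TA-00", "motor", 300.0)]
        )
        assert motor_unit_thresholds(df, rule="motor").loc[0, "threshold_ua"] == 300.0

    def test_missing_threshold_raises(self):
        df = _fiber_table([("TA", "TA-00", "sensory", np.nan)])
        with pytest.raises(ValueError, match="TA-00"):
            motor_unit_thresholds(df)


class TestCurves:
    def test_equal_thresholds_give_step(self):
        c = recruitment_from_thresholds(np.full(40, 100.0), GRID)
        assert np.all(c.fraction[GRID < 100.0] == 0.0)
        assert np.all(c.fraction[GRID >= 100.0] == 1.0)

    def test_uniform_thresholds_give_linear_curve(self):
        c = recruitment_from_thresholds(GRID.copy(), GRID)
        assert np.allclose(c.fraction, GRID / 1000.0)

    def test_empty_recruitment_is_zero(self):
        c = recruitment_from_thresholds(np.full(40, np.inf), GRID)
        assert np.all(c.fraction == 0.0)

    def test_curve_invariants_enforced(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            RecruitmentCurve("x", GRID, np.linspace(1, 0, GRID.size), np.empty(0))


class TestThresholdSaturation:
    def test_distinct_thresholds_hit_order_statistics(self):
        rng = np.random.default_rng(11)
        thr = rng.choice(GRID, 40, replace=False)
        c = recruitment_from_thresholds(thr, GRID)
        t, s = threshold_saturation(c)
        srt = np.sort(thr)
        assert t == srt[3]  # 4th order statistic reaches 10% of 40
        assert s == srt[35]  # 36th order statistic reaches 90%

    def test_degenerate_pool_threshold_equals_saturation(self):
        c = recruitment_from_thresholds(np.full(40, 250.0), GRID)
        assert threshold_saturation(c) == (250.0, 250.0)

    def test_half_recruited_pool_never_saturates(self):
        thr = np.r_[np.full(20, 100.0), np.full(20, np.inf)]
        t, s = threshold_saturation(recruitment_from_thresholds(thr, GRID))
        assert t == 100.0
        assert s == NOT_REACHED


class TestSelectivity:
    def test_exclusive_full_recruitment_gives_one(self):
        assert selectivity_index({"TA": 1.0, "GC": 0, "VM": 0, "ST": 0}, "TA") == 1.0

    def test_equal_recruitment_gives_zero(self):
        assert selectivity_index(dict.fromkeys("abcd", 0.6), "a") == 0.0

    def test_hand_computed_example(self):
        R = {"TA": 0.8, "GC": 0.2, "VM": 0.1, "ST": 0.3}
        assert selectivity_index(R, "TA") == pytest.approx(0.6)

    def test_fewer_than_two_muscles_rejected(self):
        with pytest.raises(ValueError):
            selectivity_index({"TA": 1.0}, "TA")

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=6))
    def test_bounded_in_unit_interval(self, rs):
        R = {f"m{i}": v for i, v in enumerate(rs)}
        si = selectivity_index(R, "m0")
        assert -1.0 <= si <= 1.0


def _random_curves(seed, n_units=40):
    rng = np.random.default_rng(seed)
    out = {}
    for mu in ("TA", "GC", "VM", "ST"):
        thr = rng.choice(GRID, n_units, replace=True)
        thr[rng.random(n_units) < 0.1] = np.inf
        out[mu] = recruitment_from_thresholds(thr, GRID)
    return out


class TestMaxSelectivity:
    def test_sole_recruited_muscle_reaches_one(self):
        curves = {
            "TA": recruitment_from_thresholds(np.full(40, 100.0), GRID),
            "GC": recruitment_from_thresholds(np.full(40, np.inf), GRID),
            "VM": recruitment_from_thresholds(np.full(40, np.inf), GRID),
            "ST": recruitment_from_thresholds(np.full(40, np.inf), GRID),
        }
        si, amp = max_selectivity(curves, "TA")
        assert si == 1.0

    def test_shared_curve_gives_zero(self):
        c = recruitment_from_thresholds(np.linspace(100, 800, 40), GRID)
        curves = {m: c for m in ("TA", "GC", "VM", "ST")}
        si, _ = max_selectivity(curves, "TA")
        assert si == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        curves = _random_curves(seed)
        for target in curves:
            thr, sat = threshold_saturation(curves[target])
            if not np.isfinite(thr):
                continue
            hi = sat if np.isfinite(sat) else GRID[-1]
            si = si_profile(curves, target)
            mask = (GRID >= thr) & (GRID <= hi)
            best = np.max(si[mask])
            got_si, got_amp = max_selectivity(curves, target)
            assert got_si == pytest.approx(best)
            # lowest-amplitude tie-break
            assert got_amp == GRID[mask][np.argmax(si[mask])]

    def test_amplitude_at_max_lies_in_dynamic_range(self):
        for seed in range(5):
            curves = _random_curves(seed)
            for target in curves:
                thr, sat = threshold_saturation(curves[target])
                si, amp = max_selectivity(curves, target)
                if not np.isfinite(thr):
                    assert np.isnan(si)
                    continue
                assert thr <= amp <= (sat if np.isfinite(sat) else GRID[-1])

    def test_unreachable_target_gives_nan(self):
        curves = {m: recruitment_from_thresholds(np.full(40, np.inf), GRID)
                  for m in ("TA", "GC")}
        si, amp = max_selectivity(curves, "TA")
        assert np.isnan(si) and np.isnan(amp)

    def test_invariant_to_muscle_ordering(self):
        curves = _random_curves(3)
        reordered = dict(reversed(list(curves.items())))
        for target in curves:
            assert max_selectivity(curves, target) == max_selectivity(
                reordered, target
            )


def _metrics_table(seed):
    rng = np.random.default_rng(seed)
    rows = []
    for side in ("dorsal", "ventral"):
        for mode in ("monopolar", "bipolar", "tripolar"):
            for cfg in ("A", "B", "C"):
                for mu in ("TA", "GC", "VM", "ST"):
                    rows.append(
                        {
                            "side": side,
                            "mode": mode,
                            "configuration": cfg,
                            "muscle": mu,
                            "threshold_ua": rng.choice(GRID),
                            "saturation_ua": rng.choice(GRID),
                            "si_max": rng.uniform(-1, 1),
                        }
                    )
    return pd.DataFrame(rows)


class TestSweep:
    def test_single_configuration_wins_everything(self):
        df = _metrics_table(0)
        one = df[df["configuration"] == "A"].copy()
        sel = sweep_selections(one)
        assert set(sel["configuration"]) == {"A"}

    def test_selections_match_bruteforce(self):
        df = _metrics_table(1)
        sel = sweep_selections(df).set_index(
            ["side", "mode", "muscle", "selection"]
        )
        for (side, mode, mu), grp in df.groupby(["side", "mode", "muscle"]):
            assert (
                sel.loc[(side, mode, mu, "min_threshold"), "value"]
                == grp["threshold_ua"].min()
            )
            assert (
                sel.loc[(side, mode, mu, "min_saturation"), "value"]
                == grp["saturation_ua"].min()
            )
            assert (
                sel.loc[(side, mode, mu, "max_selectivity"), "value"]
                == grp["si_max"].max()
            )

    def test_row_bookkeeping(self):
        sel = sweep_selections(_metrics_table(2))
        per_metric = sel.groupby("selection").size()
        assert (per_metric == 2 * 3 * 4).all()  # sides x modes x muscles

    def test_invariant_to_row_order(self):
        df = _metrics_table(3)
        shuffled = df.sample(frac=1.0, random_state=0)
        a = sweep_selections(df).sort_values(
            ["side", "mode", "muscle", "selection"], ignore_index=True
        )
        b = sweep_selections(shuffled).sort_values(
            ["side", "mode", "muscle", "selection"], ignore_index=True
        )
        pd.testing.assert_frame_equal(a, b)


class TestFrequencyComparison:
    def _top(self):
        return pd.DataFrame(
            [
                {"side": "d", "mode": "mono", "muscle": "GC", "configuration": "L5"},
                {"side": "d", "mode": "mono", "muscle": "ST", "configuration": "L5"},
                {"side": "d", "mode": "mono", "muscle": "TA", "configuration": "L4"},
            ]
        )

    def test_rate_independent_metrics_are_identical(self):
        def evaluate(side, mode, cfg, rate):
            return {m: {"si_max": 0.5, "si_amplitude_ua": 300.0}
                    for m in ("GC", "ST", "TA")}

        df = frequency_comparison(self._top(), evaluate, rates_hz=(50.0, 100.0))
        assert df.groupby("muscle")["si_max"].nunique().eq(1).all()

    def test_shared_configuration_evaluated_once(self):
        calls = []

        def evaluate(side, mode, cfg, rate):
            calls.append((side, mode, cfg, rate))
            return {m: {"si_max": 0.1, "si_amplitude_ua": 100.0}
                    for m in ("GC", "ST", "TA")}

        df = frequency_comparison(self._top(), evaluate, rates_hz=(50.0,))
        assert len(calls) == 2  # L5 shared by GC and ST, L4 for TA
        assert len(df) == 3

    def test_matches_single_rate_pipeline(self):
        def evaluate(side, mode, cfg, rate):
            rng = np.random.default_rng(hash((cfg, rate)) % 2**31)
            return {
                m: {"si_max": rng.random(), "si_amplitude_ua": 100.0}
                for m in ("GC", "ST", "TA")
            }

        both = frequency_comparison(self._top(), evaluate, rates_hz=(50.0, 100.0))
        only100 = frequency_comparison(self._top(), evaluate, rates_hz=(100.0,))
        a = both[both["rate_hz"] == 100.0].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, only100)
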