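"""Recruitment curves, threshold/saturation, selectivity, and sweeps.

A muscle's recruitment at amplitude ``a`` is the fraction of its motor units
with threshold <= a.  A motor unit's threshold is the minimum of its sensory
and its motor fiber threshold (the monosynaptic Ia->motoneuron relay is
assumed reliably suprathreshold); the rule is switchable to a single class.
Threshold / saturation of a muscle are the smallest grid amplitudes reaching
10% / 90% recruitment.  The selectivity index of a target muscle at one
amplitude is its recruitment minus the mean recruitment of the other
muscles; the reported SI is the maximum over the target's dynamic range
(threshold..saturation, top of the grid when saturation is not reached),
ties broken toward the lowest amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RecruitmentCurve",
    "MuscleMetrics",
    "motor_unit_thresholds",
    "recruitment_from_thresholds",
    "threshold_saturation",
    "selectivity_index",
    "si_profile",
    "max_selectivity",
    "sweep_selections",
    "frequency_comparison",
    "NOT_REACHED",
]

#: Sentinel for "10%/90% level never reached on the grid".
NOT_REACHED = np.inf

THRESHOLD_LEVEL = 0.10
SATURATION_LEVEL = 0.90


@dataclass
class RecruitmentCurve:
    muscle: str
    amplitudes_ua: np.ndarray
    fraction: np.ndarray
    unit_thresholds: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fraction) < -1e-12):
            raise ValueError("recruitment fraction must be non-decreasing")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("recruitment fraction must lie in [0, 1]")


@dataclass
class MuscleMetrics:
    muscle: str
    threshold_ua: float
    saturation_ua: float
    si_max: float
    si_amplitude_ua: float


def motor_unit_thresholds(
    fiber_thresholds: pd.DataFrame,
    rule: str = "min",
) -> pd.DataFrame:
    """Per-motor-unit thresholds from per-fiber thresholds.

    ``fiber_thresholds`` columns: muscle, motor_unit_id, fiber_class,
    threshold_ua (inf = not recruited).  ``rule``: "min" (default), or
    "sensory"/"motor" for class-specific recruitment.
    """
    required = {"muscle", "motor_unit_id", "fiber_class", "threshold_ua"}
    missing = required - set(fiber_thresholds.columns)
    if missing:
        raise ValueError(f"fiber threshold table missing columns {sorted(missing)}")
    if fiber_thresholds["threshold_ua"].isna().any():
        bad = fiber_thresholds.loc[
            fiber_thresholds["threshold_ua"].isna(), "motor_unit_id"
        ].iloc[0]
        raise ValueError(f"missing fiber threshold for unit {bad}")
    df = fiber_thresholds
    if rule in ("sensory", "motor"):
        df = df[df["fiber_class"] == rule]
    elif rule != "min":
        raise ValueError(f"unknown unit-threshold rule {rule!r}")
    out = (
        df.groupby(["muscle", "motor_unit_id"], sort=True)["threshold_ua"]
        .min()
        .reset_index()
    )
    return out


def recruitment_from_thresholds(
    unit_thresholds: Sequence[float] | np.ndarray,
    grid: Sequence[float] | np.ndarray,
    muscle: str = "",
) -> RecruitmentCurve:
    """Step recruitment curve R(a) = #{thresholds <= a} / n."""
    thr = np.asarray(unit_thresholds, float)
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("amplitude grid must be ascending")
    frac = (thr[:, None] <= grid[None, :]).mean(axis=0)
    return RecruitmentCurve(muscle, grid, frac, thr)


def threshold_saturation(
    curve: RecruitmentCurve,
    threshold_level: float = THRESHOLD_LEVEL,
    saturation_level: float = SATURATION_LEVEL,
) -> tuple[float, float]:
    """Smallest grid amplitudes with R >= 10% and R >= 90% (inf sentinel)."""
    def first_at(level: float) -> float:
        hits = np.flatnonzero(curve.fraction >= level - 1e-12)
        return float(curve.amplitudes_ua[hits[0]]) if hits.size else NOT_REACHED

    return first_at(threshold_level), first_at(saturation_level)


def selectivity_index(
    recruitment_by_muscle: Mapping[str, float], target: str
) -> float:
    """Target recruitment minus the mean recruitment of the other muscles."""
    if target not in recruitment_by_muscle:
        raise KeyError(f"target muscle {target!r} not in recruitment table")
    if len(recruitment_by_muscle) < 2:
        raise ValueError("selectivity needs at least two muscles")
    others = [v for m, v in recruitment_by_muscle.items() if m != target]
    for m, v in recruitment_by_muscle.items():
        if not (0.0 - 1e-12 <= v <= 1.0 + 1e-12):
            raise ValueError(f"recruitment of {m} = {v} outside [0, 1]")
    return float(recruitment_by_muscle[target] - np.mean(others))


def si_profile(
    curves: Mapping[str, RecruitmentCurve], target: str
) -> np.ndarray:
    """Selectivity index of ``target`` at every grid amplitude."""
    grid = curves[target].amplitudes_ua
    # sorted order keeps the result bit-identical under muscle reordering
    others = np.array(
        [curves[m].fraction for m in sorted(curves) if m != target]
    )
    return curves[target].fraction - others.mean(axis=0)


def max_selectivity(
    curves: Mapping[str, RecruitmentCurve], target: str
) -> tuple[float, float]:
    """(SI_max, amplitude) over the target's dynamic range.

    The dynamic range spans the target's threshold to its saturation (top of
    the grid when saturation is not reached); ties break toward the lowest
    amplitude.  Returns (nan, nan) if the target never reaches threshold.
    """
    curve = curves[target]
    thr, sat = threshold_saturation(curve)
    if not np.isfinite(thr):
        return float("nan"), float("nan")
    grid = curve.amplitudes_ua
    hi = sat if np.isfinite(sat) else grid[-1]
    in_dr = (grid >= thr - 1e-12) & (grid <= hi + 1e-12)
    si = si_profile(curves, target)
    si_dr = np.where(in_dr, si, -np.inf)
    k = int(np.argmax(si_dr))  # argmax returns the first (lowest-amplitude) tie
    return float(si[k]), float(grid[k])


def metrics_from_curves(
    curves: Mapping[str, RecruitmentCurve], target: str
) -> MuscleMetrics:
    thr, sat = threshold_saturation(curves[target])
    si, amp = max_selectivity(curves, target)
    return MuscleMetrics(target, thr, sat, si, amp)


#: Selection names used for per-mode extreme picks.
SELECTIONS = ("min_threshold", "min_saturation", "max_selectivity")


def sweep_selections(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-(side, mode, muscle) extreme selections over configurations.

    ``metrics`` columns: side, mode, configuration, muscle, threshold_ua,
    saturation_ua, si_max.  Minimum Threshold / Minimum Saturation are the
    argmin of threshold and saturation; Maximum Selectivity Index the argmax
    of si_max.  Ties break toward the lower value of the companion amplitude
    then lexicographic configuration label.
    """
    rows = []
    for (side, mode, muscle), grp in metrics.groupby(
        ["side", "mode", "muscle"], sort=True
    ):
        grp = grp.sort_values("configuration", kind="stable")
        for metric, col, best in (
            ("min_threshold", "threshold_ua", "idxmin"),
            ("min_saturation", "saturation_ua", "idxmin"),
            ("max_selectivity", "si_max", "idxmax"),
        ):
            vals = grp[col]
            if metric == "max_selectivity" and vals.isna().all():
                continue
            k = getattr(vals, best)()
            rows.append(
                {
                    "side": side,
                    "mode": mode,
                    "muscle": muscle,
                    "selection": metric,
                    "configuration": grp.loc[k, "configuration"],
                    "value": grp.loc[k, col],
                }
            )
    return pd.DataFrame(rows)


def frequency_comparison(
    top_configs: pd.DataFrame,
    evaluate: Callable[[str, str, str, float], Mapping[str, float]],
    rates_hz: Sequence[float] = (50.0, 100.0),
) -> pd.DataFrame:
    """Evaluate the top-selectivity configurations at several pulse rates.

    ``top_configs`` columns: side, mode, muscle, configuration (typically the
    ``max_selectivity`` rows of :func:`sweep_selections`).  Configurations
    shared by several muscles are evaluated once per (side, mode, rate) and
    reported once per muscle.  ``evaluate(side, mode, configuration, rate)``
    must return a mapping muscle -> dict with keys ``si_max`` and
    ``si_amplitude_ua``.
    """
    rows = []
    for rate in rates_hz:
        cache: dict[tuple[str, str, str], Mapping] = {}
        for _, row in top_configs.iterrows():
            key = (row["side"], row["mode"], row["configuration"])
            if key not in cache:
                cache[key] = evaluate(*key, rate)
            res = cache[key][row["muscle"]]
            rows.append(
                {
                    "side": row["side"],
                    "mode": row["mode"],
                    "muscle": row["muscle"],
                    "configuration": row["configuration"],
                    "rate_hz": rate,
                    "si_max": res["si_max"],
                    "si_amplitude_ua": res["si_amplitude_ua"],
                }
            )
    return pd.DataFrame(rows)
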