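"""Config-driven orchestration: anatomy -> fields -> thresholds -> analysis.

The pipeline builds the volume conductor and fiber populations, solves one
unit-current monopole field per contact (multipolar configurations follow by
superposition through the shared grounded boundary), searches per-fiber
thresholds, reduces them to motor-unit recruitment curves and muscle metrics,
picks the per-mode extremes (Minimum Threshold, Minimum Saturation, Maximum
Selectivity Index), bootstraps the winning configurations, and runs the
dorsal-vs-ventral and between-mode significance tests.

Stage outputs are cached on disk keyed by a hash of the inputs that produce
them, so re-running with an unchanged config reuses fields and thresholds
and reproduces every output byte-for-byte for a fixed seed.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import stats as stats_mod
from .anatomy import (
    ElectrodeConfiguration,
    FiberPopulation,
    TissueModel,
    build_populations,
    build_volume,
    enumerate_configurations,
)
from .cable import (
    CableDiscretization,
    StimulusProtocol,
    discretize_fiber,
    find_fiber_threshold,
)
from .config import ExperimentConfig, config_hash
from .field import PotentialField, SourceSpec, assemble_system, combine_monopoles, sample_along_fiber, solve_field
from .recruitment import (
    RecruitmentCurve,
    max_selectivity,
    motor_unit_thresholds,
    recruitment_from_thresholds,
    sweep_selections,
    threshold_saturation,
)

__all__ = ["ExperimentResult", "run_experiment", "report_figures"]

log = logging.getLogger("eesim")

#: Metric direction for one-sided dorsal-vs-ventral tests.
_TEST_DIRECTION = {
    "min_threshold": "less",
    "min_saturation": "less",
    "max_selectivity": "greater",
}


@dataclass
class ExperimentResult:
    """All tables of one experiment run."""

    config: ExperimentConfig
    model: TissueModel
    population: FiberPopulation
    fiber_thresholds: pd.DataFrame
    unit_thresholds: pd.DataFrame
    metrics: pd.DataFrame
    selections: pd.DataFrame
    bootstrap: pd.DataFrame
    tests: pd.DataFrame
    curves: dict[tuple[str, str, str], dict[str, RecruitmentCurve]]
    curve_sd: dict[tuple[str, str, str], dict[str, np.ndarray]]
    frequency: pd.DataFrame | None = None
    out_dir: Path | None = None

    def summary(self) -> str:
        lines = ["eesim experiment summary", "=" * 24]
        lines.append(
            f"{len(self.population)} fibers, "
            f"{self.metrics['configuration'].nunique()} configuration(s), "
            f"grid {self.config.amplitude_start_ua:g}-"
            f"{self.config.amplitude_stop_ua:g} uA"
        )
        lines.append("")
        sel = self.bootstrap if len(self.bootstrap) else self.selections
        with pd.option_context("display.width", 120):
            lines.append(sel.to_string(index=False))
        if len(self.tests):
            lines.append("")
            lines.append(self.tests.to_string(index=False))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def selected_configurations(config: ExperimentConfig) -> list[ElectrodeConfiguration]:
    out = []
    for side in config.sides:
        for mode in config.modes:
            for c in enumerate_configurations(side, mode):
                if config.configurations is None or c.label in config.configurations:
                    out.append(c)
    if not out:
        raise ValueError("configuration filter selected nothing")
    return out


def _protocol(config: ExperimentConfig, rate_hz=None, n_pulses=None) -> StimulusProtocol:
    return StimulusProtocol(
        pulse_width_us=config.pulse_width_us,
        per_phase=config.per_phase,
        leading_sign=config.leading_sign,
        rate_hz=rate_hz if rate_hz is not None else config.rate_hz,
        n_pulses=n_pulses if n_pulses is not None else config.n_pulses,
        window_ms=config.window_ms,
        dt_us=config.dt_us,
        recruitment_rule=config.recruitment_rule,
    )


def _solve_monopole(
    model: TissueModel,
    side: str,
    segment: str,
    tol: float,
    cache_dir: Path | None,
    key: str,
) -> PotentialField:
    path = cache_dir / f"field_{side}_{segment}_{key}.npz" if cache_dir else None
    if path is not None and path.exists():
        with np.load(path) as z:
            return PotentialField(
                z["values"], float(z["voxel_size"]), z["origin"], float(z["residual"]),
                label=f"{side}:{segment}",
            )
    t0 = time.perf_counter()
    source = SourceSpec(shares=(((side, segment), 1.0),), label=f"{side}:{segment}")
    fld = solve_field(assemble_system(model, source), tol=tol)
    log.info(
        "solved monopole %s/%s in %.1fs (residual %.2e)",
        side, segment, time.perf_counter() - t0, fld.residual,
    )
    if path is not None:
        np.savez_compressed(
            path,
            values=fld.values,
            voxel_size=fld.voxel_size,
            origin=fld.origin,
            residual=fld.residual,
        )
    return fld


def _build_cables(population: FiberPopulation) -> dict[str, CableDiscretization]:
    return {
        f.fiber_id: discretize_fiber(f.xyz, f.diameter_um, f.fiber_class)
        for f in population
    }


def _config_thresholds(
    cfg: ElectrodeConfiguration,
    fld: PotentialField,
    population: FiberPopulation,
    cables: Mapping[str, CableDiscretization],
    protocol: StimulusProtocol,
    grid: np.ndarray,
    cache_dir: Path | None,
    key: str,
) -> pd.DataFrame:
    path = (
        cache_dir / f"thr_{cfg.side}_{cfg.label}_{key}.csv" if cache_dir else None
    )
    if path is not None and path.exists():
        return pd.read_csv(path)
    t0 = time.perf_counter()
    rows = []
    for f in population:
        cab = cables[f.fiber_id]
        ve = sample_along_fiber(fld, cab.xyz, f.fiber_id)
        thr = find_fiber_threshold(cab, ve, protocol, grid)
        rows.append(
            {
                "side": cfg.side,
                "mode": cfg.mode,
                "configuration": cfg.label,
                "fiber_id": f.fiber_id,
                "muscle": f.muscle,
                "fiber_class": f.fiber_class,
                "motor_unit_id": f.motor_unit_id,
                "threshold_ua": thr,
            }
        )
    df = pd.DataFrame(rows)
    log.info(
        "thresholds %s/%s: %d fibers in %.1fs",
        cfg.side, cfg.label, len(df), time.perf_counter() - t0,
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df


def _curves_for(
    unit_thr: pd.DataFrame, grid: np.ndarray, muscles
) -> dict[str, RecruitmentCurve]:
    out = {}
    for mu in muscles:
        thr = unit_thr.loc[unit_thr["muscle"] == mu, "threshold_ua"].to_numpy()
        out[mu] = recruitment_from_thresholds(thr, grid, mu)
    return out


def _seed_for(seed: int, *labels: str) -> int:
    h = 0
    for lab in labels:
        h = zlib.crc32(lab.encode(), h)
    return (seed * 1_000_003 + h) % (2**31 - 1)


# ---------------------------------------------------------------------------
# main entry
# ---------------------------------------------------------------------------


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> ExperimentResult:
    """Run the full experiment described by ``config``.

    When ``out_dir`` is given, writes a config snapshot, a log, tidy CSVs of
    metrics/selections/bootstrap/tests, an HDF5 store of recruitment curves,
    and reuses cached stage outputs from previous runs unless ``overwrite``.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    cache_dir = None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        cache_dir = out_path / "cache"
        cache_dir.mkdir(exist_ok=True)
        if overwrite:
            for p in cache_dir.iterdir():
                p.unlink()
        fh = logging.FileHandler(out_path / "log.txt")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
        log.setLevel(logging.INFO)
        config.to_yaml(out_path / "config.yaml")
    try:
        return _run(config, out_path, cache_dir)
    finally:
        if out_path is not None:
            log.removeHandler(fh)
            fh.close()


def _run(config, out_path, cache_dir) -> ExperimentResult:
    t_start = time.perf_counter()
    grid = config.amplitude_grid
    muscles = list(config.pools.muscles)
    log.info("building anatomy (voxel %.3g mm)", config.spec.voxel_size)
    model = build_volume(config.spec, config.conductivities)
    population = build_populations(
        config.spec, config.pools, config.n_per_pool, seed=config.seed
    )
    cables = _build_cables(population)
    configs = selected_configurations(config)

    anatomy_key = config_hash(
        config.spec, config.conductivities, config.solver_tol
    )
    protocol = _protocol(config)
    thr_key = config_hash(
        config.spec,
        config.conductivities,
        config.pools.pools,
        config.n_per_pool,
        config.seed,
        config.solver_tol,
        config.pulse_width_us,
        config.per_phase,
        config.leading_sign,
        config.dt_us,
        config.window_ms,
        config.n_pulses,
        config.rate_hz if config.n_pulses > 1 else None,
        config.recruitment_rule,
        list(grid),
    )

    # fields: one monopole per needed contact, multipoles by superposition
    needed = sorted({(c.side, seg) for c in configs for seg, _ in c.contacts})
    monopoles: dict[tuple[str, str], PotentialField] = {}
    for side, seg in needed:
        monopoles[(side, seg)] = _solve_monopole(
            model, side, seg, config.solver_tol, cache_dir, anatomy_key
        )

    # thresholds and curves per configuration
    fiber_rows, unit_rows, metric_rows = [], [], []
    curves: dict[tuple[str, str, str], dict[str, RecruitmentCurve]] = {}
    for cfg in configs:
        fld = combine_monopoles(
            {seg: monopoles[(cfg.side, seg)] for seg, _ in cfg.contacts}, cfg
        )
        fib = _config_thresholds(
            cfg, fld, population, cables, protocol, grid, cache_dir, thr_key
        )
        fiber_rows.append(fib)
        units = motor_unit_thresholds(fib, rule=config.unit_rule)
        units.insert(0, "side", cfg.side)
        units.insert(1, "mode", cfg.mode)
        units.insert(2, "configuration", cfg.label)
        unit_rows.append(units)
        cur = _curves_for(units, grid, muscles)
        curves[(cfg.side, cfg.mode, cfg.label)] = cur
        for mu in muscles:
            thr, sat = threshold_saturation(cur[mu])
            si, amp = max_selectivity(cur, mu)
            metric_rows.append(
                {
                    "side": cfg.side,
                    "mode": cfg.mode,
                    "configuration": cfg.label,
                    "muscle": mu,
                    "threshold_ua": thr,
                    "saturation_ua": sat,
                    "si_max": si,
                    "si_amplitude_ua": amp,
                }
            )

    fiber_thresholds = pd.concat(fiber_rows, ignore_index=True)
    unit_thresholds = pd.concat(unit_rows, ignore_index=True)
    metrics = pd.DataFrame(metric_rows).sort_values(
        ["side", "mode", "configuration", "muscle"], kind="stable", ignore_index=True
    )
    selections = sweep_selections(metrics).sort_values(
        ["side", "mode", "muscle", "selection"], kind="stable", ignore_index=True
    )

    # bootstrap the winning configurations (deduplicated)
    boot_cache: dict[tuple[str, str, str], dict] = {}
    curve_sd: dict[tuple[str, str, str], dict[str, np.ndarray]] = {}

    def _boot(side: str, mode: str, label: str):
        key = (side, mode, label)
        if key not in boot_cache:
            ut = unit_thresholds[
                (unit_thresholds["side"] == side)
                & (unit_thresholds["configuration"] == label)
                & (unit_thresholds["mode"] == mode)
            ]
            pools = {
                mu: ut.loc[ut["muscle"] == mu, "threshold_ua"].to_numpy()
                for mu in muscles
            }
            bseed = _seed_for(config.seed, side, mode, label)
            boot_cache[key] = stats_mod.bootstrap_metrics(
                pools, grid, K=config.bootstrap_K, m=config.bootstrap_m, seed=bseed
            )
            curve_sd[key] = stats_mod.bootstrap_recruitment_sd(
                pools, grid, K=config.bootstrap_K, m=config.bootstrap_m, seed=bseed
            )
        return boot_cache[key]

    metric_of = {
        "min_threshold": "threshold_ua",
        "min_saturation": "saturation_ua",
        "max_selectivity": "si_max",
    }
    boot_rows = []
    for _, row in selections.iterrows():
        bs = _boot(row["side"], row["mode"], row["configuration"])
        br = bs[row["muscle"]][metric_of[row["selection"]]]
        finite = br.replicates[np.isfinite(br.replicates)]
        boot_rows.append(
            {
                **row,
                "boot_mean": float(np.mean(finite)) if finite.size else np.nan,
                "boot_sd": float(np.std(finite, ddof=1)) if finite.size > 1 else np.nan,
                "n_replicates": int(br.replicates.size),
            }
        )
    bootstrap = pd.DataFrame(boot_rows)

    tests = _significance_tests(config, selections, boot_cache, metric_of)

    frequency = None
    if config.frequency_rates_hz:
        frequency = _frequency_stage(
            config, model, population, cables, monopoles, selections, cache_dir
        )

    result = ExperimentResult(
        config=config,
        model=model,
        population=population,
        fiber_thresholds=fiber_thresholds,
        unit_thresholds=unit_thresholds,
        metrics=metrics,
        selections=selections,
        bootstrap=bootstrap,
        tests=tests,
        curves=curves,
        curve_sd=curve_sd,
        frequency=frequency,
        out_dir=out_path,
    )
    if out_path is not None:
        _write_outputs(result, out_path)
    log.info("experiment finished in %.1fs", time.perf_counter() - t_start)
    return result


def _significance_tests(config, selections, boot_cache, metric_of) -> pd.DataFrame:
    """Dorsal-vs-ventral one-sided t tests and between-mode ANOVA."""
    rows = []

    def reps(side, mode, label, muscle, metric):
        r = boot_cache[(side, mode, label)][muscle][metric_of[metric]].replicates
        return r[np.isfinite(r)]

    sel = selections.set_index(["side", "mode", "muscle", "selection"])["value"]
    cfg_of = selections.set_index(["side", "mode", "muscle", "selection"])[
        "configuration"
    ]
    if {"dorsal", "ventral"} <= set(config.sides):
        for mode in config.modes:
            for mu in config.pools.muscles:
                for metric, direction in _TEST_DIRECTION.items():
                    try:
                        ref = float(sel[("ventral", mode, mu, metric)])
                        lab = cfg_of[("dorsal", mode, mu, metric)]
                    except KeyError:
                        continue
                    r = reps("dorsal", mode, lab, mu, metric)
                    if r.size < 2 or not np.isfinite(ref):
                        continue
                    p = stats_mod.one_sided_t_test(r, ref, alternative=direction)
                    rows.append(
                        {
                            "test": "dorsal_vs_ventral",
                            "mode": mode,
                            "muscle": mu,
                            "selection": metric,
                            "direction": direction,
                            "p_value": p,
                            "stars": stats_mod.significance_stars(p),
                        }
                    )
    if len(config.modes) >= 2:
        for side in config.sides:
            for mu in config.pools.muscles:
                for metric in _TEST_DIRECTION:
                    groups = []
                    for mode in config.modes:
                        try:
                            lab = cfg_of[(side, mode, mu, metric)]
                        except KeyError:
                            continue
                        r = reps(side, mode, lab, mu, metric)
                        if r.size >= 2:
                            groups.append(r)
                    if len(groups) < 2:
                        continue
                    F, p, _ = stats_mod.anova_bonferroni(groups)
                    rows.append(
                        {
                            "test": "between_modes_anova",
                            "mode": "all",
                            "muscle": mu,
                            "selection": metric,
                            "direction": f"side={side}",
                            "p_value": p,
                            "stars": stats_mod.significance_stars(p),
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "test", "mode", "muscle", "selection", "direction", "p_value", "stars",
        ],
    )


def _frequency_stage(
    config, model, population, cables, monopoles, selections, cache_dir
) -> pd.DataFrame:
    """Re-evaluate top-selectivity configurations under pulse trains."""
    from .recruitment import frequency_comparison

    top = selections[selections["selection"] == "max_selectivity"][
        ["side", "mode", "muscle", "configuration"]
    ].reset_index(drop=True)
    grid = config.amplitude_grid
    muscles = list(config.pools.muscles)

    def evaluate(side, mode, label, rate):
        cfg = next(
            c
            for c in enumerate_configurations(side, mode)
            if c.label == label
        )
        for seg, _ in cfg.contacts:
            if (side, seg) not in monopoles:
                monopoles[(side, seg)] = _solve_monopole(
                    model, side, seg, config.solver_tol, cache_dir,
                    config_hash(config.spec, config.conductivities, config.solver_tol),
                )
        fld = combine_monopoles(
            {seg: monopoles[(side, seg)] for seg, _ in cfg.contacts}, cfg
        )
        prot = _protocol(config, rate_hz=rate, n_pulses=config.frequency_n_pulses)
        key = config_hash(
            config.spec, config.conductivities, config.seed, config.n_per_pool,
            rate, config.frequency_n_pulses, list(grid), side, label,
        )
        fib = _config_thresholds(
            cfg, fld, population, cables, prot, grid, cache_dir, key
        )
        units = motor_unit_thresholds(fib, rule=config.unit_rule)
        cur = _curves_for(units, grid, muscles)
        out = {}
        for mu in muscles:
            si, amp = max_selectivity(cur, mu)
            out[mu] = {"si_max": si, "si_amplitude_ua": amp}
        return out

    return frequency_comparison(top, evaluate, rates_hz=config.frequency_rates_hz)


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------


def _write_outputs(result: ExperimentResult, out_path: Path) -> None:
    import h5py

    result.metrics.to_csv(out_path / "metrics.csv", index=False)
    result.selections.to_csv(out_path / "selections.csv", index=False)
    result.bootstrap.to_csv(out_path / "bootstrap.csv", index=False)
    result.tests.to_csv(out_path / "tests.csv", index=False)
    result.unit_thresholds.to_csv(out_path / "unit_thresholds.csv", index=False)
    result.fiber_thresholds.to_csv(out_path / "fiber_thresholds.csv", index=False)
    if result.frequency is not None:
        result.frequency.to_csv(out_path / "frequency.csv", index=False)
    with h5py.File(out_path / "curves.h5", "w") as h5:
        for (side, mode, label), cur in result.curves.items():
            grp = h5.create_group(f"{side}/{mode}/{label}")
            first = next(iter(cur.values()))
            grp.create_dataset("amplitudes_ua", data=first.amplitudes_ua)
            for mu, c in cur.items():
                g = grp.create_group(mu)
                g.create_dataset("fraction", data=c.fraction)
                g.create_dataset("unit_thresholds_ua", data=c.unit_thresholds)
                sd = result.curve_sd.get((side, mode, label), {}).get(mu)
                if sd is not None:
                    g.create_dataset("fraction_sd", data=sd)


def report_figures(result: ExperimentResult, out_dir: str | Path) -> dict:
    """Render recruitment-curve, selectivity and selection-bar figures.

    Returns a dict with the created files and the shaded-band arrays used
    (band half-width = the stored bootstrap SD of the recruitment fraction).
    Panels with missing metrics are skipped with a logged warning.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: dict[str, Path] = {}
    bands: dict = {}
    if not result.curves:
        log.warning("no recruitment curves to plot; skipping figures")
        return {"files": created, "bands": bands}

    for key in sorted(result.curve_sd):
        side, mode, label = key
        cur = result.curves[key]
        fig, axes = plt.subplots(
            1, 2, figsize=(9, 3.2), constrained_layout=True
        )
        for mu, c in cur.items():
            line, = axes[0].plot(c.amplitudes_ua, c.fraction, label=mu)
            sd = result.curve_sd[key].get(mu)
            if sd is not None:
                axes[0].fill_between(
                    c.amplitudes_ua,
                    c.fraction - sd,
                    c.fraction + sd,
                    alpha=0.25,
                    color=line.get_color(),
                )
                bands[(side, mode, label, mu)] = sd
            from .recruitment import si_profile

            axes[1].plot(c.amplitudes_ua, si_profile(cur, mu), label=mu)
        axes[0].set(
            xlabel="amplitude (uA)", ylabel="recruited fraction",
            title=f"{side} {mode} {label}", ylim=(-0.02, 1.02),
        )
        axes[1].set(xlabel="amplitude (uA)", ylabel="selectivity index",
                    ylim=(-1.02, 1.02))
        axes[1].legend(fontsize=7)
        path = out / f"recruitment_{side}_{mode}_{label}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        created[path.name] = path

    if len(result.bootstrap):
        for metric, grp in result.bootstrap.groupby("selection"):
            fig, ax = plt.subplots(figsize=(6, 3.2), constrained_layout=True)
            labels = [
                f"{r.side[0]}EES {r.muscle}\n{r['mode'][:3]} {r.configuration}"
                for _, r in grp.iterrows()
            ]
            y = grp["boot_mean"].to_numpy()
            err = grp["boot_sd"].to_numpy()
            ax.bar(range(len(y)), y, yerr=err, capsize=3)
            ax.set_xticks(range(len(y)), labels, fontsize=6, rotation=45)
            ax.set_title(metric)
            path = out / f"selection_{metric}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            created[path.name] = path

    return {"files": created, "bands": bands}
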