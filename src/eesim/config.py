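"""Experiment configuration: one object fully determines a run.

Presets:

``paper``
    The full study conditions: 0.1 mm voxels, 40 motor units per muscle, the
    complete 25-configuration catalog per side, 25 uA amplitude steps and
    K = 10,000 bootstrap replicates.
``fast``
    Desk-scale preset for directional comparisons: 0.2 mm voxels, 8 units
    per muscle, two monopolar configurations per side, the full 25 uA
    amplitude grid, K = 200.
``tiny``
    Smoke-test preset (minutes of CPU): 4 units, one configuration per side,
    200 uA steps, loose solver tolerance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .anatomy import ConductivityTable, MotorPoolTable, SpinalCordSpec

__all__ = ["ExperimentConfig", "config_hash"]


@dataclass(frozen=True)
class ExperimentConfig:
    spec: SpinalCordSpec = field(default_factory=SpinalCordSpec)
    conductivities: ConductivityTable = field(default_factory=ConductivityTable)
    pools: MotorPoolTable = field(default_factory=MotorPoolTable)
    n_per_pool: int = 40
    sides: tuple[str, ...] = ("dorsal", "ventral")
    modes: tuple[str, ...] = ("monopolar", "bipolar", "tripolar")
    #: Optional subset of configuration labels (e.g. ("L4", "L5")); None = all.
    configurations: tuple[str, ...] | None = None
    # amplitude grid in uA
    amplitude_start_ua: float = 25.0
    amplitude_step_ua: float = 25.0
    amplitude_stop_ua: float = 1000.0
    # stimulus
    pulse_width_us: float = 200.0
    per_phase: bool = True
    leading_sign: int = -1
    dt_us: float = 5.0
    window_ms: float = 10.0
    rate_hz: float = 50.0
    n_pulses: int = 1  # 1 = single-pulse recruitment (rate only labels runs)
    recruitment_rule: str = "every_pulse"
    unit_rule: str = "min"  # motor-unit threshold rule
    # statistics
    bootstrap_K: int = 10_000
    bootstrap_m: int = 40
    # frequency comparison on top-selectivity configurations; empty = skip
    frequency_rates_hz: tuple[float, ...] = ()
    frequency_n_pulses: int = 5
    # numerics
    solver_tol: float = 1e-8
    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def amplitude_grid(self) -> np.ndarray:
        return np.arange(
            self.amplitude_start_ua,
            self.amplitude_stop_ua + 1e-9,
            self.amplitude_step_ua,
        )

    def replace(self, **kwargs) -> "ExperimentConfig":
        return dataclasses.replace(self, **kwargs)

    # -- presets ---------------------------------------------------------
    @classmethod
    def paper(cls, seed: int = 0) -> "ExperimentConfig":
        return cls(seed=seed, frequency_rates_hz=(50.0, 100.0))

    @classmethod
    def fast(cls, seed: int = 0) -> "ExperimentConfig":
        return cls(
            spec=SpinalCordSpec(voxel_size=0.2, bath_margin=3.0, z_margin=1.5),
            n_per_pool=8,
            modes=("monopolar",),
            configurations=("L4", "L5"),
            bootstrap_K=200,
            bootstrap_m=8,
            seed=seed,
        )

    @classmethod
    def tiny(cls, seed: int = 0) -> "ExperimentConfig":
        return cls(
            spec=SpinalCordSpec(voxel_size=0.2, bath_margin=1.5, z_margin=1.0),
            n_per_pool=4,
            modes=("monopolar",),
            configurations=("L4",),
            amplitude_start_ua=200.0,
            amplitude_step_ua=200.0,
            amplitude_stop_ua=1000.0,
            bootstrap_K=100,
            bootstrap_m=4,
            solver_tol=1e-6,
            window_ms=6.0,
            seed=seed,
        )

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "ExperimentConfig":
        try:
            return {"paper": cls.paper, "fast": cls.fast, "tiny": cls.tiny}[name](
                seed=seed
            )
        except KeyError:
            raise ValueError(f"unknown preset {name!r}") from None

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spec"]["segment_lengths"] = dict(self.spec.segment_lengths)
        d["pools"] = {m: dict(v) for m, v in self.pools.pools.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "spec" in d:
            spec = dict(d["spec"])
            for k, v in spec.items():
                if isinstance(v, list):
                    spec[k] = tuple(v)
            d["spec"] = SpinalCordSpec(**spec)
        if "conductivities" in d:
            d["conductivities"] = ConductivityTable(**d["conductivities"])
        if "pools" in d:
            d["pools"] = MotorPoolTable(pools=d["pools"])
        for k in (
            "sides",
            "modes",
            "configurations",
            "frequency_rates_hz",
        ):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(*objects) -> str:
    """Deterministic short hash of dataclasses / dicts (cache keying)."""
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"unhashable config object {type(o)}")

    text = json.dumps(objects, default=default, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
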