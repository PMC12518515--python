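"""Ion-channel kinetics and fiber-class parameter tables.

Gating-rate functions follow the mammalian myelinated-axon node formulation
(36-37 degC rates) for fast Na (m, h), persistent Na (p), and slow K (s); the
fast K (n) gate uses human-node-type kinetics and the HCN (q) gate a slow
Boltzmann activation.  Maximal conductances, reversal potentials and the
sensory/motor differences are *data*, shipped in editable YAML tables under
``eesim/params/`` with per-entry provenance notes, and loaded into
:class:`ChannelParams`.

All voltages in mV, rates in 1/ms, conductances in S/cm^2 as loaded
(converted to mS/cm^2 internally by the cable solver).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "GATES",
    "ChannelParams",
    "load_channel_params",
    "gate_rates",
    "steady_state",
]

COMPARTMENT_KINDS = ("NODE", "MYSA", "FLUT", "STIN")
#: Channel name -> (gate name, gate exponent); leak has no gate.
CHANNELS = {
    "naf": ("mh", None),  # m^3 h
    "nap": ("p", 3),
    "ks": ("s", 1),
    "kf": ("n", 4),
    "h": ("q", 1),
    "leak": (None, None),
}
GATES = ("m", "h", "p", "s", "n", "q")


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x/y)) with the removable singularity handled."""
    x = np.asarray(x, float)
    with np.errstate(over="ignore", invalid="ignore"):
        out = x / (-np.expm1(-x / y))
    small = np.abs(x / y) < 1e-7
    return np.where(small, y * (1.0 + x / (2.0 * y)), out)


def gate_rates(v: np.ndarray, shift_na_act: float = 0.0) -> dict[str, tuple]:
    """alpha/beta for every gate at membrane voltage ``v`` (mV).

    ``shift_na_act`` shifts the fast-Na activation gate (m) toward more
    hyperpolarized voltages (positive shift = more excitable), the lever used
    by the sensory parameter table.  The persistent-Na and inactivation gates
    are left unshifted so the resting state stays stable.
    """
    v = np.asarray(v, float)
    vm = v + shift_na_act
    a_m = 6.57 * _vtrap(vm + 20.4, 10.3)
    b_m = 0.304 * _vtrap(-(vm + 25.7), 9.16)
    a_h = 0.34 * _vtrap(-(v + 114.0), 11.0)
    b_h = 12.6 / (1.0 + np.exp(-(v + 31.8) / 13.4))
    a_p = 0.0353 * _vtrap(v + 27.0, 10.2)
    b_p = 0.000883 * _vtrap(-(v + 34.0), 10.0)
    a_s = 0.3 / (1.0 + np.exp(-(v + 53.0) / 5.0))
    b_s = 0.03 / (1.0 + np.exp(-(v + 90.0) / 1.0))
    a_n = 0.0462 * _vtrap(v + 83.2, 1.1)
    b_n = 0.0824 * _vtrap(-(v + 66.0), 10.5)
    # slow HCN activation: Boltzmann steady state, ~100 ms time constant
    q_inf = 1.0 / (1.0 + np.exp((v + 94.0) / 11.0))
    tau_q = np.full_like(v, 100.0)
    a_q = q_inf / tau_q
    b_q = (1.0 - q_inf) / tau_q
    return {
        "m": (a_m, b_m),
        "h": (a_h, b_h),
        "p": (a_p, b_p),
        "s": (a_s, b_s),
        "n": (a_n, b_n),
        "q": (a_q, b_q),
    }


def steady_state(v: float, shift_na_act: float = 0.0) -> dict[str, float]:
    """Gate steady states x_inf = alpha / (alpha + beta) at voltage ``v``."""
    rates = gate_rates(np.asarray([v]), shift_na_act)
    return {g: float((a / (a + b))[0]) for g, (a, b) in rates.items()}


@dataclass(frozen=True)
class ChannelParams:
    """One fiber class's channel parameterization."""

    fiber_class: str
    v_rest: float  # mV
    e_na: float
    e_k: float
    e_leak: float
    e_h: float
    shift_na_act: float  # mV, applied to m and p gates
    #: kind -> channel -> maximal conductance, S/cm^2
    conductances: dict[str, dict[str, float]]

    def cache_key(self) -> tuple:
        """Hashable identity of the parameter set (resting-state caching)."""
        cond = tuple(
            (kind, tuple(sorted(table.items())))
            for kind, table in sorted(self.conductances.items())
        )
        return (
            self.fiber_class,
            self.v_rest,
            self.e_na,
            self.e_k,
            self.e_leak,
            self.e_h,
            self.shift_na_act,
            cond,
        )

    def g(self, kind: str, channel: str) -> float:
        return float(self.conductances.get(kind, {}).get(channel, 0.0))

    def reversal(self, channel: str) -> float:
        return {
            "naf": self.e_na,
            "nap": self.e_na,
            "ks": self.e_k,
            "kf": self.e_k,
            "h": self.e_h,
            "leak": self.e_leak,
        }[channel]


def load_channel_params(fiber_class: str | Path) -> ChannelParams:
    """Load a parameter table by class name (``motor``/``sensory``) or path."""
    if isinstance(fiber_class, Path) or str(fiber_class).endswith(".yaml"):
        text = Path(fiber_class).read_text()
    else:
        text = (
            resources.files("eesim") / "params" / f"{fiber_class}.yaml"
        ).read_text()
    raw = yaml.safe_load(text)
    cond = {
        kind: {ch: float(g) for ch, g in table.items()}
        for kind, table in raw["conductances_S_per_cm2"].items()
    }
    for kind in cond:
        if kind not in COMPARTMENT_KINDS:
            raise ValueError(f"unknown compartment kind {kind!r} in table")
        for ch in cond[kind]:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r} in table")
    e = raw["reversal_potentials_mV"]
    return ChannelParams(
        fiber_class=str(raw["fiber_class"]),
        v_rest=float(raw["v_rest_mV"]),
        e_na=float(e["na"]),
        e_k=float(e["k"]),
        e_leak=float(e["leak"]),
        e_h=float(e["h"]),
        shift_na_act=float(raw.get("na_activation_shift_mV", 0.0)),
        conductances=cond,
    )
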