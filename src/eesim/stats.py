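"""Bootstrap resampling of motor-unit thresholds and significance tests.

Each bootstrap replicate redraws ``m`` motor units per muscle with
replacement (the unit's sensory and motor fibers travel together, since unit
thresholds already combine them), recomputes the muscle's threshold,
saturation and maximum selectivity index, and the mean +/- SD across the
``K`` replicates summarizes each metric.  The t test and one-way ANOVA with
Bonferroni correction operate on those replicate sets, mirroring a common
reporting convention; note that bootstrap replicates are not independent
observations, so these p-values overstate significance — percentile
confidence intervals are available as a calibrated alternative.

Random streams are derived deterministically from one root seed and the
(muscle) label, so results are byte-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .recruitment import (
    NOT_REACHED,
    SATURATION_LEVEL,
    THRESHOLD_LEVEL,
)

__all__ = [
    "BootstrapResult",
    "bootstrap_metrics",
    "bootstrap_recruitment_sd",
    "one_sided_t_test",
    "anova_bonferroni",
    "percentile_ci",
    "significance_stars",
]

DEFAULT_K = 10_000
DEFAULT_M = 40


@dataclass
class BootstrapResult:
    metric: str
    muscle: str
    replicates: np.ndarray  # (K,)
    resample_size: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1))


def _child_rng(root_seed: int, label: str) -> np.random.Generator:
    tag = zlib.crc32(label.encode())
    return np.random.default_rng(np.random.SeedSequence([root_seed, tag]))


def _level_amplitude(frac: np.ndarray, grid: np.ndarray, level: float) -> np.ndarray:
    """Per-replicate smallest grid amplitude with recruitment >= level."""
    reached = frac >= level - 1e-12
    idx = reached.argmax(axis=-1)
    out = grid[idx]
    return np.where(reached.any(axis=-1), out, NOT_REACHED)


def bootstrap_metrics(
    unit_thresholds: Mapping[str, np.ndarray],
    grid: Sequence[float] | np.ndarray,
    K: int = DEFAULT_K,
    m: int = DEFAULT_M,
    seed: int = 0,
    chunk: int = 1000,
) -> dict[str, dict[str, BootstrapResult]]:
    """Bootstrap threshold, saturation and SI_max for every muscle.

    ``unit_thresholds`` maps muscle -> array of unit thresholds (uA, inf for
    never-recruited units).  Returns ``{muscle: {metric: BootstrapResult}}``
    with metrics ``threshold_ua``, ``saturation_ua``, ``si_max``.
    """
    if K < 1 or m < 1:
        raise ValueError("K and m must be >= 1")
    grid = np.asarray(grid, float)
    muscles = list(unit_thresholds)
    thr = {mu: np.asarray(unit_thresholds[mu], float) for mu in muscles}
    G = grid.size

    reps = {
        mu: {k: np.empty(K) for k in ("threshold_ua", "saturation_ua", "si_max")}
        for mu in muscles
    }
    rngs = {mu: _child_rng(seed, mu) for mu in muscles}
    for lo in range(0, K, chunk):
        hi = min(lo + chunk, K)
        kk = hi - lo
        frac = np.empty((len(muscles), kk, G))
        for j, mu in enumerate(muscles):
            pool = thr[mu]
            draw = pool[rngs[mu].integers(0, pool.size, size=(kk, m))]
            frac[j] = (draw[:, :, None] <= grid[None, None, :]).mean(axis=1)
        for j, mu in enumerate(muscles):
            t = _level_amplitude(frac[j], grid, THRESHOLD_LEVEL)
            s = _level_amplitude(frac[j], grid, SATURATION_LEVEL)
            reps[mu]["threshold_ua"][lo:hi] = t
            reps[mu]["saturation_ua"][lo:hi] = s
            if len(muscles) > 1:
                others = frac[[i for i in range(len(muscles)) if i != j]].mean(axis=0)
                si = frac[j] - others
                top = np.where(np.isfinite(s), s, grid[-1])
                in_dr = (grid[None, :] >= t[:, None] - 1e-12) & (
                    grid[None, :] <= top[:, None] + 1e-12
                )
                si_dr = np.where(in_dr, si, -np.inf)
                best = si_dr.max(axis=1)
                reps[mu]["si_max"][lo:hi] = np.where(
                    np.isfinite(t), best, np.nan
                )
            else:
                reps[mu]["si_max"][lo:hi] = np.nan

    return {
        mu: {
            metric: BootstrapResult(metric, mu, reps[mu][metric], m, seed)
            for metric in reps[mu]
        }
        for mu in muscles
    }


def bootstrap_recruitment_sd(
    unit_thresholds: Mapping[str, np.ndarray],
    grid: Sequence[float] | np.ndarray,
    K: int = DEFAULT_K,
    m: int = DEFAULT_M,
    seed: int = 0,
    chunk: int = 1000,
) -> dict[str, np.ndarray]:
    """Bootstrap SD of the recruitment fraction at every grid amplitude
    (the shaded band of recruitment-curve figures)."""
    grid = np.asarray(grid, float)
    out: dict[str, np.ndarray] = {}
    for mu, pool in unit_thresholds.items():
        pool = np.asarray(pool, float)
        rng = _child_rng(seed, f"curve:{mu}")
        s1 = np.zeros(grid.size)
        s2 = np.zeros(grid.size)
        for lo in range(0, K, chunk):
            kk = min(chunk, K - lo)
            draw = pool[rng.integers(0, pool.size, size=(kk, m))]
            frac = (draw[:, :, None] <= grid[None, None, :]).mean(axis=1)
            s1 += frac.sum(axis=0)
            s2 += (frac**2).sum(axis=0)
        var = (s2 - s1**2 / K) / (K - 1) if K > 1 else np.zeros_like(s1)
        out[mu] = np.sqrt(np.maximum(var, 0.0))
    return out


def one_sided_t_test(
    replicates: np.ndarray,
    reference: float,
    alternative: str = "less",
) -> float:
    """One-sample one-sided t test of replicates against a point reference.

    ``alternative='less'`` tests whether the replicate mean is below the
    reference (lower-is-better metrics).  Degenerate (zero-variance)
    replicates give p in {0, 1} by the sign of mean - reference.
    """
    x = np.asarray(replicates, float)
    if x.size == 0:
        raise ValueError("empty replicate set")
    if np.std(x, ddof=1 if x.size > 1 else 0) == 0:
        delta = float(np.mean(x) - reference)
        if delta == 0:
            return 0.5
        favored = delta < 0 if alternative == "less" else delta > 0
        return 0.0 if favored else 1.0
    res = scipy.stats.ttest_1samp(x, reference, alternative=alternative)
    return float(res.pvalue)


def anova_bonferroni(
    groups: Sequence[np.ndarray],
    m_comparisons: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t tests.

    Returns (F, p_anova, adjusted pairwise p matrix in the order of
    ``itertools.combinations`` of group indices).  The adjusted p is
    ``min(1, m * raw_p)`` with ``m`` defaulting to the number of pairs.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    if all(np.ptp(np.concatenate(groups)) == 0 for _ in (0,)):
        F, p = 0.0, 1.0
    else:
        F, p = scipy.stats.f_oneway(*groups)
        F, p = float(F), float(p)
    import itertools

    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = m_comparisons if m_comparisons is not None else len(pairs)
    adj = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        if np.std(groups[i]) == 0 and np.std(groups[j]) == 0:
            raw = 1.0 if np.mean(groups[i]) == np.mean(groups[j]) else 0.0
        else:
            raw = float(scipy.stats.ttest_ind(groups[i], groups[j]).pvalue)
        adj[k] = min(1.0, m * raw)
    return F, p, adj


def percentile_ci(
    replicates: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval."""
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(np.asarray(replicates, float), [a, 1.0 - a])
    return float(lo), float(hi)


def significance_stars(p: float) -> str:
    """Reporting convention: * for p < 0.05, *** for p < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""
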