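"""Quasi-static extracellular field solver.

Solves the anisotropic Laplace problem div(sigma grad V) = 0 on the voxel
grid of a :class:`~eesim.anatomy.TissueModel` with a finite-volume 7-point
discretization: face conductances are harmonic means of the adjacent voxels'
tensors projected on the face normal (n . sigma . n), the standard scheme for
discontinuous coefficients.  Electrode contacts inject a prescribed total
current distributed uniformly over their footprint voxels; the grounded
(Dirichlet V = 0) mask — by default the outer boundary of the enlarged saline
bath — realizes the distant monopolar return.

Unit current is 1 uA; potentials are reported in mV per uA injected, and by
quasi-static linearity every stimulus amplitude is a scalar multiple of the
unit solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import map_coordinates

from .anatomy import ElectrodeConfiguration, TissueModel

__all__ = [
    "SourceSpec",
    "LinearSystem",
    "PotentialField",
    "FieldSolveError",
    "assemble_system",
    "solve_field",
    "solve_configuration",
    "combine_monopoles",
    "sample_along_fiber",
]

#: Internal unit stimulus in uA; all amplitudes scale linearly from it.
I_UNIT_UA = 1.0


class FieldSolveError(RuntimeError):
    """Solver failed to reach tolerance; carries the residual history."""

    def __init__(self, message: str, residuals: np.ndarray):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class SourceSpec:
    """Signed current shares per contact key ``(side, segment)``.

    Shares sum to zero when all returns are modeled; a monopolar source has a
    single +1 share, its return being absorbed by the grounded boundary.
    """

    shares: tuple[tuple[tuple[str, str], float], ...]
    label: str = ""

    @classmethod
    def from_configuration(cls, config: ElectrodeConfiguration) -> "SourceSpec":
        shares = tuple(
            ((config.side, seg), share) for seg, share in config.contacts
        )
        return cls(shares=shares, label=f"{config.side}:{config.label}")

    def net_share(self) -> float:
        return float(sum(s for _, s in self.shares))


@dataclass
class LinearSystem:
    """Assembled finite-volume system A V = b over non-Dirichlet voxels."""

    A: sp.csr_matrix
    b: np.ndarray
    unknown_index: np.ndarray  # flat grid index of each unknown
    shape: tuple[int, int, int]
    voxel_size: float
    origin: np.ndarray
    label: str = ""


@dataclass
class PotentialField:
    """Extracellular potential (mV per uA injected) on the voxel grid."""

    values: np.ndarray  # (nx, ny, nz), zero at grounded/excluded voxels
    voxel_size: float
    origin: np.ndarray
    residual: float
    label: str = ""
    i_unit_ua: float = I_UNIT_UA

    def __mul__(self, k: float) -> "PotentialField":
        return PotentialField(
            self.values * k, self.voxel_size, self.origin, self.residual, self.label
        )

    __rmul__ = __mul__

    def __sub__(self, other: "PotentialField") -> "PotentialField":
        return PotentialField(
            self.values - other.values,
            self.voxel_size,
            self.origin,
            max(self.residual, other.residual),
            f"{self.label}-{other.label}",
        )

    def __add__(self, other: "PotentialField") -> "PotentialField":
        return PotentialField(
            self.values + other.values,
            self.voxel_size,
            self.origin,
            max(self.residual, other.residual),
            f"{self.label}+{other.label}",
        )


def _axis_sigma(model: TissueModel, axis: int) -> np.ndarray:
    """Per-voxel normal conductivity n . sigma . n for faces normal to axis."""
    d = model.direction[..., axis].astype(np.float64)
    return model.sigma_t + (model.sigma_l - model.sigma_t) * d * d


def assemble_system(
    model: TissueModel,
    source: SourceSpec,
    i_unit_ua: float = I_UNIT_UA,
) -> LinearSystem:
    """Assemble the symmetric finite-volume system for one source.

    Interior row sums vanish (discrete current conservation); rows adjacent to
    grounded voxels keep the face conductance on the diagonal, which encodes
    the Dirichlet V = 0 condition.
    """
    shape = model.shape
    n_total = int(np.prod(shape))
    h_m = model.voxel_size * 1e-3  # mm -> m; face area/dist ratio = h
    conductive = (model.sigma_t > 0) & (model.sigma_l > 0)
    grounded = (
        model.grounded if model.grounded is not None else model.default_grounded()
    )
    grounded = grounded & conductive
    unknown = conductive & ~grounded

    idx = -np.ones(n_total, np.int64)
    unknown_flat = np.flatnonzero(unknown.ravel())
    idx[unknown_flat] = np.arange(unknown_flat.size)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(unknown_flat.size)

    flat = np.arange(n_total).reshape(shape)
    for axis in range(3):
        sig = _axis_sigma(model, axis)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        s1 = sig[tuple(sl_lo)]
        s2 = sig[tuple(sl_hi)]
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(s1 + s2 > 0, 2.0 * s1 * s2 / (s1 + s2), 0.0) * h_m
        i1 = flat[tuple(sl_lo)].ravel()
        i2 = flat[tuple(sl_hi)].ravel()
        g = g.ravel()
        live = g > 0
        i1, i2, g = i1[live], i2[live], g[live]
        u1 = idx[i1]
        u2 = idx[i2]
        both = (u1 >= 0) & (u2 >= 0)
        rows.append(u1[both])
        cols.append(u2[both])
        vals.append(-g[both])
        np.add.at(diag, u1[u1 >= 0], g[u1 >= 0])
        np.add.at(diag, u2[u2 >= 0], g[u2 >= 0])

    r = np.concatenate(rows + cols + [np.arange(unknown_flat.size)])
    c = np.concatenate(cols + rows + [np.arange(unknown_flat.size)])
    v = np.concatenate(vals + vals + [diag])
    A = sp.csr_matrix((v, (r, c)), shape=(unknown_flat.size,) * 2)

    b = np.zeros(unknown_flat.size)
    i_amp = i_unit_ua * 1e-6
    for key, share in source.shares:
        if key not in model.contacts:
            raise KeyError(f"model has no contact {key}")
        vox = model.contacts[key]
        u = idx[vox]
        if np.all(u < 0):
            raise ValueError(f"contact {key} footprint maps to zero solvable voxels")
        u = u[u >= 0]
        b[u] += share * i_amp / u.size

    return LinearSystem(
        A=A,
        b=b,
        unknown_index=unknown_flat,
        shape=shape,
        voxel_size=model.voxel_size,
        origin=model.origin,
        label=source.label,
    )


def solve_field(
    system: LinearSystem,
    tol: float = 1e-8,
    maxiter: int = 20000,
) -> PotentialField:
    """Solve the assembled system by Jacobi-preconditioned CG.

    ``tol`` is the relative residual |Av - b| / |b|.  Deterministic (fixed
    zero initial guess).  Raises :class:`FieldSolveError` with the residual
    history on non-convergence.
    """
    A, b = system.A, system.b
    if not np.any(b):
        values = np.zeros(system.shape)
        return PotentialField(
            values, system.voxel_size, system.origin, 0.0, system.label
        )
    dinv = 1.0 / A.diagonal()
    M = spla.LinearOperator(A.shape, matvec=lambda x: dinv * x)
    residuals: list[float] = []
    bnorm = np.linalg.norm(b)

    def cb(xk):
        residuals.append(float(np.linalg.norm(b - A @ xk) / bnorm))

    v, info = spla.cg(A, b, rtol=tol, atol=0.0, maxiter=maxiter, M=M, callback=cb)
    res = float(np.linalg.norm(b - A @ v) / bnorm)
    if info != 0 or res > tol * 10:
        raise FieldSolveError(
            f"CG did not converge for {system.label!r}: info={info}, "
            f"relative residual={res:.3e} after {len(residuals)} iterations",
            np.asarray(residuals),
        )
    values = np.zeros(int(np.prod(system.shape)))
    values[system.unknown_index] = v * 1e3  # V -> mV
    return PotentialField(
        values.reshape(system.shape),
        system.voxel_size,
        system.origin,
        res,
        system.label,
    )


def solve_configuration(
    model: TissueModel,
    config: ElectrodeConfiguration,
    tol: float = 1e-8,
    maxiter: int = 20000,
) -> PotentialField:
    """Unit-current field of one electrode configuration (direct solve)."""
    source = SourceSpec.from_configuration(config)
    return solve_field(assemble_system(model, source), tol=tol, maxiter=maxiter)


def combine_monopoles(
    monopoles: dict[str, PotentialField], config: ElectrodeConfiguration
) -> PotentialField:
    """Field of a multipolar configuration by superposition of per-contact
    monopole solutions (all sharing the grounded boundary)."""
    segs = config.contacts
    out = None
    for seg, share in segs:
        term = share * monopoles[seg]
        out = term if out is None else out + term
    out.label = f"{config.side}:{config.label}"
    return out


def sample_along_fiber(
    potential: PotentialField,
    xyz: np.ndarray,
    fiber_id: str = "?",
) -> np.ndarray:
    """Trilinearly interpolate the potential at compartment centers (mm).

    Exact for affine fields.  Raises if any center falls outside the grid,
    naming the fiber and the offending compartment.
    """
    xyz = np.atleast_2d(np.asarray(xyz, float))
    frac = (xyz - potential.origin) / potential.voxel_size
    hi = np.asarray(potential.values.shape) - 1
    bad = np.any((frac < -0.5) | (frac > hi + 0.5), axis=1)
    if np.any(bad):
        k = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"fiber {fiber_id!r} compartment {k} at {xyz[k]} lies outside "
            "the potential grid"
        )
    return map_coordinates(
        potential.values, frac.T, order=1, mode="nearest", prefilter=False
    )
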