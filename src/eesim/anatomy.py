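"""Synthetic parametric anatomy of the rat lumbosacral spinal cord.

This module builds the volume conductor used by the field solver: a voxelized
model of segments L2-S1 with nested tissue compartments (gray matter, white
matter, spinal roots, CSF, dura, epidural fat, vertebral bone, outer saline
bath), epidural electrode contacts on the dorsal and ventral midline of each
segment, and the Aalpha-sensory / alpha-motor fiber populations that innervate
the four hindlimb muscles (TA, GC, VM, ST).

Cross sections are parametric ellipses (the gray-matter butterfly is the union
of two overlapping ellipses) rather than histology tracings; dimensions follow
the ~3 mm diameter of the rat lumbar cord and live in :class:`SpinalCordSpec`
so they can be overridden from config.

Coordinate convention: right-handed, x lateral, y dorsoventral (+y dorsal),
z rostro-caudal (+z caudal). All lengths in mm.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEGMENTS",
    "CONTACT_SEGMENTS",
    "MUSCLES",
    "Tissue",
    "SpinalCordSpec",
    "ConductivityTable",
    "TissueModel",
    "ElectrodeConfiguration",
    "MotorPoolTable",
    "Fiber",
    "FiberPopulation",
    "build_volume",
    "enumerate_configurations",
    "build_populations",
    "largest_remainder_counts",
]

SEGMENTS = ("L2", "L3", "L4", "L5", "L6", "S1")

#: Rostro-caudal segment lengths in mm, L2..S1.
DEFAULT_SEGMENT_LENGTHS = dict(zip(SEGMENTS, (3.3, 2.8, 2.7, 2.8, 2.4, 2.7)))

#: Segments carrying an epidural contact (5 per side -> 5 monopolar configs).
CONTACT_SEGMENTS = SEGMENTS[:5]

MUSCLES = ("TA", "GC", "VM", "ST")

#: Segmental fractions of each muscle's motor pool.
DEFAULT_MOTOR_POOLS: dict[str, dict[str, float]] = {
    "TA": {"L3": 0.2, "L4": 0.7, "L5": 0.1},
    "GC": {"L4": 0.2, "L5": 0.6, "L6": 0.2},
    "VM": {"L2": 0.2, "L3": 0.7, "L4": 0.1},
    "ST": {"L4": 0.2, "L5": 0.8},
}

SIDES = ("dorsal", "ventral")
MODES = ("monopolar", "bipolar", "tripolar")


class Tissue(IntEnum):
    """Voxel labels. SALINE..ROOT carry conductivity; CONTACT/INSULATION mark
    the electrode paddle."""

    SALINE = 0
    BONE = 1
    FAT = 2
    DURA = 3
    CSF = 4
    WHITE = 5
    GRAY = 6
    ROOT = 7
    CONTACT = 8
    INSULATION = 9


#: Labels a fiber trajectory is allowed to traverse.
FIBER_TISSUES = frozenset(
    {Tissue.GRAY, Tissue.WHITE, Tissue.ROOT, Tissue.CSF, Tissue.DURA}
)


@dataclass(frozen=True)
class ConductivityTable:
    """Tissue conductivities in S/m.

    White matter and spinal roots are anisotropic and carry a
    (longitudinal, transverse) pair; everything else is a scalar.
    """

    gray: float = 0.23
    white_longitudinal: float = 0.6
    white_transverse: float = 0.083
    csf: float = 1.7
    dura: float = 0.6
    fat: float = 0.04
    bone: float = 0.02
    saline: float = 2.0
    #: Platinum contact approximated by a high but finite conductivity so the
    #: linear system stays well conditioned; the contact is a current source,
    #: not a resistive path of interest.
    contact: float = 10.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"conductivity {name!r} must be > 0, got {value}")

    def longitudinal_transverse(self, label: int) -> tuple[float, float]:
        """(sigma_long, sigma_trans) for a label; equal for isotropic tissue."""
        aniso = self.white_longitudinal, self.white_transverse
        table = {
            Tissue.SALINE: (self.saline, self.saline),
            Tissue.BONE: (self.bone, self.bone),
            Tissue.FAT: (self.fat, self.fat),
            Tissue.DURA: (self.dura, self.dura),
            Tissue.CSF: (self.csf, self.csf),
            Tissue.WHITE: aniso,
            Tissue.GRAY: (self.gray, self.gray),
            Tissue.ROOT: aniso,
            Tissue.CONTACT: (self.contact, self.contact),
            Tissue.INSULATION: (0.0, 0.0),
        }
        return table[Tissue(label)]


@dataclass(frozen=True)
class SpinalCordSpec:
    """Parametric geometry of the lumbosacral cord and its surroundings.

    ``*_half_axes`` are (a_x, b_y) half axes in mm of concentric elliptic
    cylinders running the full rostro-caudal extent of the grid.  The nesting
    gray < white < csf < dura < fat < bone is validated.
    """

    segment_lengths: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_LENGTHS)
    )
    # gray matter butterfly = union of a wide lateral and a tall dorsoventral
    # ellipse
    gray_wing_half_axes: tuple[float, float] = (0.95, 0.42)
    gray_core_half_axes: tuple[float, float] = (0.35, 0.95)
    white_half_axes: tuple[float, float] = (1.5, 1.25)
    csf_half_axes: tuple[float, float] = (1.8, 1.55)
    dura_half_axes: tuple[float, float] = (2.0, 1.75)
    fat_half_axes: tuple[float, float] = (2.6, 2.4)
    bone_half_axes: tuple[float, float] = (3.4, 3.2)

    voxel_size: float = 0.1
    #: Saline margin beyond the bone in x/y; the grounded outer boundary of an
    #: enlarged bath realizes the monopolar distant return.
    bath_margin: float = 4.0
    #: Extra rostral/caudal extent beyond the L2-S1 span.
    z_margin: float = 2.0

    rootlets_per_segment: int = 3
    #: Corridor radius of a rootlet bundle in mm.
    root_radius: float = 0.18

    # Epidural contact footprint: 1000 um rostro-caudal x 300 um lateral.
    contact_length: float = 1.0
    contact_width: float = 0.3

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        missing = [s for s in SEGMENTS if s not in self.segment_lengths]
        if missing:
            raise ValueError(f"segment_lengths missing segments: {missing}")
        if any(l <= 0 for l in self.segment_lengths.values()):
            raise ValueError("segment lengths must be > 0")
        shells = [
            ("white", self.white_half_axes),
            ("csf", self.csf_half_axes),
            ("dura", self.dura_half_axes),
            ("fat", self.fat_half_axes),
            ("bone", self.bone_half_axes),
        ]
        inner_a = max(self.gray_wing_half_axes[0], self.gray_core_half_axes[0])
        inner_b = max(self.gray_wing_half_axes[1], self.gray_core_half_axes[1])
        prev_name, (pa, pb) = "gray", (inner_a, inner_b)
        for name, (a, b) in shells:
            if not (a > pa and b > pb):
                raise ValueError(
                    f"cross sections must nest strictly: {name} !> {prev_name}"
                )
            prev_name, (pa, pb) = name, (a, b)
        dura_thickness = min(
            self.dura_half_axes[0] - self.csf_half_axes[0],
            self.dura_half_axes[1] - self.csf_half_axes[1],
        )
        if self.voxel_size > dura_thickness + 1e-12:
            raise ValueError(
                f"voxel_size {self.voxel_size} mm cannot resolve the dura "
                f"shell ({dura_thickness:.3g} mm thick); refine the grid or "
                "thicken the dura"
            )
        if self.rootlets_per_segment < 1:
            raise ValueError("rootlets_per_segment must be >= 1")

    # -- derived geometry ------------------------------------------------

    @property
    def cord_length(self) -> float:
        """Total rostro-caudal length of L2-S1 in mm."""
        return float(sum(self.segment_lengths[s] for s in SEGMENTS))

    def segment_bounds(self, segment: str) -> tuple[float, float]:
        z0 = 0.0
        for s in SEGMENTS:
            length = self.segment_lengths[s]
            if s == segment:
                return z0, z0 + length
            z0 += length
        raise KeyError(segment)

    def segment_mid(self, segment: str) -> float:
        z0, z1 = self.segment_bounds(segment)
        return 0.5 * (z0 + z1)

    def grid_extent(self) -> tuple[tuple[float, float], ...]:
        hx = self.bone_half_axes[0] + self.bath_margin
        hy = self.bone_half_axes[1] + self.bath_margin
        return (
            (-hx, hx),
            (-hy, hy),
            (-self.z_margin, self.cord_length + self.z_margin),
        )

    def with_(self, **kwargs) -> "SpinalCordSpec":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Electrode configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeConfiguration:
    """One stimulation configuration.

    ``active`` is the cathodic contact segment; ``returns`` are the anodic
    contacts (empty for monopolar, whose return is the grounded bath
    boundary).  Return current is split equally across return contacts.
    """

    side: str
    mode: str
    active: str
    returns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        n_ret = {"monopolar": 0, "bipolar": 1, "tripolar": 2}[self.mode]
        if len(self.returns) != n_ret:
            raise ValueError(
                f"{self.mode} configuration needs {n_ret} return contact(s), "
                f"got {len(self.returns)}"
            )

    @property
    def label(self) -> str:
        """Segment-number label, e.g. ``L4`` or ``L2_5_6`` (sorted segment
        numbers of all involved contacts; the geometrically middle one is the
        active contact in tripolar mode)."""
        segs = sorted(
            (self.active, *self.returns), key=CONTACT_SEGMENTS.index
        )
        nums = [s[1:] if s.startswith("L") else s for s in segs]
        return "L" + "_".join(nums)

    @property
    def contacts(self) -> tuple[tuple[str, float], ...]:
        """(segment, signed current share) pairs; shares sum to 0 when all
        returns are modeled, +1 alone for monopolar."""
        if not self.returns:
            return ((self.active, 1.0),)
        share = -1.0 / len(self.returns)
        return ((self.active, 1.0),) + tuple((r, share) for r in self.returns)


def enumerate_configurations(
    side: str, mode: str | None = None
) -> list[ElectrodeConfiguration]:
    """Deterministically enumerate the electrode-configuration catalog.

    Per side: 5 monopolar (one per contact segment), 10 bipolar (all contact
    pairs, rostral active) and 10 tripolar (all contact triples, middle
    active) -> 25 configurations with unique labels.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    if mode is None:
        return [
            c for m in MODES for c in enumerate_configurations(side, m)
        ]
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    segs = CONTACT_SEGMENTS
    configs: list[ElectrodeConfiguration] = []
    if mode == "monopolar":
        for s in segs:
            configs.append(ElectrodeConfiguration(side, mode, s))
    elif mode == "bipolar":
        for a, b in itertools.combinations(segs, 2):
            configs.append(ElectrodeConfiguration(side, mode, a, (b,)))
    else:
        for a, b, c in itertools.combinations(segs, 3):
            configs.append(ElectrodeConfiguration(side, mode, b, (a, c)))
    return configs


# ---------------------------------------------------------------------------
# Motor pools
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotorPoolTable:
    """Segmental distribution of each muscle's motor pool (fractions sum to 1)."""

    pools: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_MOTOR_POOLS.items()}
    )

    def __post_init__(self) -> None:
        for muscle, fracs in self.pools.items():
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"pool fractions for {muscle} sum to {total}, expected 1.0"
                )
            unknown = [s for s in fracs if s not in SEGMENTS]
            if unknown:
                raise ValueError(f"unknown segments in pool {muscle}: {unknown}")

    @property
    def muscles(self) -> tuple[str, ...]:
        return tuple(self.pools)


def largest_remainder_counts(
    fractions: Mapping[str, float], n: int
) -> dict[str, int]:
    """Integer counts per key summing exactly to ``n`` (largest-remainder
    rounding; ties broken in segment order)."""
    keys = sorted(fractions, key=SEGMENTS.index)
    exact = {k: fractions[k] * n for k in keys}
    counts = {k: int(np.floor(exact[k])) for k in keys}
    short = n - sum(counts.values())
    order = sorted(keys, key=lambda k: (-(exact[k] - counts[k]), SEGMENTS.index(k)))
    for k in order[:short]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# Tissue model
# ---------------------------------------------------------------------------


@dataclass
class TissueModel:
    """Labeled voxel grid with a per-voxel anisotropic conductivity tensor.

    The tensor is stored factored as (sigma_long, sigma_trans, direction):
    ``sigma = sigma_t * I + (sigma_l - sigma_t) * d d^T``, which is symmetric
    positive definite with eigenvalues {sigma_l, sigma_t, sigma_t} and the
    sigma_l eigenvector along ``direction``.
    """

    voxel_size: float
    origin: np.ndarray  # (3,) coordinate of voxel-center (0,0,0)
    labels: np.ndarray  # (nx, ny, nz) int8
    sigma_l: np.ndarray  # (nx, ny, nz) float
    sigma_t: np.ndarray
    direction: np.ndarray  # (nx, ny, nz, 3) unit vectors
    contacts: dict = field(default_factory=dict)  # (side, segment) -> flat idx array
    grounded: np.ndarray | None = None  # bool mask of Dirichlet V=0 voxels
    spec: SpinalCordSpec | None = None
    conductivities: ConductivityTable | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + self.voxel_size * np.arange(n)

    def world_to_fractional(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel-index coordinates of world points (n, 3)."""
        return (np.asarray(xyz, float) - self.origin) / self.voxel_size

    def tensor(self, ix: int, iy: int, iz: int) -> np.ndarray:
        """Full 3x3 conductivity tensor of one voxel."""
        d = self.direction[ix, iy, iz]
        sl = float(self.sigma_l[ix, iy, iz])
        st = float(self.sigma_t[ix, iy, iz])
        return st * np.eye(3) + (sl - st) * np.outer(d, d)

    def label_at(self, xyz: np.ndarray) -> np.ndarray:
        idx = np.rint(self.world_to_fractional(np.atleast_2d(xyz))).astype(int)
        idx = np.clip(idx, 0, np.array(self.shape) - 1)
        return self.labels[idx[:, 0], idx[:, 1], idx[:, 2]]

    def default_grounded(self) -> np.ndarray:
        """Grid-boundary voxels (the distant-return Dirichlet surface)."""
        mask = np.zeros(self.shape, bool)
        mask[0, :, :] = mask[-1, :, :] = True
        mask[:, 0, :] = mask[:, -1, :] = True
        mask[:, :, 0] = mask[:, :, -1] = True
        return mask

    @classmethod
    def uniform(
        cls,
        shape: tuple[int, int, int],
        voxel_size: float,
        sigma: float,
        origin: Sequence[float] | None = None,
    ) -> "TissueModel":
        """Homogeneous isotropic model (validation and testing helper)."""
        labels = np.full(shape, int(Tissue.SALINE), np.int8)
        sig = np.full(shape, float(sigma))
        direction = np.zeros(shape + (3,), np.float32)
        direction[..., 2] = 1.0
        if origin is None:
            origin = -voxel_size * (np.asarray(shape) - 1) / 2.0
        return cls(
            voxel_size=voxel_size,
            origin=np.asarray(origin, float),
            labels=labels,
            sigma_l=sig,
            sigma_t=sig.copy(),
            direction=direction,
        )


def _inside_ellipse(x, y, half_axes) -> np.ndarray:
    a, b = half_axes
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


# -- root / fiber path geometry ---------------------------------------------

# Root entry angle from the dorsoventral axis and the radial station of the
# intrathecal (CSF) run of the roots, as fractions of the local shell.
_ENTRY_ANGLE = np.deg2rad(30.0)
_RUN_ANGLE = np.deg2rad(35.0)
_RUN_SCALE = 0.90  # fraction of the CSF half axes at which roots run


def _entry_point(spec: SpinalCordSpec, dorsal: bool, lr: int) -> np.ndarray:
    a, b = spec.white_half_axes
    sign = 1.0 if dorsal else -1.0
    return np.array([lr * a * np.sin(_ENTRY_ANGLE), sign * b * np.cos(_ENTRY_ANGLE)])


def _run_point(spec: SpinalCordSpec, dorsal: bool, lr: int) -> np.ndarray:
    a, b = spec.csf_half_axes
    sign = 1.0 if dorsal else -1.0
    return np.array(
        [
            lr * _RUN_SCALE * a * np.sin(_RUN_ANGLE),
            sign * _RUN_SCALE * b * np.cos(_RUN_ANGLE),
        ]
    )


def _resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing <= ``spacing``."""
    points = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / spacing)) + 1, 2)
    si = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(si, s, points[:, k])
    return out


def root_path(
    spec: SpinalCordSpec, side: str, lr: int, z_entry: float, caudal_run: float
) -> np.ndarray:
    """Key points of a rootlet path: cord surface entry -> oblique exit into
    the CSF -> caudal intrathecal run alongside the cord."""
    dorsal = side == "dorsal"
    p0 = _entry_point(spec, dorsal, lr)
    p1 = _run_point(spec, dorsal, lr)
    # keep the intrathecal run inside the grid's caudal margin
    z_max = spec.cord_length + spec.z_margin - 0.4
    z_run_end = min(z_entry + 0.8 + caudal_run, z_max)
    pts = [
        [p0[0], p0[1], z_entry],
        [0.5 * (p0[0] + p1[0]), 0.5 * (p0[1] + p1[1]), z_entry + 0.4],
        [p1[0], p1[1], z_entry + 0.8],
        [p1[0], p1[1], max(z_run_end, z_entry + 1.3)],
    ]
    return np.asarray(pts)


_DEFAULT_ROOT_CAUDAL_RUN = {"dorsal": 4.0, "ventral": 5.0}


def _sensory_keypoints(
    spec: SpinalCordSpec, lr: int, z_seg: float, jitter: np.ndarray
) -> np.ndarray:
    """Aalpha-sensory fiber: ascending branch in the dorsal column, curving out
    through the dorsal root entry zone into the dorsal root."""
    jx, jy = jitter
    x_dc = lr * (0.25 + jx)
    y_dc = 1.02 + jy
    z_top = max(-spec.z_margin + 0.5, z_seg - 6.0)
    root = root_path(spec, "dorsal", lr, z_seg, _DEFAULT_ROOT_CAUDAL_RUN["dorsal"])
    pts = [[x_dc, y_dc, z_top], [x_dc, y_dc, z_seg - 0.6]]
    pts.extend(root.tolist())
    return np.asarray(pts)


def _motor_keypoints(
    spec: SpinalCordSpec, lr: int, z_seg: float, jitter: np.ndarray
) -> np.ndarray:
    """Alpha-motor fiber: ventral-horn origin, exiting through the ventral
    white matter into the ventral root."""
    jx, jy = jitter
    x_vh = lr * (0.45 + jx)
    y_vh = -0.55 + jy
    root = root_path(spec, "ventral", lr, z_seg, _DEFAULT_ROOT_CAUDAL_RUN["ventral"])
    pts = [[x_vh, y_vh, z_seg - 1.2], [x_vh, y_vh, z_seg - 0.5]]
    pts.extend(root.tolist())
    return np.asarray(pts)


# ---------------------------------------------------------------------------
# Volume construction
# ---------------------------------------------------------------------------


def build_volume(
    spec: SpinalCordSpec | None = None,
    cond: ConductivityTable | None = None,
) -> TissueModel:
    """Voxelize the parametric anatomy into a :class:`TissueModel`.

    Every voxel is labeled; white matter carries rostro-caudal (z) fiber
    directions, root corridors carry tangent directions of the rootlet paths.
    The grid boundary is grounded (distant monopolar return).
    """
    spec = spec or SpinalCordSpec()
    cond = cond or ConductivityTable()
    h = spec.voxel_size
    (x0, x1), (y0, y1), (z0, z1) = spec.grid_extent()
    nx = int(round((x1 - x0) / h))
    ny = int(round((y1 - y0) / h))
    nz = int(round((z1 - z0) / h))
    origin = np.array([x0 + h / 2, y0 + h / 2, z0 + h / 2])
    xs = origin[0] + h * np.arange(nx)
    ys = origin[1] + h * np.arange(ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    section = np.full((nx, ny), int(Tissue.SALINE), np.int8)
    for label, axes in (
        (Tissue.BONE, spec.bone_half_axes),
        (Tissue.FAT, spec.fat_half_axes),
        (Tissue.DURA, spec.dura_half_axes),
        (Tissue.CSF, spec.csf_half_axes),
        (Tissue.WHITE, spec.white_half_axes),
    ):
        section[_inside_ellipse(X, Y, axes)] = int(label)
    gray = _inside_ellipse(X, Y, spec.gray_wing_half_axes) | _inside_ellipse(
        X, Y, spec.gray_core_half_axes
    )
    section[gray] = int(Tissue.GRAY)

    labels = np.repeat(section[:, :, None], nz, axis=2)
    direction = np.zeros((nx, ny, nz, 3), np.float32)
    direction[..., 2] = 1.0

    # -- root corridors --
    r_vox = max(int(np.ceil(spec.root_radius / h)), 1)
    offs = np.stack(
        np.meshgrid(*([np.arange(-r_vox, r_vox + 1)] * 3), indexing="ij"), -1
    ).reshape(-1, 3)
    offs = offs[np.linalg.norm(offs, axis=1) * h <= spec.root_radius + 0.5 * h]
    shape = np.array([nx, ny, nz])
    rootlet_dz = 0.35
    for seg in SEGMENTS:
        z_mid = spec.segment_mid(seg)
        for side in SIDES:
            for lr in (-1, 1):
                for j in range(spec.rootlets_per_segment):
                    dz = (j - (spec.rootlets_per_segment - 1) / 2) * rootlet_dz
                    kp = root_path(
                        spec, side, lr, z_mid + dz, _DEFAULT_ROOT_CAUDAL_RUN[side]
                    )
                    pts = _resample_polyline(kp, h / 2)
                    tang = np.gradient(pts, axis=0)
                    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
                    idx = np.rint((pts - origin) / h).astype(int)
                    for p, t in zip(idx, tang):
                        cells = p + offs
                        ok = np.all((cells >= 0) & (cells < shape), axis=1)
                        cells = cells[ok]
                        lab = labels[cells[:, 0], cells[:, 1], cells[:, 2]]
                        take = lab == int(Tissue.CSF)
                        cells = cells[take]
                        labels[cells[:, 0], cells[:, 1], cells[:, 2]] = int(
                            Tissue.ROOT
                        )
                        direction[cells[:, 0], cells[:, 1], cells[:, 2]] = t

    # -- electrode contacts + insulation backing --
    contacts: dict[tuple[str, str], np.ndarray] = {}
    half_w = spec.contact_width / 2
    half_l = spec.contact_length / 2
    ix_sel = np.where(np.abs(xs) <= half_w)[0]
    dura_b = spec.dura_half_axes[1]
    for side in SIDES:
        sign = 1 if side == "dorsal" else -1
        for seg in CONTACT_SEGMENTS:
            z_mid = spec.segment_mid(seg)
            iz_sel = np.where(np.abs(origin[2] + h * np.arange(nz) - z_mid) <= half_l)[
                0
            ]
            vox: list[tuple[int, int, int]] = []
            ins: list[tuple[int, int, int]] = []
            for ix in ix_sel:
                # epidural surface height at this lateral station
                frac = 1 - (xs[ix] / spec.dura_half_axes[0]) ** 2
                y_surf = sign * dura_b * np.sqrt(max(frac, 0.0))
                iy = int(np.rint((y_surf - origin[1]) / h)) + sign
                iy_ins = iy + sign
                for iz in iz_sel:
                    if labels[ix, iy, iz] == int(Tissue.FAT):
                        vox.append((ix, iy, iz))
                    if labels[ix, iy_ins, iz] == int(Tissue.FAT):
                        ins.append((ix, iy_ins, iz))
            if not vox:
                raise ValueError(
                    f"contact footprint for ({side}, {seg}) maps to zero voxels"
                )
            vi = np.array(vox)
            labels[vi[:, 0], vi[:, 1], vi[:, 2]] = int(Tissue.CONTACT)
            if ins:
                ii = np.array(ins)
                labels[ii[:, 0], ii[:, 1], ii[:, 2]] = int(Tissue.INSULATION)
            contacts[(side, seg)] = np.ravel_multi_index(
                (vi[:, 0], vi[:, 1], vi[:, 2]), (nx, ny, nz)
            )

    sigma_l = np.empty((nx, ny, nz), np.float64)
    sigma_t = np.empty((nx, ny, nz), np.float64)
    for label in Tissue:
        sl, st = cond.longitudinal_transverse(label)
        m = labels == int(label)
        sigma_l[m] = sl
        sigma_t[m] = st

    model = TissueModel(
        voxel_size=h,
        origin=origin,
        labels=labels,
        sigma_l=sigma_l,
        sigma_t=sigma_t,
        direction=direction,
        contacts=contacts,
        spec=spec,
        conductivities=cond,
    )
    model.grounded = model.default_grounded()
    return model


# ---------------------------------------------------------------------------
# Fiber populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fiber:
    fiber_id: str
    muscle: str
    fiber_class: str  # "sensory" | "motor"
    segment: str
    motor_unit_id: str
    diameter_um: float
    xyz: np.ndarray  # (n, 3) polyline, mm


@dataclass
class FiberPopulation:
    fibers: list[Fiber]
    seed: int
    n_per_pool: int

    def __iter__(self):
        return iter(self.fibers)

    def __len__(self) -> int:
        return len(self.fibers)

    def by_class(self, fiber_class: str) -> list[Fiber]:
        return [f for f in self.fibers if f.fiber_class == fiber_class]

    def units(self) -> dict[str, dict[str, Fiber]]:
        """motor_unit_id -> {"sensory": Fiber, "motor": Fiber}."""
        out: dict[str, dict[str, Fiber]] = {}
        for f in self.fibers:
            out.setdefault(f.motor_unit_id, {})[f.fiber_class] = f
        return out

    def to_frame(self) -> pd.DataFrame:
        """One row per polyline vertex (CSV export layout)."""
        rows = []
        for f in self.fibers:
            n = len(f.xyz)
            rows.append(
                pd.DataFrame(
                    {
                        "fiber_id": np.repeat(f.fiber_id, n),
                        "fiber_class": np.repeat(f.fiber_class, n),
                        "muscle": np.repeat(f.muscle, n),
                        "x": f.xyz[:, 0],
                        "y": f.xyz[:, 1],
                        "z": f.xyz[:, 2],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def build_populations(
    spec: SpinalCordSpec | None = None,
    pools: MotorPoolTable | None = None,
    n_per_pool: int = 40,
    seed: int = 0,
    diameter_um: float = 9.0,
) -> FiberPopulation:
    """Build the motor-unit fiber populations.

    Each of the ``n_per_pool`` motor units of a muscle contributes exactly one
    Aalpha-sensory fiber (dorsal root) and one alpha-motor fiber (ventral
    root), both 9 um in diameter, rooted at a segment drawn from the muscle's
    pool fractions by largest-remainder rounding.  Left/right side alternates
    across units; small seeded lateral jitter decorrelates trajectories.
    Deterministic: the same seed reproduces byte-identical coordinates.
    """
    spec = spec or SpinalCordSpec()
    pools = pools or MotorPoolTable()
    rng = np.random.default_rng(seed)
    spacing = min(spec.voxel_size, 0.1)
    fibers: list[Fiber] = []
    for muscle in pools.muscles:
        counts = largest_remainder_counts(pools.pools[muscle], n_per_pool)
        unit = 0
        for seg in sorted(counts, key=SEGMENTS.index):
            z_lo, z_hi = spec.segment_bounds(seg)
            for _ in range(counts[seg]):
                uid = f"{muscle}-{unit:02d}"
                lr = 1 if unit % 2 == 0 else -1
                z_seg = float(rng.uniform(z_lo + 0.3, z_hi - 0.3))
                for cls, keyfun in (
                    ("sensory", _sensory_keypoints),
                    ("motor", _motor_keypoints),
                ):
                    jitter = rng.uniform(-0.06, 0.06, 2)
                    kp = keyfun(spec, lr, z_seg, jitter)
                    xyz = _resample_polyline(kp, spacing)
                    fibers.append(
                        Fiber(
                            fiber_id=f"{uid}-{cls[0]}",
                            muscle=muscle,
                            fiber_class=cls,
                            segment=seg,
                            motor_unit_id=uid,
                            diameter_um=diameter_um,
                            xyz=xyz,
                        )
                    )
                unit += 1
    return FiberPopulation(fibers=fibers, seed=seed, n_per_pool=n_per_pool)
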