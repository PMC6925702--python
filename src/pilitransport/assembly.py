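"""Helical symmetry: build an N-subunit pilus from one subunit and measure it.

A type IV pilus is a right-handed helical polymer: subunit *i* is subunit 0
rotated by *i*·rotation about the filament axis and translated by *i*·rise
along it. This module applies that operator, estimates rise/rotation back
from an assembly (the test oracle for planted parameters), and measures the
filament diameter.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import PilinStructure, StructureError

__all__ = [
    "HelicalParams",
    "AssemblyModel",
    "chain_id_sequence",
    "align_to_axis",
    "apply_helical_symmetry",
    "estimate_helical_params",
    "measure_diameter",
]

# Single-character chain alphabet usable in PDB files (62 ids), after which
# two-character ids are generated for in-memory assemblies.
_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


def chain_id_sequence() -> Iterator[str]:
    """Yield chain identifiers A..Z, a..z, 0..9, then AA, AB, ..."""
    yield from _CHAIN_ALPHABET
    for first in string.ascii_uppercase:
        for second in string.ascii_uppercase:
            yield first + second


@dataclass(frozen=True)
class HelicalParams:
    """Parameters of the helical symmetry operator.

    ``rotation_per_subunit`` is in degrees; positive rotation is
    counter-clockwise looking down +z (right-handed helix). Set
    ``right_handed=False`` to flip handedness.
    """

    rise_per_subunit: float  # Å
    rotation_per_subunit: float  # degrees
    radius_to_com: float = 0.0  # Å
    n_subunits: int = 21
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    right_handed: bool = True

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError(f"n_subunits must be >= 1, got {self.n_subunits}")
        if self.rise_per_subunit <= 0:
            raise ValueError(f"rise_per_subunit must be > 0, got {self.rise_per_subunit}")
        if not 0 < self.rotation_per_subunit < 360:
            raise ValueError(
                f"rotation_per_subunit must lie in (0, 360) degrees, "
                f"got {self.rotation_per_subunit}"
            )
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("axis must be a nonzero vector")
        object.__setattr__(self, "axis", axis / norm)
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, dtype=float))

    def operator(self, i: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Rotation matrix and translation of the symmetry operator applied i times."""
        sign = 1.0 if self.right_handed else -1.0
        angle = sign * np.deg2rad(self.rotation_per_subunit) * i
        R = Rotation.from_rotvec(angle * self.axis).as_matrix()
        # x -> R (x - p) + p + i * rise * axis
        t = self.axis_point - R @ self.axis_point + i * self.rise_per_subunit * self.axis
        return R, t


@dataclass
class AssemblyModel:
    """A helical assembly: the generating parameters plus the subunit copies."""

    params: HelicalParams
    subunits: list[PilinStructure]

    def __post_init__(self) -> None:
        ids = [s.chain_id for s in self.subunits]
        if len(set(ids)) != len(ids):
            raise StructureError("assembly chain ids must be unique")

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    def all_coords(self) -> np.ndarray:
        return np.concatenate([s.coords() for s in self.subunits])


def align_to_axis(
    subunit: PilinStructure,
    helix_residues: tuple[int, int] | None = None,
    radius_to_com: float = 0.0,
) -> PilinStructure:
    """Rotate a subunit so its helical segment runs along +z.

    The principal axis of the Cα atoms of the designated segment (all residues
    if ``helix_residues`` is None) is made parallel to +z, oriented N-to-C
    toward +z, and the center of mass is placed at radial distance
    ``radius_to_com`` from the z-axis (on +x).
    """
    if helix_residues is None:
        ca = subunit.coords("CA")
    else:
        lo, hi = helix_residues
        sel = [
            r.atom("CA").position
            for r in subunit.residues
            if lo <= r.seq <= hi and r.has_atom("CA")
        ]
        ca = np.asarray(sel).reshape(-1, 3)
    if ca.shape[0] < 3:
        raise StructureError("helix alignment requires >= 3 Cα atoms")
    center = ca.mean(axis=0)
    centered = ca - center
    _, svals, vt = np.linalg.svd(centered)
    if svals[0] < 1e-9:
        raise StructureError("degenerate Cα set: no principal axis")
    axis = vt[0]
    # orient N->C along +z
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    R = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    all_center = subunit.coords().mean(axis=0)
    new_com = np.array([radius_to_com, 0.0, 0.0])
    t = new_com - R @ all_center
    return subunit.transformed(R, t)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(np.pi * perp).as_matrix()
    return Rotation.from_rotvec(v / np.linalg.norm(v) * np.arccos(np.clip(c, -1, 1))).as_matrix()


def apply_helical_symmetry(subunit: PilinStructure, params: HelicalParams) -> AssemblyModel:
    """Replicate ``subunit`` into an N-subunit helical assembly.

    Subunit *i* is subunit 0 rotated by *i*·rotation about the axis and
    translated by *i*·rise along it; chains are labelled A, B, C, ... in
    order (extended ids beyond 62 subunits).
    """
    ids = chain_id_sequence()
    subunits = []
    for i in range(params.n_subunits):
        R, t = params.operator(i)
        subunits.append(subunit.transformed(R, t, chain_id=next(ids)))
    return AssemblyModel(params, subunits)


def estimate_helical_params(assembly: AssemblyModel) -> HelicalParams:
    """Recover rise and rotation from consecutive subunit centroids.

    Rise is the mean axial displacement between consecutive subunit centroids
    and rotation the mean azimuthal displacement about the axis; exact for
    ideal (noise-free) assemblies. Requires >= 2 subunits of identical size.
    """
    subs = assembly.subunits
    if len(subs) < 2:
        raise StructureError("parameter estimation requires >= 2 subunits")
    sizes = {len(s.atoms) for s in subs}
    if len(sizes) != 1:
        raise StructureError(f"subunit atom counts differ: {sorted(sizes)}")
    axis = assembly.params.axis
    point = assembly.params.axis_point
    # basis perpendicular to the axis
    u = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(axis, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    centroids = np.stack([s.coords().mean(axis=0) - point for s in subs])
    z = centroids @ axis
    phi = np.unwrap(np.arctan2(centroids @ v, centroids @ u))
    radial = np.linalg.norm(centroids - np.outer(z, axis), axis=1)
    rise = float(np.mean(np.diff(z)))
    rot = float(np.rad2deg(np.mean(np.diff(phi))))
    right_handed = rot >= 0
    return HelicalParams(
        rise_per_subunit=rise,
        rotation_per_subunit=abs(rot),
        radius_to_com=float(np.mean(radial)),
        n_subunits=len(subs),
        axis=axis,
        axis_point=point,
        right_handed=right_handed,
    )


def measure_diameter(assembly: AssemblyModel) -> float:
    """Filament diameter: twice the largest radial atom distance from the axis.

    Measured from atom centers (no van der Waals padding).
    """
    coords = assembly.all_coords()
    if coords.size == 0:
        raise StructureError("cannot measure the diameter of an empty assembly")
    axis = assembly.params.axis
    rel = coords - assembly.params.axis_point
    axial = rel @ axis
    radial = np.linalg.norm(rel - np.outer(axial, axis), axis=1)
    return 2.0 * float(radial.max())
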