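"""Synthetic fixtures: ideal rings, pilins, planted-parameter pili, ensembles.

Everything downstream of structure input consumes only backbone (Cα) and
ring geometry, so the generators emit geometrically ideal stand-ins rather
than chemically faithful pilins:

* ``make_ring`` — a regular six-carbon hexagon (C-C bond 1.39 Å).
* ``make_ideal_pilin`` — a 61-residue poly-alanine α-helix Cα trace
  (1.5 Å rise, 100° twist per residue, textbook values) with full aromatic
  rings grafted at the mature-sequence aromatic positions 1, 24, 27, 32,
  51, 57 (Phe at 1, 24, 51; Tyr at 27, 32, 57).
* ``make_pathway_pilus`` — a helical assembly whose F1/F24/Y27 rings realize
  a planted (d1, d2, d3) interaromatic-distance triple exactly, repeating
  with the helical period, with the remaining aromatics parked >= 8 Å off
  the pathway.
* ``make_orbital_fixture`` / ``make_four_point_fixture`` — scalar
  electronic-structure fixtures that invert exactly through the energy-gap
  and four-point formulas.

All generators are deterministic under a fixed seed; noise is optional and
defaults to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import AssemblyModel, HelicalParams, apply_helical_symmetry
from .structure import (
    RING_ATOM_NAMES,
    AtomRecord,
    PilinStructure,
    Residue,
)
from .transport import FourPointEnergies, OrbitalEnergies

__all__ = [
    "SyntheticSpec",
    "InfeasibleGeometryError",
    "AROMATIC_POSITIONS",
    "make_ring",
    "make_ideal_pilin",
    "make_pathway_pilus",
    "add_assembly_noise",
    "make_orbital_fixture",
    "make_four_point_fixture",
    "make_angle_ensemble",
]

#: Mature-sequence positions of the pilin aromatics and their one-letter type.
AROMATIC_POSITIONS: dict[int, str] = {1: "F", 24: "F", 27: "Y", 32: "Y", 51: "F", 57: "Y"}

_RING_RADIUS = 1.39  # Å, C-C bond length of a regular aromatic hexagon

# Cα helix radius chosen so the consecutive-Cα chord is exactly 3.8 Å at
# 1.5 Å rise and 100° twist: r = sqrt(3.8² - 1.5²) / (2 sin 50°).
_HELIX_RISE = 1.5
_HELIX_TWIST_DEG = 100.0
_HELIX_RADIUS = np.sqrt(3.8**2 - _HELIX_RISE**2) / (2 * np.sin(np.deg2rad(_HELIX_TWIST_DEG / 2)))


class InfeasibleGeometryError(ValueError):
    """The requested distance triple cannot be realized on the chosen helix."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic generators.

    Defaults plant the canonical model geometry: 21 subunits, 10.5 Å rise,
    100.8° rotation, pathway anchor radius 5 Å, and the (3.9, 6.1, 5.1) Å
    distance triple of the first pilus model.
    """

    seed: int = 0
    noise_sigma: float = 0.0  # Å, isotropic Gaussian on atom positions
    rise: float = 10.5  # Å per subunit
    rotation: float = 100.8  # degrees per subunit
    anchor_radius: float = 5.0  # Å, radial distance of the F1 ring centroid
    n_subunits: int = 21
    distances: tuple[float, float, float] = (3.9, 6.1, 5.1)  # planted (d1, d2, d3), Å
    n_residues: int = 61
    angle_blobs: tuple[tuple[float, float, int], ...] = (
        (58.0, 26.0, 60),
        (106.0, 22.0, 30),
        (145.0, 18.0, 10),
    )  # (center, half-width, count) in degrees, for clustering ensembles

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _orthonormal_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane basis (u, v) perpendicular to ``normal``."""
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("ring normal must be nonzero")
    n = n / norm
    trial = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = trial - np.dot(trial, n) * n
    u /= np.linalg.norm(u)
    return u, np.cross(n, u)


def make_ring(
    center: np.ndarray,
    normal: np.ndarray,
    residue_type: str = "F",
    in_plane_rotation: float = 0.0,
    residue_seq: int = 1,
    chain_id: str = "A",
    serial_start: int = 1,
) -> Residue:
    """A regular aromatic hexagon as a Phe/Tyr residue.

    Six carbons named CG, CD1, CE1, CZ, CE2, CD2 sit at radius 1.39 Å in the
    plane perpendicular to ``normal``; the centroid equals ``center`` exactly.
    """
    u, v = _orthonormal_frame(normal)
    center = np.asarray(center, dtype=float)
    resname = "PHE" if residue_type.upper() == "F" else "TYR"
    # hexagon vertex order matching consecutive ring bonds
    ordered = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    atoms = []
    for j, name in enumerate(ordered):
        ang = np.deg2rad(in_plane_rotation + 60.0 * j)
        pos = center + _RING_RADIUS * (np.cos(ang) * u + np.sin(ang) * v)
        atoms.append(
            AtomRecord(serial_start + j, name, resname, chain_id, residue_seq, pos, "C")
        )
    atoms.sort(key=lambda a: RING_ATOM_NAMES.index(a.name))
    return Residue(resname, residue_seq, atoms)


def _helix_point(index: float) -> np.ndarray:
    """Point on the ideal α-helix Cα curve at fractional residue ``index``."""
    theta = np.deg2rad(_HELIX_TWIST_DEG) * index
    return np.array(
        [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * index]
    )


def make_ideal_pilin(spec: SyntheticSpec | None = None) -> PilinStructure:
    """Idealized aromatic-bearing pilin: poly-Ala helix Cα trace + grafted rings.

    Aromatic residues carry their full six-carbon ring, grafted 3 Å radially
    outward from the Cα with the ring plane containing the helix axis
    direction. Deterministic under ``spec.seed``; optional Gaussian noise.
    """
    spec = spec or SyntheticSpec()
    rng = spec.rng()
    residues: list[Residue] = []
    serial = 1
    for i in range(spec.n_residues):
        seq = i + 1
        ca = _helix_point(i)
        aro = AROMATIC_POSITIONS.get(seq)
        resname = "ALA" if aro is None else ("PHE" if aro == "F" else "TYR")
        atoms = [AtomRecord(serial, "CA", resname, "A", seq, ca.copy(), "C")]
        serial += 1
        if aro is not None:
            radial = np.array([ca[0], ca[1], 0.0])
            radial /= np.linalg.norm(radial)
            centroid = ca + 3.0 * radial
            normal = np.cross(radial, [0.0, 0.0, 1.0])  # plane contains z and radial
            ring = make_ring(centroid, normal, aro, 0.0, seq, "A", serial)
            atoms.extend(ring.atoms)
            serial += 6
        residues.append(Residue(resname, seq, atoms))
    struct = PilinStructure("A", residues)
    if spec.noise_sigma > 0:
        noisy = [
            Residue(
                r.name,
                r.seq,
                [
                    AtomRecord(
                        a.serial,
                        a.name,
                        a.residue_name,
                        a.chain_id,
                        a.residue_seq,
                        a.position + rng.normal(0.0, spec.noise_sigma, 3),
                        a.element,
                    )
                    for a in r.atoms
                ],
            )
            for r in struct.residues
        ]
        struct = PilinStructure("A", noisy)
    return struct


def _solve_chain(
    a: np.ndarray, b: np.ndarray, d1: float, d2: float, d3: float
) -> tuple[np.ndarray, np.ndarray]:
    """Place p2, p3 with |a-p2| = d1, |p2-p3| = d2, |p3-b| = d3.

    Deterministic planar construction in the plane through a and b; raises
    :class:`InfeasibleGeometryError` when the three-link chain cannot span
    the endpoint separation.
    """
    span = b - a
    big_d = float(np.linalg.norm(span))
    total = d1 + d2 + d3
    if big_d > total + 1e-9 or big_d < 2 * max(d1, d2, d3) - total - 1e-9:
        raise InfeasibleGeometryError(
            f"distance triple ({d1}, {d2}, {d3}) cannot span the {big_d:.3f} Å "
            "separation imposed by the helical operator"
        )
    u = span / big_d
    v, _ = _orthonormal_frame(u)  # any unit vector perpendicular to u
    # pick the reach e = |p2 - b| inside the intersection of what the d1 arm
    # can produce and what the (d2, d3) pair can close
    e_lo = max(abs(d2 - d3), abs(big_d - d1))
    e_hi = min(d2 + d3, big_d + d1)
    if e_lo > e_hi + 1e-9:
        raise InfeasibleGeometryError(
            f"distance triple ({d1}, {d2}, {d3}) unreachable at separation {big_d:.3f} Å"
        )
    e = 0.5 * (e_lo + e_hi)
    cos_alpha = np.clip((big_d**2 + d1**2 - e**2) / (2 * big_d * d1), -1.0, 1.0)
    sin_alpha = np.sqrt(max(0.0, 1.0 - cos_alpha**2))
    p2 = a + d1 * (cos_alpha * u + sin_alpha * v)
    # intersect circles around p2 (radius d2) and b (radius d3), in-plane
    to_b = b - p2
    e_actual = float(np.linalg.norm(to_b))
    along = to_b / e_actual
    perp = np.cross(np.cross(along, v), along)
    if np.linalg.norm(perp) < 1e-9:
        perp = v - np.dot(v, along) * along
    perp /= np.linalg.norm(perp)
    proj = (d2**2 - d3**2 + e_actual**2) / (2 * e_actual)
    height_sq = d2**2 - proj**2
    if height_sq < -1e-9:
        raise InfeasibleGeometryError(
            f"cannot close the (d2={d2}, d3={d3}) pair at reach {e_actual:.3f} Å"
        )
    p3 = p2 + proj * along + np.sqrt(max(0.0, height_sq)) * perp
    return p2, p3


def make_pathway_pilus(spec: SyntheticSpec | None = None) -> AssemblyModel:
    """Helical assembly realizing a planted (d1, d2, d3) pathway triple.

    F1, F24, Y27 centroids of every subunit satisfy |F1-F24| = d1,
    |F24-Y27| = d2 and |Y27-F1(next)| = d3 exactly (at zero noise), repeating
    with the helical period; Y32, F51, Y57 are placed >= 8 Å away from every
    pathway ring so they stay off the shortest path at the default 7 Å
    cutoff. Verified by assertion at generation time.
    """
    spec = spec or SyntheticSpec()
    d1, d2, d3 = spec.distances
    if min(d1, d2, d3) <= 0:
        raise InfeasibleGeometryError("planted distances must be positive")
    params = HelicalParams(
        rise_per_subunit=spec.rise,
        rotation_per_subunit=spec.rotation,
        radius_to_com=spec.anchor_radius,
        n_subunits=spec.n_subunits,
    )
    p1 = np.array([spec.anchor_radius, 0.0, 0.0])
    rot, trans = params.operator(1)
    p1_next = rot @ p1 + trans
    p2, p3 = _solve_chain(p1, p1_next, d1, d2, d3)

    # ring normals along the local chain direction: a pi-stack-like geometry
    directions = {1: p2 - p1, 24: p3 - p2, 27: p1_next - p3}
    centroids = {1: p1, 24: p2, 27: p3}
    # off-pathway aromatics: parked on a wide outer shell, staggered in z
    off_shell = {32: (20.0, 40.0, 2.5), 51: (20.0, 160.0, 5.0), 57: (20.0, 280.0, 7.5)}
    for seq, (radius, azimuth_deg, z) in off_shell.items():
        az = np.deg2rad(azimuth_deg)
        centroids[seq] = np.array([radius * np.cos(az), radius * np.sin(az), z])
        directions[seq] = np.array([0.0, 0.0, 1.0])

    rng = spec.rng()
    residues = []
    serial = 1
    for seq in sorted(AROMATIC_POSITIONS):
        ring = make_ring(
            centroids[seq],
            directions[seq] / np.linalg.norm(directions[seq]),
            AROMATIC_POSITIONS[seq],
            0.0,
            seq,
            "A",
            serial,
        )
        serial += 6
        atoms = list(ring.atoms)
        if spec.noise_sigma > 0:
            atoms = [
                AtomRecord(
                    a.serial,
                    a.name,
                    a.residue_name,
                    a.chain_id,
                    a.residue_seq,
                    a.position + rng.normal(0.0, spec.noise_sigma, 3),
                    a.element,
                )
                for a in atoms
            ]
        residues.append(Residue(ring.name, seq, atoms))
    subunit = PilinStructure("A", residues)
    assembly = apply_helical_symmetry(subunit, params)

    if spec.noise_sigma == 0:
        _check_off_path_separation(centroids, params)
    return assembly


def _check_off_path_separation(centroids: dict[int, np.ndarray], params: HelicalParams) -> None:
    """Assert every off-path ring sits >= 8 Å from every pathway ring."""
    on_path = [centroids[s] for s in (1, 24, 27)]
    off_path = [centroids[s] for s in (32, 51, 57)]
    min_sep = np.inf
    for shift in range(-2, 3):  # neighboring subunits suffice by periodicity
        rot, trans = params.operator(shift)
        for c_off in off_path:
            moved = rot @ c_off + trans
            for c_on in on_path:
                min_sep = min(min_sep, float(np.linalg.norm(moved - c_on)))
    if min_sep < 8.0:
        raise InfeasibleGeometryError(
            f"off-pathway aromatics come within {min_sep:.2f} Å of the pathway "
            "(must stay >= 8 Å); adjust the synthetic layout"
        )


def add_assembly_noise(
    assembly: AssemblyModel, sigma: float, seed: int = 0
) -> AssemblyModel:
    """Independent isotropic Gaussian noise on every atom of an assembly.

    Unlike subunit-level noise (which would replicate helically), this breaks
    the exact symmetry, emulating refinement jitter; used to test planted
    parameter recovery under perturbation.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    subunits = []
    for sub in assembly.subunits:
        residues = [
            Residue(
                r.name,
                r.seq,
                [
                    AtomRecord(
                        a.serial,
                        a.name,
                        a.residue_name,
                        a.chain_id,
                        a.residue_seq,
                        a.position + rng.normal(0.0, sigma, 3),
                        a.element,
                    )
                    for a in r.atoms
                ],
            )
            for r in sub.residues
        ]
        subunits.append(PilinStructure(sub.chain_id, residues))
    return AssemblyModel(assembly.params, subunits)


def make_orbital_fixture(
    t_hole: float, t_elec: float, base_energy: float = -5.0
) -> OrbitalEnergies:
    """Dimer orbital energies whose splittings encode the given integrals.

    The HOMO/HOMO-1 splitting is 2·t_hole below ``base_energy`` and the
    LUMO/LUMO+1 splitting 2·t_elec above it, so the energy-gap scheme
    recovers (t_hole, t_elec) exactly.
    """
    if t_hole < 0 or t_elec < 0:
        raise ValueError("transfer integrals must be non-negative")
    return OrbitalEnergies(
        homo=base_energy,
        homo_minus_1=base_energy - 2.0 * t_hole,
        lumo=base_energy + 3.0,
        lumo_plus_1=base_energy + 3.0 + 2.0 * t_elec,
    )


def make_four_point_fixture(
    lambda_donor: float, lambda_acceptor: float, base_energy: float = -120.0
) -> FourPointEnergies:
    """Four-point energies summing to λ = lambda_donor + lambda_acceptor."""
    return FourPointEnergies(
        e_cn_donor=base_energy + lambda_donor,
        e_nn_donor=base_energy,
        e_nc_acceptor=base_energy + lambda_acceptor,
        e_cc_acceptor=base_energy,
    )


def make_angle_ensemble(spec: SyntheticSpec | None = None) -> np.ndarray:
    """Rotation-angle ensemble drawn from the spec's angle blobs (degrees).

    Each blob contributes ``count`` angles uniform on
    [center - half_width, center + half_width]; deterministic under the seed.
    """
    spec = spec or SyntheticSpec()
    rng = spec.rng()
    parts = [
        rng.uniform(center - half, center + half, size=count)
        for center, half, count in spec.angle_blobs
    ]
    return np.concatenate(parts) % 360.0
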