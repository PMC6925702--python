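"""Macromolecular structure I/O and geometry primitives.

Reads and writes PDB files (via Bio.PDB), identifies the six-carbon aromatic
rings of Phe/Tyr residues, and provides Kabsch superposition and
Kyte-Doolittle hydropathy utilities.

Conventions
-----------
* All coordinates are in Ångström.
* Residue numbering is the mature-pilin 1-based numbering (F1 is the first
  residue of the mature Geobacter sulfurreducens pilin).
* The "aromatic ring" of both Phe and Tyr is the six-carbon cycle
  CG, CD1, CD2, CE1, CE2, CZ; the Tyr hydroxyl oxygen is excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.SeqUtils import ProtParamData
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "Residue",
    "PilinStructure",
    "AromaticRing",
    "StructureError",
    "MissingRingAtomError",
    "RING_ATOM_NAMES",
    "AROMATIC_RESIDUES",
    "read_pdb",
    "write_pdb",
    "extract_aromatic_rings",
    "kabsch_rmsd",
    "hydropathy_profile",
    "KYTE_DOOLITTLE",
]

#: Names of the six ring carbons shared by Phe and Tyr.
RING_ATOM_NAMES: tuple[str, ...] = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")

#: Three-letter codes of the aromatic residues carrying a transfer-pathway ring.
AROMATIC_RESIDUES: frozenset[str] = frozenset({"PHE", "TYR"})

#: Kyte-Doolittle hydropathy scale (one-letter code -> score).
KYTE_DOOLITTLE: dict[str, float] = dict(ProtParamData.kd)


class StructureError(ValueError):
    """Raised for malformed or incomplete structural input."""


class MissingRingAtomError(StructureError):
    """An aromatic residue lacks one or more of its six ring carbons."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom with its PDB identity and position (Å)."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    position: np.ndarray
    element: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.name} has invalid position {self.position}")
        object.__setattr__(self, "position", pos)
        if self.residue_seq < 1:
            raise StructureError(
                f"atom {self.name}: residue_seq must be >= 1 (mature numbering), "
                f"got {self.residue_seq}"
            )


@dataclass
class Residue:
    """One residue: name, mature sequence number, and its atoms."""

    name: str
    seq: int
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, atom_name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == atom_name:
                return a
        raise KeyError(atom_name)

    def has_atom(self, atom_name: str) -> bool:
        return any(a.name == atom_name for a in self.atoms)


@dataclass
class PilinStructure:
    """A single chain of a pilin (or any protein), ordered by residue number."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        seqs = [r.seq for r in self.residues]
        if any(b <= a for a, b in zip(seqs, seqs[1:])):
            raise StructureError(
                f"chain {self.chain_id}: residue numbers must be strictly increasing"
            )

    @property
    def sequence(self) -> str:
        """One-letter sequence derived from residue names ('X' for unknowns)."""
        out = []
        for r in self.residues:
            out.append(protein_letters_3to1.get(r.name.capitalize(), "X"))
        return "".join(out)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]

    def coords(self, atom_name: str | None = None) -> np.ndarray:
        """(n, 3) array of atom positions; optionally restricted to one atom name."""
        sel = self.atoms if atom_name is None else [a for a in self.atoms if a.name == atom_name]
        if not sel:
            return np.empty((0, 3))
        return np.stack([a.position for a in sel])

    def residue(self, seq: int) -> Residue:
        for r in self.residues:
            if r.seq == seq:
                return r
        raise KeyError(f"residue {seq} not in chain {self.chain_id}")

    def transformed(
        self,
        rotation: np.ndarray | None = None,
        translation: np.ndarray | None = None,
        chain_id: str | None = None,
    ) -> "PilinStructure":
        """Return a rigidly transformed copy: x -> R x + t."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        cid = self.chain_id if chain_id is None else chain_id
        new_res = [
            Residue(
                r.name,
                r.seq,
                [
                    replace(a, chain_id=cid, position=R @ a.position + t)
                    for a in r.atoms
                ],
            )
            for r in self.residues
        ]
        return PilinStructure(cid, new_res)


@dataclass(frozen=True)
class AromaticRing:
    """The six-carbon aromatic ring of a Phe or Tyr residue.

    ``centroid`` is the arithmetic mean of the six ring carbons and ``normal``
    the unit normal of the best-fit ring plane (smallest principal component),
    oriented toward the positive-z half-space.
    """

    chain_id: str
    residue_seq: int
    residue_type: str  # "F" or "Y"
    ring_coords: np.ndarray  # (6, 3)
    centroid: np.ndarray
    normal: np.ndarray
    subunit_index: int = 0

    def __post_init__(self) -> None:
        rc = np.asarray(self.ring_coords, dtype=float)
        if rc.shape != (6, 3):
            raise StructureError("aromatic ring requires exactly six ring-carbon positions")
        object.__setattr__(self, "ring_coords", rc)
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise StructureError("ring normal must be a unit vector")
        object.__setattr__(self, "normal", n)

    @property
    def key(self) -> tuple[int, int]:
        """Deterministic node identity: (subunit index, residue number)."""
        return (self.subunit_index, self.residue_seq)


def _plane_normal(centered: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through centered points.

    The sign is chosen toward the +z half-space; if the normal is exactly
    perpendicular to z the tie cascades to +y then +x.
    """
    _, _, vt = np.linalg.svd(centered)
    n = vt[-1]
    for comp in (2, 1, 0):
        if abs(n[comp]) > 1e-12:
            if n[comp] < 0:
                n = -n
            break
    return n / np.linalg.norm(n)


def ring_from_coords(
    coords: Sequence[np.ndarray] | np.ndarray,
    chain_id: str = "A",
    residue_seq: int = 1,
    residue_type: str = "F",
    subunit_index: int = 0,
) -> AromaticRing:
    """Build an :class:`AromaticRing` directly from six carbon positions."""
    rc = np.asarray(coords, dtype=float)
    if rc.shape != (6, 3):
        raise StructureError(f"expected six ring atoms, got shape {rc.shape}")
    centroid = rc.mean(axis=0)
    normal = _plane_normal(rc - centroid)
    return AromaticRing(chain_id, residue_seq, residue_type, rc, centroid, normal, subunit_index)


def extract_aromatic_rings(structure: PilinStructure, subunit_index: int = 0) -> list[AromaticRing]:
    """Extract one ring per Phe/Tyr residue of ``structure``.

    Raises :class:`MissingRingAtomError` naming the chain and residue if any
    of the six ring carbons CG, CD1, CD2, CE1, CE2, CZ is absent.
    """
    rings: list[AromaticRing] = []
    for res in structure.residues:
        if res.name.upper() not in AROMATIC_RESIDUES:
            continue
        missing = [n for n in RING_ATOM_NAMES if not res.has_atom(n)]
        if missing:
            raise MissingRingAtomError(
                f"chain {structure.chain_id} residue {res.name}{res.seq}: "
                f"missing ring atoms {', '.join(missing)}"
            )
        coords = np.stack([res.atom(n).position for n in RING_ATOM_NAMES])
        rtype = "F" if res.name.upper() == "PHE" else "Y"
        rings.append(
            ring_from_coords(coords, structure.chain_id, res.seq, rtype, subunit_index)
        )
    return rings


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _pick_altloc(atom):
    """Return the primary conformer of a possibly disordered Bio.PDB atom."""
    if not atom.is_disordered():
        return atom
    children = atom.disordered_get_list()
    for preferred in (" ", "", "A"):
        for child in children:
            if child.get_altloc() == preferred:
                return child
    return sorted(children, key=lambda a: a.get_altloc())[0]


def read_pdb(path: str | Path, model_index: int = 0) -> list[PilinStructure]:
    """Read a PDB file into one :class:`PilinStructure` per chain.

    Only ``model_index`` of a multi-model (NMR) file is read (default: first).
    The first altloc of disordered atoms is kept. Malformed ATOM records raise
    :class:`StructureError` carrying the parser's line diagnostics; an empty
    file raises as well.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            bio_structure = parser.get_structure(path.stem, str(path))
        except (PDBConstructionException, ValueError) as exc:
            raise StructureError(f"{path}: malformed PDB record ({exc})") from exc
    models = list(bio_structure)
    if not models:
        raise StructureError(f"{path}: no coordinate records found (empty structure)")
    if model_index >= len(models):
        raise StructureError(
            f"{path}: model {model_index} requested but file has {len(models)} model(s)"
        )
    model = models[model_index]

    chains: list[PilinStructure] = []
    serial = 0
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            atoms: list[AtomRecord] = []
            resseq = res.get_id()[1]
            for atom in res:
                atom = _pick_altloc(atom)
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=atom.get_serial_number() or serial,
                        name=atom.get_name(),
                        residue_name=res.get_resname(),
                        chain_id=chain.id,
                        residue_seq=resseq,
                        position=np.asarray(atom.get_coord(), dtype=float),
                        element=atom.element or "",
                    )
                )
            if atoms:
                residues.append(Residue(res.get_resname(), resseq, atoms))
        if residues:
            chains.append(PilinStructure(chain.id, residues))
    if not chains:
        raise StructureError(f"{path}: no chains with atoms (empty structure)")
    return chains


def write_pdb(structures: Iterable[PilinStructure], path: str | Path) -> None:
    """Write chains to a PDB file (coordinates at standard 1e-3 Å precision).

    PDB chain identifiers are a single character; extended in-memory chain ids
    (two characters, used for assemblies past 62 subunits) cannot be written
    and raise :class:`StructureError`.
    """
    builder = StructureBuilder()
    builder.init_structure("pili")
    builder.init_model(0)
    serial = 0
    for struct in structures:
        if len(struct.chain_id) != 1:
            raise StructureError(
                f"chain id {struct.chain_id!r} is not a single character; "
                "the PDB format cannot represent it"
            )
        builder.init_chain(struct.chain_id)
        builder.init_seg("    ")
        for res in struct.residues:
            builder.init_residue(res.name, " ", res.seq, " ")
            for atom in res.atoms:
                serial += 1
                element = atom.element or atom.name[:1]
                builder.init_atom(
                    atom.name,
                    np.asarray(atom.position, dtype=float),
                    0.0,
                    1.0,
                    " ",
                    atom.name.center(4) if len(atom.name) < 4 else atom.name,
                    serial,
                    element,
                )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# Superposition and hydropathy
# ---------------------------------------------------------------------------

def kabsch_rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares superposition RMSD between two equal-length point sets.

    Returns ``(rmsd, rotation, translation)`` such that applying
    ``x -> rotation @ x + translation`` to every point of ``coords_b``
    attains the returned RMSD against ``coords_a``. The rotation is proper
    (determinant +1).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise StructureError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise StructureError("superposition requires >= 3 points of dimension 3")
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on near-degenerate sets
        rot, rssd = Rotation.align_vectors(a - mean_a, b - mean_b)
    R = rot.as_matrix()
    t = mean_a - R @ mean_b
    rmsd = float(rssd) / np.sqrt(a.shape[0])
    return rmsd, R, t


def hydropathy_profile(
    sequence: str,
    window: int = 9,
    scale: dict[str, float] | None = None,
) -> list[tuple[int, float]]:
    """Sliding-window mean hydropathy along a protein sequence.

    Parameters
    ----------
    sequence:
        One-letter amino-acid string (standard 20 letters).
    window:
        Odd window size, at most ``len(sequence)``.
    scale:
        Per-residue hydropathy values; defaults to Kyte-Doolittle.

    Returns
    -------
    list of ``(residue_index, score)`` with 1-based window-center indices;
    positions without a full window are omitted.
    """
    scale = KYTE_DOOLITTLE if scale is None else scale
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window > len(sequence):
        raise ValueError(f"window {window} exceeds sequence length {len(sequence)}")
    values = []
    for i, letter in enumerate(sequence):
        if letter not in scale:
            raise ValueError(f"unknown amino-acid letter {letter!r} at position {i + 1}")
        values.append(scale[letter])
    arr = np.asarray(values)
    half = window // 2
    kernel = np.ones(window) / window
    means = np.convolve(arr, kernel, mode="valid")
    return [(i + half + 1, float(m)) for i, m in enumerate(means)]
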