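"""Flat-harmonic distance restraints and ambiguous (min-over-pairs) constraints.

The restraint used during symmetric assembly is a flat harmonic: zero inside
a tolerance band around the target distance x0 and quadratic outside it,

    f(d) = 0                                  |d - x0| <= tol
    f(d) = ((d - x0 - tol) / sd)^2            d > x0 + tol
    f(d) = ((d - x0 + tol) / sd)^2            d < x0 - tol

so a pair that is either too short or too long is penalized, continuously at
both band edges. An ambiguous constraint is a set of candidate restraints
across two subunits scoring as the minimum over its candidates.

Default parameterizations: low-resolution restraints on Cα atoms with
(x0, sd, tol) = (10, 0.5, 5) Å; high-resolution restraints on N-O salt-bridge
pairs with (4, 2, 0.5) Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .assembly import AssemblyModel

__all__ = [
    "AtomSelector",
    "ConstraintSpec",
    "AmbiguousConstraint",
    "LOW_RESOLUTION_DEFAULTS",
    "HIGH_RESOLUTION_DEFAULTS",
    "flat_harmonic",
    "score_constraints",
    "default_ambiguous_constraints",
    "read_constraints",
    "write_constraints",
]

#: (x0, sd, tolerance) in Å for the coarse Cα-Cα phase.
LOW_RESOLUTION_DEFAULTS: tuple[float, float, float] = (10.0, 0.5, 5.0)

#: (x0, sd, tolerance) in Å for the all-atom N-O salt-bridge phase.
HIGH_RESOLUTION_DEFAULTS: tuple[float, float, float] = (4.0, 2.0, 0.5)


@dataclass(frozen=True)
class AtomSelector:
    """Identifies one atom in an assembly: chain, residue number, atom name."""

    chain_id: str
    residue_seq: int
    atom_name: str

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_seq}:{self.atom_name}"

    @classmethod
    def parse(cls, token: str) -> "AtomSelector":
        parts = token.split(":")
        if len(parts) != 3:
            raise ValueError(f"bad atom selector {token!r}, expected chain:res:atom")
        return cls(parts[0], int(parts[1]), parts[2])


@dataclass(frozen=True)
class ConstraintSpec:
    """A flat-harmonic restraint between two atoms."""

    atom_a: AtomSelector
    atom_b: AtomSelector
    x0: float
    sd: float
    tolerance: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")
        if self.tolerance < 0:
            raise ValueError(f"tolerance must be >= 0, got {self.tolerance}")


@dataclass(frozen=True)
class AmbiguousConstraint:
    """Min-over-candidates restraint linking residue pairs of two subunits."""

    candidates: tuple[ConstraintSpec, ...]

    def __post_init__(self) -> None:
        if len(self.candidates) < 1:
            raise ValueError("ambiguous constraint needs >= 1 candidate")


Constraint = Union[ConstraintSpec, AmbiguousConstraint]


def flat_harmonic(d: float, x0: float, sd: float, tolerance: float) -> float:
    """Flat-harmonic penalty of an observed distance ``d`` (Å)."""
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    dev = d - x0
    if abs(dev) <= tolerance:
        return 0.0
    if dev > 0:
        return ((dev - tolerance) / sd) ** 2
    return ((dev + tolerance) / sd) ** 2


def _resolve(assembly: AssemblyModel, sel: AtomSelector) -> np.ndarray:
    for sub in assembly.subunits:
        if sub.chain_id == sel.chain_id:
            try:
                return sub.residue(sel.residue_seq).atom(sel.atom_name).position
            except KeyError as exc:
                raise KeyError(f"cannot resolve atom selector {sel}") from exc
    raise KeyError(f"cannot resolve atom selector {sel}: no chain {sel.chain_id!r}")


def _pair_penalty(assembly: AssemblyModel, c: ConstraintSpec) -> float:
    pa = _resolve(assembly, c.atom_a)
    pb = _resolve(assembly, c.atom_b)
    d = float(np.linalg.norm(pa - pb))
    return flat_harmonic(d, c.x0, c.sd, c.tolerance)


def score_constraints(
    assembly: AssemblyModel, constraints: Sequence[Constraint]
) -> tuple[float, list[float]]:
    """Total restraint penalty of an assembly plus the per-constraint breakdown.

    Plain constraints contribute their flat-harmonic penalty; ambiguous
    constraints contribute the minimum penalty over their candidate pairs.
    """
    breakdown: list[float] = []
    for c in constraints:
        if isinstance(c, AmbiguousConstraint):
            breakdown.append(min(_pair_penalty(assembly, cand) for cand in c.candidates))
        else:
            breakdown.append(_pair_penalty(assembly, c))
    return float(sum(breakdown)), breakdown


def default_ambiguous_constraints(
    assembly: AssemblyModel,
    residue_pairs: Iterable[tuple[int, int]],
    x0: float = LOW_RESOLUTION_DEFAULTS[0],
    sd: float = LOW_RESOLUTION_DEFAULTS[1],
    tolerance: float = LOW_RESOLUTION_DEFAULTS[2],
    atom_name: str = "CA",
    n_upper: int = 10,
) -> list[AmbiguousConstraint]:
    """Ambiguous constraints from the middle subunit to the ``n_upper`` above it.

    By symmetry only the middle chain (index n//2) needs restraining; each
    ``(res_a, res_b)`` residue pair expands into one candidate per upper chain.
    """
    mid = assembly.n_subunits // 2
    upper = range(mid + 1, min(mid + 1 + n_upper, assembly.n_subunits))
    mid_id = assembly.subunits[mid].chain_id
    out = []
    for res_a, res_b in residue_pairs:
        cands = tuple(
            ConstraintSpec(
                AtomSelector(mid_id, res_a, atom_name),
                AtomSelector(assembly.subunits[j].chain_id, res_b, atom_name),
                x0,
                sd,
                tolerance,
            )
            for j in upper
        )
        if cands:
            out.append(AmbiguousConstraint(cands))
    return out


# ---------------------------------------------------------------------------
# Constraint-file round trip
# ---------------------------------------------------------------------------
# Format, one restraint per line:
#   PAIR chainA:res:atom chainB:res:atom x0 sd tol
# ambiguous blocks:
#   AMBIG
#       chainA:res:atom chainB:res:atom x0 sd tol
#       ...


def _parse_pair_tokens(tokens: list[str], lineno: int) -> ConstraintSpec:
    if len(tokens) != 5:
        raise ValueError(f"line {lineno}: expected 'selA selB x0 sd tol', got {tokens}")
    return ConstraintSpec(
        AtomSelector.parse(tokens[0]),
        AtomSelector.parse(tokens[1]),
        float(tokens[2]),
        float(tokens[3]),
        float(tokens[4]),
    )


def read_constraints(path: str | Path) -> list[Constraint]:
    """Parse a constraint file (see module docstring for the line format)."""
    constraints: list[Constraint] = []
    pending: list[ConstraintSpec] | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        indented = raw[0].isspace()
        tokens = raw.split()
        if indented:
            if pending is None:
                raise ValueError(f"line {lineno}: candidate line outside an AMBIG block")
            pending.append(_parse_pair_tokens(tokens, lineno))
            continue
        if pending is not None:
            constraints.append(AmbiguousConstraint(tuple(pending)))
            pending = None
        if tokens[0] == "PAIR":
            constraints.append(_parse_pair_tokens(tokens[1:], lineno))
        elif tokens[0] == "AMBIG":
            pending = []
        else:
            raise ValueError(f"line {lineno}: unknown record {tokens[0]!r}")
    if pending is not None:
        constraints.append(AmbiguousConstraint(tuple(pending)))
    return constraints


def write_constraints(constraints: Sequence[Constraint], path: str | Path) -> None:
    """Write constraints in the round-trippable text format."""
    lines = []
    for c in constraints:
        if isinstance(c, AmbiguousConstraint):
            lines.append("AMBIG")
            for cand in c.candidates:
                lines.append(
                    f"    {cand.atom_a} {cand.atom_b} {cand.x0:g} {cand.sd:g} {cand.tolerance:g}"
                )
        else:
            lines.append(f"PAIR {c.atom_a} {c.atom_b} {c.x0:g} {c.sd:g} {c.tolerance:g}")
    Path(path).write_text("\n".join(lines) + "\n")
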