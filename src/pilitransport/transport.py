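"""Marcus-theory charge transport ladder for a one-dimensional aromatic wire.

From scalar electronic-structure inputs (dimer frontier-orbital splittings
and a four-point reorganization energy) the module chains:

    t (eV)  ──►  w = (t²/ħ)·√(π/(λ·k_B·T))      rate upper bound, ΔG° = 0
    w       ──►  D = W₀·Z₀²                      1-D diffusion coefficient
    D       ──►  μ = e·D/(k_B·T)                 Einstein mobility
    geometry ──► ρ = n/(π·r₀²·z₀)                carrier number density
    ρ, μ    ──►  σ = e·ρ·(μ_h + μ_e)             conductivity
    σ       ──►  G = σ·S/l                       conductance

The rate is the ΔG° = 0 prefactor of the Marcus electron-transfer rate: an
upper bound, appropriate because the free-energy difference between
equivalent aromatic sites along a symmetric wire is unknown but bounded.
W₀ is the lowest per-step rate along the smallest symmetric pathway unit
(the rate of the bottleneck, i.e. largest-distance, step).

All energies enter in eV, lengths in Å; conversion to SI happens exactly
once, at ingestion, using :mod:`pilitransport.constants`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .constants import ANGSTROM, BOLTZMANN_EV_PER_K, ELEMENTARY_CHARGE, HBAR_EV_S
from .pathway import SymmetricUnit, bottleneck_distance

__all__ = [
    "OrbitalEnergies",
    "FourPointEnergies",
    "TransportInputs",
    "TransportResult",
    "transfer_integral",
    "reorganization_energy",
    "marcus_rate_upper",
    "diffusion_coefficient",
    "charge_mobility",
    "carrier_density",
    "conductivity",
    "conductance",
    "transport_report",
    "read_transport_inputs",
    "DEFAULT_TEMPERATURE_K",
    "DEFAULT_Z0_A",
    "DEFAULT_R0_A",
]

#: Default temperature (K). Ambient laboratory temperature for which the
#: Einstein-relation chain is internally consistent to three significant
#: figures.
DEFAULT_TEMPERATURE_K = 298.0

#: Default periodic-cell height Z0 (Å) of the 1-D diffusion step. Derived by
#: back-solving D = W0·Z0² against published model diffusion coefficients
#: (consistent across carriers and models); a derived convention, not a
#: measured value.
DEFAULT_Z0_A = 3.10

#: Default radius of the aromatic packing cylinder (Å).
DEFAULT_R0_A = 13.0


@dataclass(frozen=True)
class OrbitalEnergies:
    """Dimer frontier-orbital energies (eV) for the energy-gap scheme."""

    homo: float
    homo_minus_1: float
    lumo: float
    lumo_plus_1: float

    def __post_init__(self) -> None:
        if self.homo_minus_1 > self.homo:
            raise ValueError("HOMO-1 energy must not exceed the HOMO energy")
        if self.lumo > self.lumo_plus_1:
            raise ValueError("LUMO energy must not exceed the LUMO+1 energy")


@dataclass(frozen=True)
class FourPointEnergies:
    """Four single-point energies (eV) defining the reorganization energy.

    Subscripts: first = geometry, second = charge state. ``e_cn_donor`` is
    the neutral donor at its charged-state geometry, etc.
    """

    e_cn_donor: float
    e_nn_donor: float
    e_nc_acceptor: float
    e_cc_acceptor: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")


@dataclass(frozen=True)
class TransportInputs:
    """Scalar inputs of the transport chain.

    Transfer integrals and λ in eV; Z0, r0, conductor length in Å; conductor
    cross-section in Å². ``rho_per_m3`` optionally overrides the carrier
    density computed from (r0, z0, carriers_per_cell).
    """

    t_hole: float
    t_elec: float
    reorg_lambda: float
    temperature: float = DEFAULT_TEMPERATURE_K
    z0: float = DEFAULT_Z0_A
    r0: float = DEFAULT_R0_A
    area_s: float | None = None  # Å²
    length_l: float | None = None  # Å
    rho_per_m3: float | None = None
    carriers_per_cell: int = 4

    def __post_init__(self) -> None:
        for name in ("t_hole", "t_elec"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("reorg_lambda", "temperature", "z0", "r0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TransportResult:
    """Computed transport quantities, SI units throughout.

    ``audit`` records every intermediate value of the chain.
    """

    w_hole: float  # s^-1
    w_elec: float  # s^-1
    d_hole: float  # m^2 s^-1
    d_elec: float  # m^2 s^-1
    mu_hole: float  # m^2 V^-1 s^-1
    mu_elec: float  # m^2 V^-1 s^-1
    rho: float  # m^-3
    sigma: float  # S m^-1
    conductance: float | None  # S, None when S or l unspecified
    audit: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        out = {
            "rate_hole_per_s": self.w_hole,
            "rate_elec_per_s": self.w_elec,
            "diffusion_hole_m2_per_s": self.d_hole,
            "diffusion_elec_m2_per_s": self.d_elec,
            "mobility_hole_m2_per_Vs": self.mu_hole,
            "mobility_elec_m2_per_Vs": self.mu_elec,
            "carrier_density_per_m3": self.rho,
            "conductivity_S_per_m": self.sigma,
            "conductance_S": self.conductance,
        }
        out["audit"] = dict(self.audit)
        return out


def transfer_integral(energies: OrbitalEnergies) -> tuple[float, float]:
    """Hole and electron transfer integrals (eV) from dimer orbital splittings.

    The energy-gap scheme: t_hole is half the HOMO/HOMO-1 splitting, t_elec
    half the LUMO+1/LUMO splitting.
    """
    t_hole = (energies.homo - energies.homo_minus_1) / 2.0
    t_elec = (energies.lumo_plus_1 - energies.lumo) / 2.0
    return t_hole, t_elec


def reorganization_energy(energies: FourPointEnergies) -> float:
    """λ = λ_D + λ_A from the four single-point energies (eV)."""
    lam_d = energies.e_cn_donor - energies.e_nn_donor
    lam_a = energies.e_nc_acceptor - energies.e_cc_acceptor
    return lam_d + lam_a


def marcus_rate_upper(t: float, reorg_lambda: float, temperature: float) -> float:
    """Upper bound of the Marcus electron-transfer rate (s⁻¹), ΔG° = 0.

    w = (t²/ħ)·√(π/(λ·k_B·T)), with t and λ in eV and T in K. Equivalent to
    the textbook prefactor (2π/ħ)·t²/√(4π·λ·k_B·T).
    """
    if reorg_lambda <= 0:
        raise ValueError(f"reorganization energy must be positive, got {reorg_lambda}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    kt = BOLTZMANN_EV_PER_K * temperature
    return (t**2 / HBAR_EV_S) * math.sqrt(math.pi / (reorg_lambda * kt))


def diffusion_coefficient(w0: float, z0: float) -> float:
    """1-D diffusion coefficient D = W₀·Z₀² (m²·s⁻¹) with Z₀ in Å."""
    if w0 < 0:
        raise ValueError(f"rate must be non-negative, got {w0}")
    if z0 <= 0:
        raise ValueError(f"z0 must be positive, got {z0}")
    return w0 * (z0 * ANGSTROM) ** 2


def charge_mobility(diffusion: float, temperature: float) -> float:
    """Einstein-relation mobility μ = e·D/(k_B·T) (m²·V⁻¹·s⁻¹).

    With k_B·T expressed in eV the electron charge cancels numerically:
    μ = D / (k_B·T [eV]).
    """
    if diffusion < 0:
        raise ValueError(f"diffusion coefficient must be non-negative, got {diffusion}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return diffusion / (BOLTZMANN_EV_PER_K * temperature)


def carrier_density(r0: float, z0: float, carriers_per_cell: int = 4) -> float:
    """Aromatic-site number density ρ = n/(π·r₀²·z₀) (m⁻³); r₀, z₀ in Å.

    Four aromatic residues per symmetric unit packed in a cylinder of radius
    r₀ and height z₀.
    """
    if r0 <= 0 or z0 <= 0:
        raise ValueError("r0 and z0 must be positive")
    if carriers_per_cell < 0:
        raise ValueError("carriers_per_cell must be non-negative")
    return carriers_per_cell / (math.pi * (r0 * ANGSTROM) ** 2 * (z0 * ANGSTROM))


def conductivity(rho: float, mu_hole: float, mu_elec: float) -> float:
    """σ = e·ρ·(μ_h + μ_e) (S·m⁻¹); ρ in m⁻³, mobilities in m²·V⁻¹·s⁻¹."""
    if rho < 0 or mu_hole < 0 or mu_elec < 0:
        raise ValueError("carrier density and mobilities must be non-negative")
    return ELEMENTARY_CHARGE * rho * (mu_hole + mu_elec)


def conductance(sigma: float, area_s: float, length_l: float) -> float:
    """G = σ·S/l (S); cross-section S in Å², conductor length l in Å."""
    if area_s <= 0 or length_l <= 0:
        raise ValueError("conductor area and length must be positive")
    return sigma * (area_s * ANGSTROM**2) / (length_l * ANGSTROM)


def transport_report(unit: SymmetricUnit, inputs: TransportInputs) -> TransportResult:
    """Chain the full transport ladder for a symmetric pathway unit.

    The effective rate W₀ of each carrier is the lowest per-step rate along
    the unit; with one (t, λ) per carrier this is the rate associated with
    the bottleneck (largest) distance. The unit's bottleneck distance also
    serves as the default conductor length for the conductance when
    ``inputs.length_l`` is unset.
    """
    bottleneck = bottleneck_distance(unit)
    w_h = marcus_rate_upper(inputs.t_hole, inputs.reorg_lambda, inputs.temperature)
    w_e = marcus_rate_upper(inputs.t_elec, inputs.reorg_lambda, inputs.temperature)
    d_h = diffusion_coefficient(w_h, inputs.z0)
    d_e = diffusion_coefficient(w_e, inputs.z0)
    mu_h = charge_mobility(d_h, inputs.temperature)
    mu_e = charge_mobility(d_e, inputs.temperature)
    if inputs.rho_per_m3 is not None:
        rho = inputs.rho_per_m3
        rho_source = "input"
    else:
        rho = carrier_density(inputs.r0, inputs.z0, inputs.carriers_per_cell)
        rho_source = "computed"
    sigma = conductivity(rho, mu_h, mu_e)
    length = inputs.length_l if inputs.length_l is not None else bottleneck
    g = conductance(sigma, inputs.area_s, length) if inputs.area_s is not None else None
    audit = {
        "bottleneck_A": bottleneck,
        "unit_distances_A": list(unit.distances),
        "t_hole_eV": inputs.t_hole,
        "t_elec_eV": inputs.t_elec,
        "lambda_eV": inputs.reorg_lambda,
        "temperature_K": inputs.temperature,
        "z0_A": inputs.z0,
        "r0_A": inputs.r0,
        "rho_source": rho_source,
        "conductor_length_A": length,
        "conductor_area_A2": inputs.area_s,
    }
    return TransportResult(w_h, w_e, d_h, d_e, mu_h, mu_e, rho, sigma, g, audit)


# ---------------------------------------------------------------------------
# Input file dialect (JSON or YAML)
# ---------------------------------------------------------------------------

_INPUT_KEYS = {
    "t_hole_eV": "t_hole",
    "t_elec_eV": "t_elec",
    "lambda_eV": "reorg_lambda",
    "temperature_K": "temperature",
    "z0_A": "z0",
    "r0_A": "r0",
    "area_A2": "area_s",
    "length_A": "length_l",
    "rho_per_m3": "rho_per_m3",
    "carriers_per_cell": "carriers_per_cell",
}


def read_transport_inputs(source: str | Path | dict[str, Any]) -> TransportInputs:
    """Load :class:`TransportInputs` from a JSON/YAML file or a mapping.

    Recognized keys: t_hole_eV, t_elec_eV, lambda_eV, temperature_K, z0_A,
    r0_A, area_A2, length_A, rho_per_m3, carriers_per_cell. Unknown keys are
    rejected.
    """
    if isinstance(source, dict):
        data = dict(source)
    else:
        text = Path(source).read_text()
        data = yaml.safe_load(text) if str(source).endswith((".yml", ".yaml")) else json.loads(text)
    unknown = set(data) - set(_INPUT_KEYS)
    if unknown:
        raise ValueError(f"unknown transport-input key(s): {sorted(unknown)}")
    missing = {"t_hole_eV", "t_elec_eV", "lambda_eV"} - set(data)
    if missing:
        raise ValueError(f"missing required transport-input key(s): {sorted(missing)}")
    return TransportInputs(**{_INPUT_KEYS[k]: v for k, v in data.items()})


def write_transport_table(result: TransportResult, path: str | Path) -> None:
    """Emit a two-carrier summary table (TSV) of the transport chain."""
    rows = [
        ("Transfer integral (eV)", result.audit["t_hole_eV"], result.audit["t_elec_eV"]),
        ("Rate upper bound (s^-1)", result.w_hole, result.w_elec),
        ("Diffusion coefficient (m^2 s^-1)", result.d_hole, result.d_elec),
        ("Charge mobility (m^2 V^-1 s^-1)", result.mu_hole, result.mu_elec),
        ("Carrier density (m^-3)", result.rho, result.rho),
        ("Conductivity (S m^-1)", result.sigma, result.sigma),
        ("Conductance (S)", result.conductance, result.conductance),
    ]
    lines = ["quantity\thole\telectron"]
    for name, h, e in rows:
        hs = "" if h is None else f"{h:.6g}"
        es = "" if e is None else f"{e:.6g}"
        lines.append(f"{name}\t{hs}\t{es}")
    Path(path).write_text("\n".join(lines) + "\n")
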