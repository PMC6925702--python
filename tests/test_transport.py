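"""Marcus transport ladder: rates, diffusion, mobility, conductivity, conductance.

Published model values used as fixtures (transfer integrals in eV, diffusion
coefficients in m²/s, mobilities in m²/(V·s), conductivities in S/m):

    model 1: t_h 1.56e-2, t_e 3.25e-2, D_h 6.50e-7, D_e 2.81e-6,
             mu_h 2.53e-5, mu_e 1.09e-4, sigma 8601.51
    model 2: t_h 1.46e-2, t_e 2.93e-2, D_h 5.65e-7, D_e 2.28e-6,
             mu_h 2.19e-5, mu_e 8.86e-5, sigma 7073.26
"""

import json
import math

import pytest

from pilitransport.constants import BOLTZMANN_EV_PER_K, ELEMENTARY_CHARGE, HBAR_EV_S
from pilitransport.pathway import SymmetricUnit
from pilitransport.synthetic import make_four_point_fixture, make_orbital_fixture
from pilitransport.transport import (
    FourPointEnergies,
    OrbitalEnergies,
    TransportInputs,
    carrier_density,
    charge_mobility,
    conductance,
    conductivity,
    diffusion_coefficient,
    marcus_rate_upper,
    read_transport_inputs,
    reorganization_energy,
    transfer_integral,
    transport_report,
)
from conftest import GS1_DISTANCES, LAMBDA_EV, RHO_PER_M3


def make_unit(distances=GS1_DISTANCES):
    """Minimal symmetric unit carrying a given distance triple."""
    import numpy as np

    from pilitransport.structure import ring_from_coords
    from pilitransport.synthetic import make_ring

    z = np.cumsum((0.0,) + tuple(distances))
    rings = []
    for i, zz in enumerate(z):
        res = make_ring(np.array([0.0, 0.0, zz]), np.array([0.0, 0.0, 1.0]), "F")
        coords = np.stack([a.position for a in res.atoms])
        rings.append(ring_from_coords(coords, "A", 1, "F", subunit_index=i))
    return SymmetricUnit(rings)


class TestTransferIntegral:
    def test_half_the_homo_splitting(self):
        t_h, _ = transfer_integral(OrbitalEnergies(-5.0, -5.2, -1.0, -0.9))
        assert t_h == pytest.approx(0.1)

    def test_degenerate_pair_gives_zero(self):
        t_h, t_e = transfer_integral(OrbitalEnergies(-5.0, -5.0, -1.0, -1.0))
        assert t_h == 0.0 and t_e == 0.0

    def test_published_electron_splitting(self):
        # LUMO splitting of 6.50e-2 eV encodes t_e = 3.25e-2 eV
        energies = OrbitalEnergies(-5.0, -5.5, -1.0, -1.0 + 6.50e-2)
        _, t_e = transfer_integral(energies)
        assert t_e == pytest.approx(3.25e-2)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            OrbitalEnergies(-5.2, -5.0, -1.0, -0.9)


class TestReorganization:
    def test_component_sum(self):
        lam = reorganization_energy(make_four_point_fixture(0.19, 0.18))
        assert lam == pytest.approx(0.37)

    def test_all_equal_energies_give_zero(self):
        assert reorganization_energy(FourPointEnergies(-3.0, -3.0, -3.0, -3.0)) == 0.0

    def test_donor_only_contribution(self):
        lam = reorganization_energy(make_four_point_fixture(0.21, 0.0))
        assert lam == pytest.approx(0.21)


class TestMarcusRate:
    def test_zero_coupling_gives_zero_rate(self):
        assert marcus_rate_upper(0.0, 0.37, 298.0) == 0.0

    def test_closed_form_value(self):
        # independent arithmetic: (t^2/hbar) * sqrt(pi / (lambda kT))
        t, lam, temp = 3.25e-2, 0.37, 298.0
        expected = (t * t / HBAR_EV_S) * math.sqrt(
            math.pi / (lam * BOLTZMANN_EV_PER_K * temp)
        )
        assert expected == pytest.approx(2.92e13, rel=5e-3)
        assert marcus_rate_upper(t, lam, temp) == pytest.approx(expected, rel=1e-12)

    def test_quadratic_in_coupling(self):
        w1 = marcus_rate_upper(0.01, 0.37, 298.0)
        w2 = marcus_rate_upper(0.02, 0.37, 298.0)
        assert w2 == pytest.approx(4 * w1, rel=1e-12)

    def test_nonpositive_lambda_or_temperature_rejected(self):
        with pytest.raises(ValueError):
            marcus_rate_upper(0.01, 0.0, 298.0)
        with pytest.raises(ValueError):
            marcus_rate_upper(0.01, 0.37, 0.0)


class TestDiffusionAndMobility:
    def test_unit_cell_conversion(self):
        assert diffusion_coefficient(1e13, 1.0) == pytest.approx(1e-7)
        assert diffusion_coefficient(0.0, 1.0) == 0.0

    def test_chained_from_bottleneck_rate(self):
        w = marcus_rate_upper(3.25e-2, LAMBDA_EV, 298.0)
        assert diffusion_coefficient(w, 3.10) == pytest.approx(2.8e-6, rel=0.02)

    @pytest.mark.parametrize(
        "diffusion,expected",
        [(2.81e-6, 1.09e-4), (6.50e-7, 2.53e-5), (2.28e-6, 8.86e-5), (5.65e-7, 2.19e-5)],
    )
    def test_einstein_relation_reproduces_published_mobilities(self, diffusion, expected):
        assert charge_mobility(diffusion, 298.0) == pytest.approx(expected, rel=0.015)

    def test_mobility_over_diffusion_ratio_consistent_across_models(self):
        pairs = [(2.81e-6, 1.09e-4), (6.50e-7, 2.53e-5), (2.28e-6, 8.86e-5), (5.65e-7, 2.19e-5)]
        ratios = [mu / d for d, mu in pairs]
        assert max(ratios) / min(ratios) < 1.01


class TestDensityConductivityConductance:
    def test_cylinder_density(self):
        assert carrier_density(13.0, 18.83) == pytest.approx(4.0e26, rel=0.01)
        assert carrier_density(13.0, 2 * 18.83) == pytest.approx(
            carrier_density(13.0, 18.83) / 2
        )
        assert carrier_density(13.0, 18.83, carriers_per_cell=0) == 0.0

    @pytest.mark.parametrize(
        "mu_h,mu_e,expected",
        [(2.53e-5, 1.09e-4, 8601.51), (2.19e-5, 8.86e-5, 7073.26)],
    )
    def test_conductivity_reproduces_published_values(self, mu_h, mu_e, expected):
        assert conductivity(RHO_PER_M3, mu_h, mu_e) == pytest.approx(expected, rel=0.005)

    def test_zero_density_gives_zero_conductivity(self):
        assert conductivity(0.0, 1.0, 1.0) == 0.0

    def test_conductance_unit_sanity(self):
        # 1 S/m conductor of 1 m^2 cross-section and 1 m length -> 1 S
        assert conductance(1.0, 1e20, 1e10) == pytest.approx(1.0)
        assert conductance(8.60e3, 30.0, 6.1) == pytest.approx(4.2e-6, rel=0.01)
        assert conductance(1.0, 10.0, 4.0) == pytest.approx(2 * conductance(1.0, 10.0, 8.0))


class TestTransportReport:
    def make_inputs(self, **over):
        defaults = dict(
            t_hole=1.56e-2,
            t_elec=3.25e-2,
            reorg_lambda=LAMBDA_EV,
            temperature=298.0,
            z0=3.10,
            rho_per_m3=RHO_PER_M3,
            area_s=30.0,
        )
        defaults.update(over)
        return TransportInputs(**defaults)

    def test_chain_equals_manual_composition(self):
        unit = make_unit()
        inputs = self.make_inputs()
        res = transport_report(unit, inputs)
        w_h = marcus_rate_upper(inputs.t_hole, inputs.reorg_lambda, inputs.temperature)
        w_e = marcus_rate_upper(inputs.t_elec, inputs.reorg_lambda, inputs.temperature)
        d_h = diffusion_coefficient(w_h, inputs.z0)
        d_e = diffusion_coefficient(w_e, inputs.z0)
        mu_h = charge_mobility(d_h, inputs.temperature)
        mu_e = charge_mobility(d_e, inputs.temperature)
        sigma = conductivity(RHO_PER_M3, mu_h, mu_e)
        assert (res.w_hole, res.w_elec) == (w_h, w_e)
        assert (res.d_hole, res.d_elec) == (d_h, d_e)
        assert (res.mu_hole, res.mu_elec) == (mu_h, mu_e)
        assert res.sigma == sigma
        assert res.conductance == conductance(sigma, 30.0, max(GS1_DISTANCES))

    def test_bottleneck_distance_sets_conductor_length(self):
        res = transport_report(make_unit(), self.make_inputs())
        assert res.audit["bottleneck_A"] == pytest.approx(6.1)
        assert res.audit["conductor_length_A"] == pytest.approx(6.1)

    def test_zero_couplings_give_zero_transport(self):
        res = transport_report(make_unit(), self.make_inputs(t_hole=0.0, t_elec=0.0))
        assert res.w_hole == res.w_elec == 0.0
        assert res.sigma == 0.0

    def test_sigma_homogeneous_of_degree_two_in_coupling(self):
        base = transport_report(make_unit(), self.make_inputs())
        for c in (0.5, 2.0, 3.0):
            scaled = transport_report(
                make_unit(), self.make_inputs(t_hole=c * 1.56e-2, t_elec=c * 3.25e-2)
            )
            assert scaled.sigma == pytest.approx(c**2 * base.sigma, rel=1e-9)

    def test_density_computed_when_no_override(self):
        res = transport_report(make_unit(), self.make_inputs(rho_per_m3=None, z0=3.10))
        assert res.rho == pytest.approx(carrier_density(13.0, 3.10))
        assert res.audit["rho_source"] == "computed"


class TestInputsIO:
    def test_json_round_trip(self, tmp_path):
        block = {
            "t_hole_eV": 1.56e-2,
            "t_elec_eV": 3.25e-2,
            "lambda_eV": 0.37,
            "temperature_K": 298.0,
            "z0_A": 3.10,
            "rho_per_m3": 4.0e26,
            "area_A2": 30.0,
        }
        p = tmp_path / "inputs.json"
        p.write_text(json.dumps(block))
        inputs = read_transport_inputs(p)
        assert inputs.t_elec == pytest.approx(3.25e-2)
        assert inputs.rho_per_m3 == pytest.approx(4.0e26)

    def test_unknown_and_missing_keys_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown"):
            read_transport_inputs({"t_hole_eV": 1e-2, "t_elec_eV": 1e-2,
                                   "lambda_eV": 0.37, "bogus": 1})
        with pytest.raises(ValueError, match="missing"):
            read_transport_inputs({"t_hole_eV": 1e-2})


class TestOrbitalFixtures:
    @pytest.mark.parametrize("t_h,t_e", [(1.56e-2, 3.25e-2), (1.46e-2, 2.93e-2)])
    def test_published_integrals_round_trip(self, t_h, t_e):
        got = transfer_integral(make_orbital_fixture(t_h, t_e))
        assert got == pytest.approx((t_h, t_e), rel=1e-12)

    def test_degenerate_fixture(self):
        fx = make_orbital_fixture(0.0, 0.0)
        assert fx.homo == fx.homo_minus_1 and fx.lumo == fx.lumo_plus_1

    def test_base_energy_gauge_invariance(self):
        for base in (-10.0, 0.0, 3.7):
            got = transfer_integral(make_orbital_fixture(0.02, 0.03, base_energy=base))
            assert got == pytest.approx((0.02, 0.03), rel=1e-12)
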