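"""Elastic energies, relaxation, shear modulus, and bead probing."""

import numpy as np
import pytest

from emtecm.lattice import LatticeSpec, average_connectivity, build_lattice
from emtecm.mechanics import (
    DegenerateProbeError,
    ElasticParams,
    TrapSetup,
    assemble_hessian,
    energy_and_gradient,
    probe_compliance,
    relax,
    shear_modulus,
    total_energy,
)
from emtecm.workbench import make_fixture

AFFINE_G = np.sqrt(3.0) / 4.0  # closed-form shear modulus of the full lattice


class TestEnergy:
    def test_stretched_single_bond(self):
        net = make_fixture("single-bond")
        pos = net.node_positions()
        pos[1, 0] += 0.1
        e, _ = total_energy(net, pos, ElasticParams(k=1.0, kappa=0.0))
        assert e == pytest.approx(0.005, rel=1e-12)

    def test_bent_triple(self):
        net = make_fixture("bend-triple")
        pos = net.node_positions()
        th = 0.1
        c, s = np.cos(th), np.sin(th)
        v = pos[2] - pos[1]
        pos[2] = pos[1] + np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])
        e, _ = total_energy(net, pos, ElasticParams(k=1.0, kappa=1.0))
        assert e == pytest.approx(0.005, rel=1e-9)

    def test_rest_configuration_is_zero_energy(self, small_disordered_net, elastic):
        pos = small_disordered_net.node_positions()
        e, g = total_energy(small_disordered_net, pos, elastic, gamma=0.0)
        assert e == pytest.approx(0.0, abs=1e-24)
        assert np.abs(g).max() == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motions_leave_energy_invariant(self, small_disordered_net, elastic, rng):
        """Translations and rotations of any configuration cost nothing."""
        net = small_disordered_net
        pos = net.node_positions() + 0.1 * rng.standard_normal((net.n_nodes, 2))
        e0, _ = total_energy(net, pos, elastic)
        e1, _ = total_energy(net, pos + np.array([1.3, -0.7]), elastic)
        th = 0.4
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        # rotation only commutes with the periodic images in a fixed box,
        # so test it on the bonds' displacement form via a fixed fixture
        fixture = make_fixture("bend-triple")
        fpos = fixture.node_positions() + 0.05 * rng.standard_normal((3, 2))
        ef0, _ = total_energy(fixture, fpos, elastic)
        ef1, _ = total_energy(fixture, fpos @ R.T, elastic)
        assert e1 == pytest.approx(e0, rel=1e-12, abs=1e-15)
        assert ef1 == pytest.approx(ef0, rel=1e-10, abs=1e-15)

    def test_analytic_gradient_matches_finite_differences(self, small_disordered_net, rng):
        net = small_disordered_net
        params = ElasticParams(k=1.0, kappa=0.01)
        pos = net.node_positions() + 0.05 * rng.standard_normal((net.n_nodes, 2))
        es, eb, g = energy_and_gradient(net, pos, params, gamma=0.02)
        h = 1e-6
        idx = rng.choice(net.n_nodes, size=10, replace=False)
        for n in idx:
            for c in range(2):
                pp = pos.copy()
                pp[n, c] += h
                e1 = sum(energy_and_gradient(net, pp, params, 0.02)[:2])
                pp[n, c] -= 2 * h
                e2 = sum(energy_and_gradient(net, pp, params, 0.02)[:2])
                num = (e1 - e2) / (2 * h)
                assert num == pytest.approx(g[n, c], rel=1e-6, abs=1e-8)

    def test_hessian_matches_finite_difference_gradient(self, rng):
        net = build_lattice(LatticeSpec(4, 4, 0.9, 0.5, seed=3))
        params = ElasticParams(k=1.0, kappa=0.01)
        pos = net.node_positions() + 0.05 * rng.standard_normal((net.n_nodes, 2))
        H = assemble_hessian(net, pos, params, gamma=0.02).toarray()
        assert np.abs(H - H.T).max() < 1e-12
        h = 1e-6
        for q in rng.choice(2 * net.n_nodes, size=6, replace=False):
            pp = pos.copy()
            pp[q // 2, q % 2] += h
            g1 = energy_and_gradient(net, pp, params, 0.02)[2].ravel()
            pp[q // 2, q % 2] -= 2 * h
            g2 = energy_and_gradient(net, pp, params, 0.02)[2].ravel()
            np.testing.assert_allclose((g1 - g2) / (2 * h), H[:, q],
                                       rtol=1e-5, atol=1e-7)

    def test_zero_length_bond_raises(self):
        net = make_fixture("single-bond")
        pos = net.node_positions()
        pos[1] = pos[0]
        with pytest.raises(FloatingPointError):
            total_energy(net, pos, ElasticParams())


class TestRelax:
    def test_unstrained_network_stays_at_rest(self, small_disordered_net, elastic):
        res = relax(small_disordered_net, elastic, gamma=0.0)
        assert res.converged
        assert res.e_total == pytest.approx(0.0, abs=1e-18)

    def test_full_lattice_relaxes_to_affine(self):
        """With kappa=0 the full triangular lattice deforms affinely."""
        net = build_lattice(LatticeSpec(6, 6, 1.0, 0.0, seed=0))
        params = ElasticParams(k=1.0, kappa=0.0, force_tol=1e-10)
        gamma = 1e-3
        res = relax(net, params, gamma=gamma)
        pos_affine = net.node_positions()
        pos_affine[:, 0] += gamma * pos_affine[:, 1]
        e_aff, _ = total_energy(net, pos_affine, params, gamma=gamma)
        assert res.converged
        assert res.e_total == pytest.approx(e_aff, rel=1e-6)


class TestShearModulus:
    def test_full_lattice_closed_form(self):
        net = build_lattice(LatticeSpec(8, 8, 1.0, 0.0, seed=0))
        res = shear_modulus(net, ElasticParams(k=1.0, kappa=0.0, gamma0=1e-4))
        assert res.converged
        assert res.modulus == pytest.approx(AFFINE_G, rel=1e-2)

    def test_five_point_stencil_agrees(self):
        net = build_lattice(LatticeSpec(6, 6, 1.0, 0.0, seed=0))
        p = ElasticParams(k=1.0, kappa=0.0, gamma0=1e-4)
        g3 = shear_modulus(net, p, stencil=3).modulus
        g5 = shear_modulus(net, p, stencil=5).modulus
        assert g5 == pytest.approx(g3, rel=1e-4)

    def test_subisostatic_floppy_then_bend_dominated(self):
        """Below z=4: G ~ 0 for kappa=0 and G = O(kappa) for small kappa."""
        net = build_lattice(LatticeSpec(14, 14, 0.8, 0.75, seed=1))
        assert average_connectivity(net) < 4.0
        g_cf = shear_modulus(net, ElasticParams(k=1.0, kappa=0.0, gamma0=5e-3)).modulus
        assert abs(g_cf) < 1e-5
        g_bend = shear_modulus(
            net, ElasticParams(k=1.0, kappa=1e-4, force_tol=1e-9, gamma0=5e-3)
        ).modulus
        assert 0 < g_bend < 1e-2

    def test_strain_stiffening_below_isostatic(self):
        """G(gamma) rises by orders of magnitude along the rising branch."""
        net = build_lattice(LatticeSpec(12, 12, 0.7, 0.6, seed=2))
        p = ElasticParams(k=1.0, kappa=1e-6, force_tol=1e-9, gamma0=5e-3)
        gammas = [0.0, 0.1, 0.3]
        gs = [shear_modulus(net, p, gamma=g).modulus for g in gammas]
        assert all(g >= -1e-8 for g in gs)
        assert gs[-1] > 100 * max(gs[0], 1e-8)
        assert gs[1] <= gs[2]

    def test_requires_periodic_boundary(self):
        net = build_lattice(LatticeSpec(4, 4, 1.0, 0.0, seed=0, boundary="fixed"))
        with pytest.raises(ValueError):
            shear_modulus(net, ElasticParams())


class TestProbe:
    def test_single_spring_compliance(self):
        net, trap = make_fixture("one-spring-probe")
        res = probe_compliance(net, ElasticParams(k=2.0, kappa=0.0), trap)
        assert res.converged
        assert res.compliance == pytest.approx(0.5, rel=1e-3)

    def test_clamped_bead_has_zero_compliance(self):
        """A bead pinned by an infinitely stiff surrounding does not move."""
        net, trap = make_fixture("one-spring-probe")
        res = probe_compliance(net, ElasticParams(k=1e9, kappa=0.0), trap)
        assert res.compliance == pytest.approx(0.0, abs=1e-8)

    def test_compliance_independent_of_dtrap(self):
        net = build_lattice(LatticeSpec(12, 12, 0.9, 0.4, seed=2, boundary="fixed"))
        c = 0.5 * (net.box_vectors[0] + net.box_vectors[1])
        p = ElasticParams(k=1.0, kappa=1e-4)
        j1 = probe_compliance(net, p, TrapSetup(center=tuple(c), bead_radius=1.2,
                                                ktrap=1.0, dtrap=0.02)).compliance
        j2 = probe_compliance(net, p, TrapSetup(center=tuple(c), bead_radius=1.2,
                                                ktrap=1.0, dtrap=0.04)).compliance
        assert abs(j2 - j1) / j1 < 0.02

    def test_lower_pphan_stiffens(self):
        p = ElasticParams(k=1.0, kappa=1e-4)
        nets = [build_lattice(LatticeSpec(12, 12, 0.9, ph, seed=5, boundary="fixed"))
                for ph in (0.6, 0.1)]
        c = 0.5 * (nets[0].box_vectors[0] + nets[0].box_vectors[1])
        trap = TrapSetup(center=tuple(c), bead_radius=1.2, ktrap=1.0, dtrap=0.02)
        j_soft = probe_compliance(nets[0], p, trap).compliance
        j_stiff = probe_compliance(nets[1], p, trap).compliance
        assert j_stiff < j_soft

    def test_detached_bead_raises(self):
        net = build_lattice(LatticeSpec(12, 12, 0.9, 0.4, seed=2, boundary="fixed"))
        c = 0.5 * (net.box_vectors[0] + net.box_vectors[1]) + np.array([0.31, 0.27])
        trap = TrapSetup(center=tuple(c), bead_radius=1e-6, ktrap=1.0, dtrap=0.02)
        with pytest.raises(DegenerateProbeError):
            probe_compliance(net, ElasticParams(), trap)
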