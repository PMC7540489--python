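"""Point-dipole couplings, Hamiltonian assembly and exciton-state properties."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringdye.excitons import (
    build_hamiltonian,
    diagonalize,
    dipole_coupling,
    dye_band_couplings,
    group_bands,
    ring_subhamiltonian,
)
from ringdye.exceptions import MissingDyeError, SingularGeometryError
from ringdye.geometry import TransitionDipole, add_dye, build_ring

from .conftest import point_dipole_assembly


def dip(origin, direction, mu=1.0, e=12500.0):
    d = np.array(direction, float)
    return TransitionDipole(np.array(origin, float), d / np.linalg.norm(d), mu, e)


class TestDipoleCoupling:
    def test_si_reference_value(self):
        """1 D x 1 D, parallel, side-by-side at 1 nm in vacuum: mu^2/(4 pi eps0 R^3).

        Oracle: direct SI evaluation from CODATA constants via scipy.constants.
        """
        from scipy.constants import c, epsilon_0, h, pi

        debye = 1e-21 / c  # C m
        expected = debye**2 / (4 * pi * epsilon_0 * (1e-9) ** 3) / (h * c * 100.0)
        v = dipole_coupling(dip([0, 0, 0], [0, 0, 1]), dip([1, 0, 0], [0, 0, 1]))
        assert v == pytest.approx(expected, rel=1e-6)
        assert v == pytest.approx(5.03, abs=0.01)

    def test_parallel_side_by_side_kappa_one(self):
        v = dipole_coupling(dip([0, 0, 0], [0, 0, 1]), dip([2, 0, 0], [0, 0, 1]))
        v_ref = dipole_coupling(dip([0, 0, 0], [0, 1, 0]), dip([2, 0, 0], [0, 1, 0]))
        assert v == pytest.approx(v_ref)  # kappa = 1 either way
        assert v > 0

    def test_collinear_head_to_tail_kappa_minus_two(self):
        v_side = dipole_coupling(dip([0, 0, 0], [0, 0, 1]), dip([1.5, 0, 0], [0, 0, 1]))
        v_line = dipole_coupling(dip([0, 0, 0], [0, 0, 1]), dip([0, 0, 1.5], [0, 0, 1]))
        assert v_line == pytest.approx(-2.0 * v_side, rel=1e-12)

    def test_screening_reduces_coupling_by_n_squared(self):
        d1, d2 = dip([0, 0, 0], [0, 0, 1]), dip([1, 0, 0], [0, 0, 1])
        assert dipole_coupling(d1, d2, 1.424) == pytest.approx(
            dipole_coupling(d1, d2) / 1.424**2, rel=1e-12
        )

    def test_coincident_origins_raise(self):
        with pytest.raises(SingularGeometryError):
            dipole_coupling(dip([0, 0, 0], [0, 0, 1]), dip([0, 0, 0], [1, 0, 0]))


RING_KW = dict(site_energy_tangential=13100.0, site_energy_axial=12350.0,
               mu_tangential=5.0, mu_axial=0.65)


def full_assembly(conformer="A"):
    return add_dye(build_ring(6, 1.2, **RING_KW), conformer, 0.4, 13793.0, 11.0)


class TestBuildHamiltonian:
    def test_single_site(self):
        g = point_dipole_assembly([([0, 0, 0], [0, 0, 1], 2.0, 14000.0)])
        h = build_hamiltonian(g)
        assert h.matrix.shape == (1, 1) and h.matrix[0, 0] == 14000.0

    def test_symmetric_dimer_matrix(self):
        e, d = 12500.0, 1.0
        g = point_dipole_assembly(
            [([0, 0, 0], [0, 0, 1], 1.0, e), ([d, 0, 0], [0, 0, 1], 1.0, e)]
        )
        h = build_hamiltonian(g).matrix
        v = dipole_coupling(dip([0, 0, 0], [0, 0, 1]), dip([d, 0, 0], [0, 0, 1]))
        assert np.allclose(h, [[e, v], [v, e]])

    def test_hermiticity(self):
        h = build_hamiltonian(full_assembly("B"), screening_n=1.424).matrix
        assert np.max(np.abs(h - h.T)) < 1e-9

    def test_intra_site_transitions_uncoupled(self):
        g = build_ring(6, 1.2, **RING_KW)
        h = build_hamiltonian(g)
        ids = g.transition_site_ids()
        same_site = np.equal.outer(ids, ids) & ~np.eye(len(ids), dtype=bool)
        assert np.all(h.matrix[same_site] == 0.0)

    def test_c6_symmetry_of_dye_row(self):
        """Conformer A: dye couples identically to the six axial transitions and
        exactly zero to every tangential one (orientation-factor cancellation)."""
        g = full_assembly("A")
        h = build_hamiltonian(g).matrix
        dye = g.dye_transition_index()
        labels = [t.label for t in g.transitions()]
        ax = [h[dye, i] for i in range(len(labels)) if labels[i] == "ring-axial"]
        tg = [h[dye, i] for i in range(len(labels)) if labels[i] == "ring-tangential"]
        assert np.ptp(ax) < 1e-9 and ax[0] > 0
        assert np.max(np.abs(tg)) < 1e-12

    def test_r_cubed_scaling(self):
        """Doubling every inter-site distance divides all couplings by 8."""
        g1 = full_assembly("B")
        g2 = add_dye(build_ring(6, 2.4, **RING_KW), "B", 0.8, 13793.0, 11.0)
        h1, h2 = build_hamiltonian(g1).matrix, build_hamiltonian(g2).matrix
        off = ~np.eye(h1.shape[0], dtype=bool)
        nz = off & (np.abs(h1) > 1e-30)
        assert np.allclose(h1[nz] / h2[nz], 8.0, rtol=1e-9)
        assert np.allclose(h2[off & ~nz], 0.0, atol=1e-30)


class TestDiagonalize:
    def test_dimer_splitting_is_2v(self):
        e, d = 12500.0, 1.2
        g = point_dipole_assembly(
            [([0, 0, 0], [0, 0, 1], 1.5, e), ([d, 0, 0], [0, 0, 1], 1.5, e)]
        )
        h = build_hamiltonian(g)
        v = h.matrix[0, 1]
        states = diagonalize(h)
        assert states.energies[0] == pytest.approx(e - v, abs=1e-9)
        assert states.energies[1] == pytest.approx(e + v, abs=1e-9)

    def test_h_aggregate_dimer_dark_lower_state(self):
        """Parallel side-by-side dipoles: all strength in the upper state."""
        g = point_dipole_assembly(
            [([0, 0, 0], [0, 0, 1], 1.0, 12500.0), ([1, 0, 0], [0, 0, 1], 1.0, 12500.0)]
        )
        states = diagonalize(build_hamiltonian(g))
        assert states.dipole_strengths[0] == pytest.approx(0.0, abs=1e-12)
        assert states.dipole_strengths[1] == pytest.approx(2.0, rel=1e-9)

    def test_coefficients_orthonormal(self):
        states = diagonalize(build_hamiltonian(full_assembly("A")))
        c = states.coefficients
        assert np.max(np.abs(c.T @ c - np.eye(c.shape[0]))) < 1e-8

    @given(
        n_sites=st.integers(2, 6),
        radius=st.floats(0.8, 3.0),
        mu_t=st.floats(0.5, 8.0),
        mu_a=st.floats(0.1, 3.0),
        conformer=st.sampled_from(["A", "B"]),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_dipole_strength_sum_rule(self, n_sites, radius, mu_t, mu_a, conformer):
        """Sum over states of |mu_k|^2 equals the basis sum (orthogonal transform).

        Oracle: direct summation over the basis dipoles.
        """
        g = add_dye(
            build_ring(n_sites, radius, 13100.0, 12350.0, mu_t, mu_a),
            conformer, 0.4, 13793.0, 11.0,
        )
        states = diagonalize(build_hamiltonian(g, 1.424))
        basis_total = sum(t.magnitude**2 for t in g.transitions())
        assert states.dipole_strengths.sum() == pytest.approx(basis_total, rel=1e-6)

    def test_basis_order_independence(self):
        g = full_assembly("A")
        g_rev = dataclasses.replace(g, sites=list(reversed(g.sites)))
        e1 = diagonalize(build_hamiltonian(g, 1.424)).energies
        e2 = diagonalize(build_hamiltonian(g_rev, 1.424)).energies
        assert np.allclose(e1, e2, atol=1e-9)


class TestBandsAndCouplings:
    def test_group_bands_chain_clustering(self):
        e = np.array([0.0, 30.0, 55.0, 200.0, 240.0])
        bands = group_bands(e, tol=50.0)
        assert [list(b) for b in bands] == [[0, 1, 2], [3, 4]]

    def test_missing_dye_raises(self):
        g = build_ring(6, 1.2, **RING_KW)
        h = build_hamiltonian(g)
        with pytest.raises(MissingDyeError):
            dye_band_couplings(h, diagonalize(h), g)

    def test_zero_dye_coupling_gives_zero_profile(self):
        g = full_assembly("A")
        h = build_hamiltonian(g, 1.424, dye_coupling_scale=0.0)
        ring_states = diagonalize(ring_subhamiltonian(h, g))
        prof = dye_band_couplings(h, ring_states, g)
        assert np.max(prof.coupling_cm1) < 1e-12

    def test_only_axial_band_couples_in_conformer_a(self, fitted):
        """Symmetry: the dye couples to the axial (lowest, 810 nm) band only."""
        prof = fitted.coupling_profile("A")
        assert prof.band_center_nm[0] == pytest.approx(810.0, abs=0.5)
        assert prof.lowest_band_coupling > 1.0
        assert np.max(prof.coupling_cm1[1:]) < 1e-9

    def test_rss_coupling_conserved_under_disorder(self, fitted):
        """Completeness: disorder redistributes but conserves sum_k V_k^2."""
        from ringdye.geometry import DisorderModel, sample_disorder

        g = fitted.assembly("A")
        n = fitted.config.medium.refractive_index
        total0 = None
        for real in sample_disorder(g, DisorderModel(200.0, 3, seed=5)):
            h = build_hamiltonian(real, n)
            states = diagonalize(ring_subhamiltonian(h, real))
            prof = dye_band_couplings(h, states, real)
            total = np.sum(prof.coupling_cm1**2)
            total0 = total if total0 is None else total0
            assert total == pytest.approx(total0, rel=1e-9)
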