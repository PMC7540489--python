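"""Golden-rule rates, spectral overlaps, and ensemble transfer distributions."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ringdye.geometry import ConformerEnsemble, DisorderModel, sample_disorder
from ringdye.exceptions import InvalidParameterError
from ringdye.spectra import LineshapeParams
from ringdye.transfer import (
    RATE_PREFACTOR,
    golden_rule_rate,
    spectral_overlap,
    transfer_distribution,
    transfer_result,
)

from ._oracles import exact_decay_rate, overlap_by_quadrature


class TestGoldenRuleRate:
    def test_zero_coupling_zero_rate(self):
        assert golden_rule_rate(0.0, 1e-3) == 0.0

    def test_quadratic_in_coupling(self):
        assert golden_rule_rate(10.0, 2e-3) == pytest.approx(
            4.0 * golden_rule_rate(5.0, 2e-3), rel=1e-12
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            golden_rule_rate(-1.0, 1e-3)

    def test_matches_exact_unitary_dynamics(self):
        """Rate for a Lorentzian density at resonance vs brute-force dynamics.

        The Weisskopf-Wigner reference: one level coupled to a dense
        equidistant manifold reproducing the same Lorentzian J.  Agreement
        within 5 % in the weak-coupling regime (V << bandwidth).
        """
        v, gamma = 7.0, 50.0
        j_resonance = 1.0 / (math.pi * gamma)
        k_model = golden_rule_rate(v, j_resonance)
        k_exact = exact_decay_rate(v, gamma)
        assert k_model == pytest.approx(k_exact, rel=0.05)


class TestSpectralOverlap:
    def test_identical_gaussians_closed_form(self):
        """Two unit-area Gaussians, FWHM f, same center: J = 2*sqrt(ln2/(2*pi))/f."""
        f = 350.0
        lp = LineshapeParams(shape="gaussian", fwhm=f)
        expected = math.sqrt(math.log(2.0) / math.pi) * 2.0 / f / math.sqrt(2.0)
        assert spectral_overlap(12500.0, lp, 12500.0, lp) == pytest.approx(
            expected, rel=1e-9
        )

    @pytest.mark.parametrize(
        "shape1,shape2", [("gaussian", "gaussian"), ("lorentzian", "lorentzian"),
                          ("gaussian", "lorentzian")]
    )
    @pytest.mark.parametrize("detuning", [0.0, 185.6, 700.0])
    def test_against_quadrature(self, shape1, shape2, detuning):
        lp1 = LineshapeParams(shape=shape1, fwhm=350.0)
        lp2 = LineshapeParams(shape=shape2, fwhm=280.0)
        j = spectral_overlap(12500.0, lp1, 12500.0 + detuning, lp2)
        assert j == pytest.approx(
            overlap_by_quadrature(12500.0, lp1, 12500.0 + detuning, lp2), rel=1e-4
        )

    def test_vanishes_at_large_separation(self):
        lp = LineshapeParams(shape="gaussian", fwhm=300.0)
        assert spectral_overlap(12000.0, lp, 18000.0, lp) < 1e-12

    def test_maximal_at_zero_detuning(self):
        lp = LineshapeParams(fwhm=350.0)
        j0 = spectral_overlap(12500.0, lp, 12500.0, lp)
        for d in (50.0, 200.0, 500.0):
            assert spectral_overlap(12500.0, lp, 12500.0 + d, lp) < j0


class TestTransferResult:
    def test_zero_coupling_infinite_time_flagged(self, fitted, lineshape):
        res = transfer_result(
            fitted.assembly("A"), lineshape,
            screening_n=fitted.config.medium.refractive_index,
            stokes_shift_cm1=fitted.config.lineshape.stokes_shift_cm1,
            dye_coupling_scale=0.0,
        )
        assert res.total_rate == 0.0
        assert math.isinf(res.transfer_time) and not res.finite

    def test_band_rates_sum_to_total(self, fitted):
        res = fitted.transfer("A")
        assert res.per_band.rate_ps_inv.sum() == pytest.approx(
            res.total_rate, abs=1e-9
        )
        assert res.transfer_time == pytest.approx(1.0 / res.total_rate, rel=1e-12)

    def test_rate_increases_toward_resonance(self, fitted, lineshape):
        """Monotonicity in the overlap: rates grow as the donor emission
        approaches the acceptor band at fixed couplings."""
        g = fitted.assembly("A")
        n = fitted.config.medium.refractive_index
        band = 1e7 / 810.0
        dye_e = fitted.config.energies.dye_energy_cm1
        detunings = [900.0, 600.0, 300.0, 0.0]
        rates = [
            transfer_result(g, lineshape, n, stokes_shift_cm1=dye_e - band - d).total_rate
            for d in detunings
        ]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_rotation_invariance(self, fitted, lineshape):
        """Transfer time is invariant under rigid SO(3) rotation of the assembly."""
        g = fitted.assembly("B")
        n = fitted.config.medium.refractive_index
        stokes = fitted.config.lineshape.stokes_shift_cm1
        t0 = transfer_result(g, lineshape, n, stokes).transfer_time
        rot = Rotation.random(random_state=7).as_matrix()
        t1 = transfer_result(g.rotated(rot), lineshape, n, stokes).transfer_time
        assert t1 == pytest.approx(t0, rel=1e-6)


class TestTransferDistribution:
    def test_degenerate_without_disorder(self, fitted, lineshape):
        """sigma=0, one conformer: every sample equals the deterministic result."""
        g = fitted.assembly("A")
        n = fitted.config.medium.refractive_index
        stokes = fitted.config.lineshape.stokes_shift_cm1
        ref = transfer_result(g, lineshape, n, stokes).transfer_time
        dist = transfer_distribution(
            ConformerEnsemble.single(g), DisorderModel(0.0, 20, seed=1),
            lineshape, n, stokes,
        )
        assert np.allclose(dist.samples, ref, rtol=1e-12)

    def test_fixed_seed_bitwise_reproducible(self, fitted, lineshape):
        n = fitted.config.medium.refractive_index
        stokes = fitted.config.lineshape.stokes_shift_cm1
        ens = ConformerEnsemble.from_conformers(fitted.assembly("A"), fitted.assembly("B"))
        dm = DisorderModel(250.0, 200, seed=77)
        d1 = transfer_distribution(ens, dm, lineshape, n, stokes)
        d2 = transfer_distribution(ens, dm, lineshape, n, stokes)
        assert np.array_equal(d1.samples, d2.samples)

    def test_matches_naive_per_realization_path(self, fitted, lineshape):
        """The fast diagonal-update engine reproduces geometry-by-geometry
        transfer_result computations for the same disorder draws."""
        g = fitted.assembly("A")
        n = fitted.config.medium.refractive_index
        stokes = fitted.config.lineshape.stokes_shift_cm1
        dm = DisorderModel(250.0, 10, seed=123)
        dist = transfer_distribution(ConformerEnsemble.single(g), dm, lineshape, n, stokes)
        naive = [
            transfer_result(real, lineshape, n, stokes).transfer_time
            for real in sample_disorder(g, dm)
        ]
        assert np.allclose(dist.samples, naive, rtol=1e-9)

    def test_prob_within_is_empirical_cdf(self, fitted, lineshape):
        n = fitted.config.medium.refractive_index
        stokes = fitted.config.lineshape.stokes_shift_cm1
        dist = transfer_distribution(
            ConformerEnsemble.single(fitted.assembly("A")),
            DisorderModel(250.0, 300, seed=5), lineshape, n, stokes,
        )
        ts = [0.5, 1.0, 2.0, 5.0, 50.0]
        probs = [dist.prob_within(t) for t in ts]
        assert all(b >= a for a, b in zip(probs, probs[1:]))  # monotone
        for t, p in zip(ts, probs):
            assert p == pytest.approx(np.mean(dist.samples < t))
        assert dist.prob_within(np.inf) == 1.0

    def test_mean_rate_definition(self, fitted, lineshape):
        n = fitted.config.medium.refractive_index
        stokes = fitted.config.lineshape.stokes_shift_cm1
        dist = transfer_distribution(
            ConformerEnsemble.single(fitted.assembly("B")),
            DisorderModel(200.0, 150, seed=8), lineshape, n, stokes,
        )
        assert dist.mean_rate == pytest.approx(
            np.mean(1.0 / dist.samples), rel=1e-12
        )

    def test_summary_and_bootstrap(self, fitted, lineshape):
        n = fitted.config.medium.refractive_index
        stokes = fitted.config.lineshape.stokes_shift_cm1
        dist = transfer_distribution(
            ConformerEnsemble.single(fitted.assembly("A")),
            DisorderModel(250.0, 400, seed=2), lineshape, n, stokes,
        )
        s = dist.summary()
        lo, hi = s["median_ci95_ps"]
        assert lo <= s["median_ps"] <= hi
        assert s["n"] == 400 and s["seed"] == 2
        assert 0.0 <= s["p_lt_50ps"] <= 1.0


def test_rate_prefactor_is_4pi2_c():
    assert RATE_PREFACTOR == pytest.approx(4 * math.pi**2 * 2.99792458e-2, rel=1e-12)
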