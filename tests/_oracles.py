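"""Independent numerical oracles used by the test suite.

Kept separate from the library: these recompute reference values by brute
force (exact unitary dynamics, numerical quadrature) and must never call
the code paths they validate.
"""

import numpy as np

# speed of light in cm/ps, written out independently of the package constants
_C_CM_PS = 2.99792458e-2


def exact_decay_rate(v_total: float, gamma_hwhm: float,
                     spacing: float = 2.0, span: float = 2000.0) -> float:
    """Decay rate of one level coupled to a dense Lorentzian-weighted manifold.

    Discretizes a continuum of states at ``spacing`` cm^-1 over +-``span``
    around resonance, with couplings v_j = V*sqrt(L(E_j)*spacing) so that the
    coupling-weighted density reproduces a Lorentzian of HWHM ``gamma_hwhm``.
    Exact unitary evolution of the (N+1)-level system then gives a survival
    probability whose log-slope is the reference (Weisskopf-Wigner) rate.
    """
    e = np.arange(-span, span + spacing / 2, spacing)
    lorentz = (gamma_hwhm / np.pi) / (e**2 + gamma_hwhm**2)
    v = v_total * np.sqrt(lorentz * spacing)
    n = e.size
    h = np.zeros((n + 1, n + 1))
    h[0, 1:] = v
    h[1:, 0] = v
    h[np.arange(1, n + 1), np.arange(1, n + 1)] = e
    w, u = np.linalg.eigh(h)
    pop0 = u[0, :] ** 2  # |<donor|k>|^2

    k_expected = 4 * np.pi**2 * _C_CM_PS * v_total**2 * lorentz.max()
    times = np.linspace(0.2 / k_expected, 1.2 / k_expected, 25)
    amp = np.exp(-2j * np.pi * _C_CM_PS * np.outer(times, w)) @ pop0
    surv = np.abs(amp) ** 2
    slope = np.polyfit(times, np.log(surv), 1)[0]
    return -float(slope)


def overlap_by_quadrature(center1, lp1, center2, lp2, n_points=400001, half_width=2e4):
    """Overlap integral of two unit-area lines by direct trapezoidal quadrature."""
    e = np.linspace(-half_width, half_width, n_points) + 0.5 * (center1 + center2)
    return float(np.trapezoid(lp1.kernel(e - center1) * lp2.kernel(e - center2), e))
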