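"""Physical constants and unit conversions.

Internal unit system: positions in nm, transition dipoles in Debye,
energies in cm^-1, time in ps, temperature in K.
"""

import math

PLANCK_J_S = 6.62607015e-34
C_CM_S = 2.99792458e10
#: speed of light in cm/ps, the conversion between cm^-1 and angular ps^-1 / (2*pi)
C_CM_PS = C_CM_S * 1e-12
HC_J_CM = PLANCK_J_S * C_CM_S

#: 1 Debye in C*m
DEBYE_C_M = 1e-21 / 2.99792458e8
#: 4*pi*eps0 in C^2 J^-1 m^-1
FOUR_PI_EPS0 = 1.11265005545e-10

#: Coupling prefactor: mu1*mu2/R^3 with mu in Debye, R in nm -> cm^-1.
#: Numerically ~5.034 cm^-1 for 1 D x 1 D at 1 nm in vacuum.
DIPOLE_COUPLING_CM1 = DEBYE_C_M**2 / (FOUR_PI_EPS0 * 1e-27 * HC_J_CM)

#: Boltzmann constant in kJ mol^-1 K^-1
KB_KJ_MOL_K = 8.31446261815324e-3

#: lambda(nm) = NM_PER_CM1 / E(cm^-1)
NM_PER_CM1 = 1.0e7

#: FWHM -> Gaussian sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def wavelength_nm(energy_cm1: float) -> float:
    """Convert a transition energy in cm^-1 to its wavelength in nm."""
    return NM_PER_CM1 / energy_cm1


def wavenumber_cm1(wavelength_nm_: float) -> float:
    """Convert a wavelength in nm to energy in cm^-1."""
    return NM_PER_CM1 / wavelength_nm_
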