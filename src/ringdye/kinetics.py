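"""Rate-competition analysis of fluorescence quenching.

The dye's excited state decays either as in the free rotaxane (total rate
1/tau_fl, radiative + nonradiative) or by energy transfer to the nanoring
(rate k_ET).  The donor-band brightness ratio of the complex relative to the
free dye under equal excitation is then the branching fraction

    r = (1/tau_fl) / (1/tau_fl + k_ET)

which inverts in closed form to k_ET = (1 - r) / (r * tau_fl).  With the
measured r = 0.0051 and tau_fl = 0.97 ns this places the transfer time near
5 ps, well under the 10 ps bound implied by >99 % quenching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .exceptions import InvalidParameterError

__all__ = [
    "KineticScheme",
    "brightness_ratio_from_rate",
    "transfer_time_from_brightness",
    "quenching_efficiency",
    "quenching_report",
]

PS_PER_NS = 1000.0


@dataclass
class KineticScheme:
    """Measured photophysical scalars of the donor and the complex."""

    tau_fl_donor: float  # ns
    brightness_ratio: float  # dimensionless, in [0, 1]
    phi_donor: Optional[float] = None  # fluorescence quantum yield, fraction
    phi_complex: Optional[float] = None
    k_et: Optional[float] = None  # ps^-1, filled by analysis

    def __post_init__(self):
        if self.tau_fl_donor <= 0:
            raise InvalidParameterError("tau_fl_donor must be > 0")
        if not 0.0 <= self.brightness_ratio <= 1.0:
            raise InvalidParameterError("brightness_ratio must lie in [0, 1]")
        for name in ("phi_donor", "phi_complex"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")


def brightness_ratio_from_rate(k_et_ps_inv: float, tau_fl_ns: float) -> float:
    """Donor-channel brightness ratio r = k_fl / (k_fl + k_ET)."""
    if k_et_ps_inv < 0:
        raise InvalidParameterError("k_ET must be >= 0")
    if tau_fl_ns <= 0:
        raise InvalidParameterError("tau_fl must be > 0")
    k_fl = 1.0 / (tau_fl_ns * PS_PER_NS)
    return k_fl / (k_fl + k_et_ps_inv)


def transfer_time_from_brightness(r: float, tau_fl_ns: float) -> float:
    """Invert the brightness ratio into a transfer time, ps.

    tau_ET = 1/k_ET with k_ET = (1 - r) / (r * tau_fl).
    """
    if not 0.0 < r < 1.0:
        raise InvalidParameterError(
            "brightness ratio must lie strictly inside (0, 1): "
            "r=0 implies an infinite rate, r=1 a zero rate"
        )
    if tau_fl_ns <= 0:
        raise InvalidParameterError("tau_fl must be > 0")
    k_et = (1.0 - r) / (r * tau_fl_ns * PS_PER_NS)
    return 1.0 / k_et


def quenching_efficiency(r: float) -> float:
    """Fraction of donor emission suppressed by the ring: 1 - r."""
    if not 0.0 <= r <= 1.0:
        raise InvalidParameterError("brightness ratio must lie in [0, 1]")
    return 1.0 - r


def quenching_report(scheme: KineticScheme) -> dict:
    """Full inversion of the quenching observables into rate/time estimates."""
    r = scheme.brightness_ratio
    tau_et = transfer_time_from_brightness(r, scheme.tau_fl_donor)
    report = {
        "r": r,
        "tau_fl_ns": scheme.tau_fl_donor,
        "k_ET_ps_inv": 1.0 / tau_et,
        "tau_ET_ps": tau_et,
        "quenching_efficiency": quenching_efficiency(r),
    }
    if scheme.phi_donor is not None:
        report["phi_donor"] = scheme.phi_donor
    if scheme.phi_complex is not None:
        report["phi_complex"] = scheme.phi_complex
    return report
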