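"""Run configuration: schema-validated parameter blocks with physical defaults.

Defaults encode the calibrated dye-in-nanoring study conditions: a six-site
ring of radius 1.2 nm in CH2Cl2 (n = 1.424), Gaussian lineshapes of FWHM
350 cm^-1, the dye absorbing at the 725 nm excitation wavelength with a
Stokes shift placing its emission at the observed 798 nm, conformers A/B
split by 0.7 kJ/mol at 298 K, and 250 cm^-1 static site-energy disorder.
Unknown keys are rejected; a seed is mandatory whenever more than one
disorder realization is requested.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .constants import wavenumber_cm1
from .exceptions import ConfigError

__all__ = ["RunConfig", "load_config", "config_hash"]

_DYE_ABS_NM = 725.0  # excitation wavelength of the brightness measurement
_DYE_EM_NM = 798.0  # donor emission maximum


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Block):
    n_sites: int = Field(6, ge=2)
    ring_radius_nm: float = Field(1.2, gt=0)
    axial_offset_b_nm: float = Field(0.4, gt=0)


class EnergiesConfig(_Block):
    """Site energies (cm^-1) and dipole magnitudes (Debye); calibration refines
    the tangential/axial energies and the axial magnitude."""

    site_energy_tangential_cm1: float = Field(13120.0, gt=0)
    site_energy_axial_cm1: float = Field(12350.0, gt=0)
    dye_energy_cm1: float = Field(wavenumber_cm1(_DYE_ABS_NM), gt=0)
    mu_tangential_d: float = Field(5.0, gt=0)
    mu_axial_d: float = Field(0.65, gt=0)
    mu_dye_d: float = Field(11.0, gt=0)


class MediumConfig(_Block):
    refractive_index: float = Field(1.424, gt=0)  # CH2Cl2


class LineshapeConfig(_Block):
    shape: str = "gaussian"
    fwhm_cm1: float = Field(350.0, gt=0)
    grid_min_nm: float = 650.0
    grid_max_nm: float = 900.0
    grid_step_nm: float = Field(0.25, gt=0)
    stokes_shift_cm1: float = Field(
        wavenumber_cm1(_DYE_ABS_NM) - wavenumber_cm1(_DYE_EM_NM), ge=0
    )


class CalibrationConfig(_Block):
    targets_nm: List[float] = Field(default_factory=lambda: [810.0, 765.0])
    dye_coupling_target_cm1: Optional[float] = 25.0
    band_tolerance_cm1: float = Field(50.0, gt=0)


class DisorderConfig(_Block):
    sigma_cm1: float = Field(250.0, ge=0)
    n_realizations: int = Field(5000, ge=1)
    seed: Optional[int] = 2026


class EnsembleConfig(_Block):
    delta_e_kj_mol: float = 0.7  # conformer B above A
    temperature_k: float = Field(298.0, gt=0)


class KineticsConfig(_Block):
    brightness_ratio: float = Field(0.0051, ge=0, le=1)
    tau_fl_ns: float = Field(0.97, gt=0)
    phi_donor: float = Field(0.36, ge=0, le=1)
    phi_complex: float = Field(0.006, ge=0, le=1)


class OutputConfig(_Block):
    directory: str = "ringdye_out"
    write_plots: bool = False


class RunConfig(_Block):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    energies: EnergiesConfig = Field(default_factory=EnergiesConfig)
    medium: MediumConfig = Field(default_factory=MediumConfig)
    lineshape: LineshapeConfig = Field(default_factory=LineshapeConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    disorder: DisorderConfig = Field(default_factory=DisorderConfig)
    ensemble: EnsembleConfig = Field(default_factory=EnsembleConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)

    @model_validator(mode="after")
    def _seed_required_for_ensembles(self):
        if self.disorder.n_realizations > 1 and self.disorder.seed is None:
            raise ValueError("disorder.seed is required when n_realizations > 1")
        return self

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config; defaults fill missing blocks.

    Raises :class:`ConfigError` listing the offending keys on schema
    violations (unknown keys, wrong types, out-of-range values).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as err:
        locs = "; ".join(
            "/".join(str(p) for p in e["loc"]) + f": {e['msg']}" for e in err.errors()
        )
        raise ConfigError(f"invalid configuration ({locs})") from err


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 of the canonical JSON serialization (reproducibility manifest)."""
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
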