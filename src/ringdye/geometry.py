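"""Synthetic molecular geometries for the dye-in-nanoring assembly.

Builds the optical-site model of a six-porphyrin nanoring with a cyanine
dye threaded along its axis.  Each porphyrin carries two orthogonal Q-band
transition dipoles — one tangential to the ring circle, one parallel to the
ring axis — and the dye carries a single transition along the axis.  Two
conformers are supported: A (dye centered in the plane of the zinc centers)
and B (dye shifted toward one rim of the ring).  Gaussian static site-energy
disorder generates the realization ensembles consumed downstream.

Coordinate convention: ring plane is z = 0, ring axis is +z, site 0 sits on
the +x axis.  Positions in nm, dipoles in Debye, energies in cm^-1.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .constants import KB_KJ_MOL_K
from .exceptions import DuplicateSiteError, InvalidParameterError

__all__ = [
    "TransitionDipole",
    "ChromophoreSite",
    "AssemblyGeometry",
    "ConformerEnsemble",
    "DisorderModel",
    "build_ring",
    "build_dye_only",
    "add_dye",
    "sample_disorder",
    "boltzmann_weights",
    "geometry_to_json",
    "geometry_from_json",
    "geometry_to_xyz",
]

_UNIT_TOL = 1e-9


@dataclass(eq=False)
class TransitionDipole:
    """A point transition dipole: position, orientation, strength and energy."""

    origin: np.ndarray  # nm
    direction: np.ndarray  # unit vector
    magnitude: float  # Debye
    site_energy: float  # cm^-1
    label: str = ""

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.origin.shape != (3,) or self.direction.shape != (3,):
            raise InvalidParameterError("origin and direction must be 3-vectors")
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-6:
            raise InvalidParameterError(f"direction must be a unit vector, |d|={norm}")
        # snap to exactly unit length so downstream identities hold to 1e-9
        self.direction = self.direction / norm
        if not self.magnitude > 0:
            raise InvalidParameterError("dipole magnitude must be > 0")
        if not self.site_energy > 0:
            raise InvalidParameterError("site energy must be > 0")

    @property
    def moment(self) -> np.ndarray:
        """Dipole vector magnitude*direction (Debye)."""
        return self.magnitude * self.direction

    def shifted(self, delta_energy: float) -> "TransitionDipole":
        """Copy with the site energy shifted by ``delta_energy`` (cm^-1)."""
        return dataclasses.replace(self, site_energy=self.site_energy + delta_energy)


@dataclass(eq=False)
class ChromophoreSite:
    """One chromophore: a ring porphyrin (2 orthogonal transitions) or the dye (1)."""

    id: int
    role: str  # "ring" | "dye"
    transitions: List[TransitionDipole]

    def __post_init__(self):
        if self.role not in ("ring", "dye"):
            raise InvalidParameterError(f"unknown site role {self.role!r}")
        n = len(self.transitions)
        if self.role == "ring":
            if n != 2:
                raise InvalidParameterError("ring sites carry exactly 2 transitions")
            dot = float(np.dot(self.transitions[0].direction, self.transitions[1].direction))
            if abs(dot) > 1e-6:
                raise InvalidParameterError("ring-site transitions must be orthogonal")
        elif n != 1:
            raise InvalidParameterError("the dye carries exactly 1 transition")


@dataclass(eq=False)
class AssemblyGeometry:
    """Full optical-site geometry of one conformer (or a bare component)."""

    sites: List[ChromophoreSite]
    conformer: str  # "A" | "B" | "ring_only" | "dye_only"
    ring_radius: float  # nm
    dye_axial_offset: float = 0.0  # nm; 0 for conformer A

    def __post_init__(self):
        if self.conformer not in ("A", "B", "ring_only", "dye_only"):
            raise InvalidParameterError(f"unknown conformer {self.conformer!r}")

    # -- views ------------------------------------------------------------

    def transitions(self) -> List[TransitionDipole]:
        """All transition dipoles, sites in order, transitions in site order."""
        return [t for s in self.sites for t in s.transitions]

    def ring_sites(self) -> List[ChromophoreSite]:
        return [s for s in self.sites if s.role == "ring"]

    def dye_site(self) -> ChromophoreSite | None:
        for s in self.sites:
            if s.role == "dye":
                return s
        return None

    @property
    def n_transitions(self) -> int:
        return sum(len(s.transitions) for s in self.sites)

    def transition_site_ids(self) -> np.ndarray:
        """Site id of each transition, aligned with :meth:`transitions`."""
        return np.array([s.id for s in self.sites for _ in s.transitions])

    def dye_transition_index(self) -> int | None:
        """Index of the dye transition within :meth:`transitions`, or None."""
        idx = 0
        for s in self.sites:
            for _ in s.transitions:
                if s.role == "dye":
                    return idx
                idx += 1
        return None

    # -- transformed copies ------------------------------------------------

    def with_energy_shifts(self, shifts: Sequence[float]) -> "AssemblyGeometry":
        """Copy with per-transition site-energy shifts (cm^-1), in transition order."""
        shifts = np.asarray(shifts, dtype=float)
        if shifts.shape != (self.n_transitions,):
            raise InvalidParameterError(
                f"need {self.n_transitions} shifts, got {shifts.shape}"
            )
        new_sites = []
        k = 0
        for s in self.sites:
            new_tr = []
            for t in s.transitions:
                new_tr.append(t.shifted(float(shifts[k])))
                k += 1
            new_sites.append(ChromophoreSite(s.id, s.role, new_tr))
        return dataclasses.replace(self, sites=new_sites)

    def rotated(self, rotation: np.ndarray) -> "AssemblyGeometry":
        """Copy rigidly rotated by a 3x3 rotation matrix about the origin."""
        rotation = np.asarray(rotation, dtype=float)
        new_sites = []
        for s in self.sites:
            new_tr = [
                dataclasses.replace(
                    t, origin=rotation @ t.origin, direction=rotation @ t.direction
                )
                for t in s.transitions
            ]
            new_sites.append(ChromophoreSite(s.id, s.role, new_tr))
        return dataclasses.replace(self, sites=new_sites)


@dataclass
class ConformerEnsemble:
    """Boltzmann-weighted set of conformers (A/B split by ``delta_e`` kJ/mol)."""

    members: List[Tuple[AssemblyGeometry, float]]
    delta_e: float  # kJ/mol
    temperature: float  # K

    def __post_init__(self):
        w = sum(w for _, w in self.members)
        if abs(w - 1.0) > 1e-9:
            raise InvalidParameterError(f"conformer weights must sum to 1, got {w}")

    @classmethod
    def from_conformers(
        cls,
        geom_a: AssemblyGeometry,
        geom_b: AssemblyGeometry,
        delta_e: float = 0.7,
        temperature: float = 298.0,
    ) -> "ConformerEnsemble":
        """A/B ensemble with Boltzmann weights for B lying ``delta_e`` above A."""
        w_a, w_b = boltzmann_weights(delta_e, temperature)
        return cls([(geom_a, w_a), (geom_b, w_b)], delta_e, temperature)

    @classmethod
    def single(cls, geom: AssemblyGeometry) -> "ConformerEnsemble":
        return cls([(geom, 1.0)], delta_e=0.0, temperature=298.0)


def boltzmann_weights(delta_e_kj_mol: float, temperature_k: float) -> Tuple[float, float]:
    """Two-state Boltzmann weights (ground, excited) for an energy gap in kJ/mol."""
    if temperature_k <= 0:
        raise InvalidParameterError("temperature must be > 0")
    b = math.exp(-delta_e_kj_mol / (KB_KJ_MOL_K * temperature_k))
    return 1.0 / (1.0 + b), b / (1.0 + b)


@dataclass
class DisorderModel:
    """Static Gaussian site-energy disorder: N(0, sigma_site) per transition."""

    sigma_site: float  # cm^-1
    n_realizations: int
    seed: int

    def __post_init__(self):
        if self.sigma_site < 0:
            raise InvalidParameterError("sigma_site must be >= 0")
        if self.n_realizations < 1:
            raise InvalidParameterError("n_realizations must be >= 1")


# ---------------------------------------------------------------------------
# builders


def build_ring(
    n_sites: int,
    ring_radius: float,
    site_energy_tangential: float,
    site_energy_axial: float,
    mu_tangential: float,
    mu_axial: float,
) -> AssemblyGeometry:
    """Ring of ``n_sites`` porphyrin-like sites on a circle of ``ring_radius``.

    Site k sits at angle 2*pi*k/n_sites in the z=0 plane and carries one
    transition tangent to the circle and one parallel to +z, both originating
    at the site position.
    """
    if n_sites < 2:
        raise InvalidParameterError("a ring needs at least 2 sites")
    if ring_radius <= 0:
        raise InvalidParameterError("ring_radius must be > 0")
    for name, v in (
        ("site_energy_tangential", site_energy_tangential),
        ("site_energy_axial", site_energy_axial),
        ("mu_tangential", mu_tangential),
        ("mu_axial", mu_axial),
    ):
        if v <= 0:
            raise InvalidParameterError(f"{name} must be > 0")

    sites = []
    for k in range(n_sites):
        theta = 2.0 * math.pi * k / n_sites
        origin = np.array(
            [ring_radius * math.cos(theta), ring_radius * math.sin(theta), 0.0]
        )
        tangent = np.array([-math.sin(theta), math.cos(theta), 0.0])
        axial = np.array([0.0, 0.0, 1.0])
        sites.append(
            ChromophoreSite(
                id=k,
                role="ring",
                transitions=[
                    TransitionDipole(origin, tangent, mu_tangential,
                                     site_energy_tangential, "ring-tangential"),
                    TransitionDipole(origin, axial, mu_axial,
                                     site_energy_axial, "ring-axial"),
                ],
            )
        )
    return AssemblyGeometry(sites=sites, conformer="ring_only", ring_radius=ring_radius)


def build_dye_only(dye_energy: float, dye_mu: float,
                   axial_offset: float = 0.0) -> AssemblyGeometry:
    """A bare dye on the z-axis (for component spectra)."""
    site = ChromophoreSite(
        id=0,
        role="dye",
        transitions=[
            TransitionDipole(
                np.array([0.0, 0.0, axial_offset]),
                np.array([0.0, 0.0, 1.0]),
                dye_mu,
                dye_energy,
                "dye",
            )
        ],
    )
    return AssemblyGeometry(sites=[site], conformer="dye_only", ring_radius=0.0,
                            dye_axial_offset=axial_offset)


def add_dye(
    geom: AssemblyGeometry,
    conformer: str,
    axial_offset_b: float,
    dye_energy: float,
    dye_mu: float,
) -> AssemblyGeometry:
    """Thread the dye along the ring axis: conformer A at z=0, B at z=axial_offset_b.

    The dye transition dipole points along +z (the ring axis).
    """
    if geom.dye_site() is not None:
        raise DuplicateSiteError("assembly already contains a dye site")
    if geom.conformer != "ring_only":
        raise InvalidParameterError("add_dye expects a ring_only geometry")
    if conformer not in ("A", "B"):
        raise InvalidParameterError("conformer must be 'A' or 'B'")
    if conformer == "B" and not axial_offset_b > 0:
        raise InvalidParameterError("conformer B requires axial_offset_b > 0")
    offset = 0.0 if conformer == "A" else float(axial_offset_b)
    dye = ChromophoreSite(
        id=max(s.id for s in geom.sites) + 1,
        role="dye",
        transitions=[
            TransitionDipole(
                np.array([0.0, 0.0, offset]),
                np.array([0.0, 0.0, 1.0]),
                dye_mu,
                dye_energy,
                "dye",
            )
        ],
    )
    return AssemblyGeometry(
        sites=list(geom.sites) + [dye],
        conformer=conformer,
        ring_radius=geom.ring_radius,
        dye_axial_offset=offset,
    )


# ---------------------------------------------------------------------------
# disorder


def sample_disorder(
    geom: AssemblyGeometry, dm: DisorderModel
) -> List[AssemblyGeometry]:
    """Disorder realizations: independent N(0, sigma) shifts on every transition.

    Deterministic given ``dm.seed``; identical seeds yield bitwise-identical
    energy sequences.
    """
    rng = np.random.default_rng(dm.seed)
    out = []
    for _ in range(dm.n_realizations):
        shifts = rng.normal(0.0, dm.sigma_site, size=geom.n_transitions)
        if dm.sigma_site == 0:
            shifts = np.zeros(geom.n_transitions)
        out.append(geom.with_energy_shifts(shifts))
    return out


# ---------------------------------------------------------------------------
# serialization


def geometry_to_json(geom: AssemblyGeometry, path=None) -> str:
    """Serialize a geometry to JSON records (one per transition)."""
    records = []
    for s in geom.sites:
        for t in s.transitions:
            records.append(
                {
                    "id": s.id,
                    "role": s.role,
                    "origin": t.origin.tolist(),
                    "direction": t.direction.tolist(),
                    "magnitude_D": t.magnitude,
                    "site_energy_cm1": t.site_energy,
                    "label": t.label,
                }
            )
    payload = {
        "conformer": geom.conformer,
        "ring_radius_nm": geom.ring_radius,
        "dye_axial_offset_nm": geom.dye_axial_offset,
        "transitions": records,
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def geometry_from_json(source: str) -> AssemblyGeometry:
    """Inverse of :func:`geometry_to_json` (accepts a JSON string or a path)."""
    try:
        payload = json.loads(source)
    except (json.JSONDecodeError, TypeError):
        with open(source) as fh:
            payload = json.load(fh)
    by_site: dict = {}
    roles: dict = {}
    order: list = []
    for rec in payload["transitions"]:
        sid = rec["id"]
        if sid not in by_site:
            by_site[sid] = []
            order.append(sid)
        roles[sid] = rec["role"]
        by_site[sid].append(
            TransitionDipole(
                np.array(rec["origin"]),
                np.array(rec["direction"]),
                rec["magnitude_D"],
                rec["site_energy_cm1"],
                rec.get("label", ""),
            )
        )
    sites = [ChromophoreSite(sid, roles[sid], by_site[sid]) for sid in order]
    return AssemblyGeometry(
        sites=sites,
        conformer=payload["conformer"],
        ring_radius=payload["ring_radius_nm"],
        dye_axial_offset=payload.get("dye_axial_offset_nm", 0.0),
    )


def geometry_to_xyz(geom: AssemblyGeometry, path=None) -> str:
    """Flat XYZ-style text of site origins (Zn for ring sites, C for the dye)."""
    lines = [str(len(geom.sites)), f"ring-dye assembly conformer={geom.conformer}"]
    for s in geom.sites:
        x, y, z = s.transitions[0].origin * 10.0  # nm -> Angstrom
        el = "Zn" if s.role == "ring" else "C"
        lines.append(f"{el} {x:.4f} {y:.4f} {z:.4f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
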