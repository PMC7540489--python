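"""Frenkel exciton Hamiltonian of coupled transition dipoles.

The assembly's optical transitions form the site basis; diagonal entries are
the site transition energies and off-diagonal entries the point-dipole
couplings, screened by the solvent refractive index as 1/n^2.  The two
orthogonal Q transitions on the same porphyrin are not mutually coupled
(coincident origins make the point-dipole kernel singular; symmetry sets the
interaction to zero).

Diagonalizing yields the exciton states whose vector transition dipoles are
the coefficient-weighted sums of the basis dipoles; near-degenerate ring
eigenstates are grouped into bands, and the root-sum-square coupling of the
dye basis state to each band gives the dye->band coupling profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd

from .constants import DIPOLE_COUPLING_CM1, wavelength_nm
from .exceptions import InvalidParameterError, MissingDyeError, SingularGeometryError
from .geometry import AssemblyGeometry, TransitionDipole

__all__ = [
    "ExcitonHamiltonian",
    "ExcitonStates",
    "CouplingProfile",
    "dipole_coupling",
    "orientation_factor",
    "build_hamiltonian",
    "diagonalize",
    "group_bands",
    "dye_band_couplings",
    "ring_subhamiltonian",
]

#: eigenstates closer than this (cm^-1) are grouped into one exciton band
DEFAULT_BAND_TOL = 50.0


def orientation_factor(d1: np.ndarray, d2: np.ndarray, r_hat: np.ndarray) -> float:
    """kappa = d1.d2 - 3 (d1.R)(d2.R) for unit vectors; ranges -2..+1."""
    return float(np.dot(d1, d2) - 3.0 * np.dot(d1, r_hat) * np.dot(d2, r_hat))


def dipole_coupling(
    d1: TransitionDipole, d2: TransitionDipole, screening_n: float = 1.0
) -> float:
    """Point-dipole coupling kappa*mu1*mu2/(n^2 R^3), in cm^-1 (R in nm, mu in D)."""
    if screening_n <= 0:
        raise InvalidParameterError("refractive index must be > 0")
    rvec = d2.origin - d1.origin
    r = float(np.linalg.norm(rvec))
    if r < 1e-9:
        raise SingularGeometryError("coincident dipole origins")
    kappa = orientation_factor(d1.direction, d2.direction, rvec / r)
    return (
        DIPOLE_COUPLING_CM1
        * kappa
        * d1.magnitude
        * d2.magnitude
        / (screening_n**2 * r**3)
    )


@dataclass(eq=False)
class ExcitonHamiltonian:
    """Site-basis Hamiltonian: diagonal site energies, off-diagonal couplings (cm^-1)."""

    basis: List[TransitionDipole]
    matrix: np.ndarray
    screening_n: float
    #: site id of each basis transition (two basis entries share an id on a porphyrin)
    site_ids: np.ndarray = field(default=None)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_hamiltonian(
    geom: AssemblyGeometry, screening_n: float = 1.0, dye_coupling_scale: float = 1.0
) -> ExcitonHamiltonian:
    """Assemble the Frenkel Hamiltonian of all transitions in ``geom``.

    ``dye_coupling_scale`` multiplies every dye-ring off-diagonal element
    (0 decouples the dye exactly, giving the block-diagonal reference model).
    """
    basis = geom.transitions()
    site_ids = geom.transition_site_ids()
    n = len(basis)
    if n < 1:
        raise InvalidParameterError("empty geometry")
    h = np.zeros((n, n))
    dye_idx = geom.dye_transition_index()
    for i in range(n):
        h[i, i] = basis[i].site_energy
        for j in range(i + 1, n):
            if site_ids[i] == site_ids[j]:
                continue  # orthogonal transitions on one porphyrin: no coupling
            v = dipole_coupling(basis[i], basis[j], screening_n)
            if dye_idx is not None and (i == dye_idx or j == dye_idx):
                v *= dye_coupling_scale
            h[i, j] = h[j, i] = v
    return ExcitonHamiltonian(basis=basis, matrix=h, screening_n=screening_n,
                              site_ids=site_ids)


@dataclass(eq=False)
class ExcitonStates:
    """Eigen-decomposition with per-state vector transition dipoles."""

    energies: np.ndarray  # ascending, cm^-1
    coefficients: np.ndarray  # column k = state k in the site basis
    state_dipoles: np.ndarray  # (n_states, 3), Debye
    dipole_strengths: np.ndarray  # |mu_k|^2, Debye^2

    @property
    def n(self) -> int:
        return self.energies.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "energy_cm1": self.energies,
                "wavelength_nm": 1e7 / self.energies,
                "dipole_strength_D2": self.dipole_strengths,
            }
        )


def diagonalize(h: ExcitonHamiltonian) -> ExcitonStates:
    """Eigenstates (ascending energies) and their transition dipoles.

    mu_k = sum_i c_ik mu_i: the vector sum of basis dipoles weighted by the
    eigenvector coefficients.
    """
    asym = np.max(np.abs(h.matrix - h.matrix.T)) if h.n > 1 else 0.0
    if asym > 1e-9:
        raise InvalidParameterError(f"Hamiltonian not symmetric (max asym {asym})")
    energies, coeff = np.linalg.eigh(h.matrix)
    moments = np.array([t.moment for t in h.basis])  # (n, 3)
    state_dipoles = coeff.T @ moments
    strengths = np.einsum("kj,kj->k", state_dipoles, state_dipoles)
    return ExcitonStates(energies, coeff, state_dipoles, strengths)


def ring_subhamiltonian(h: ExcitonHamiltonian, geom: AssemblyGeometry) -> ExcitonHamiltonian:
    """The ring-only block of a full assembly Hamiltonian."""
    dye_idx = geom.dye_transition_index()
    if dye_idx is None:
        return h
    keep = [i for i in range(h.n) if i != dye_idx]
    return ExcitonHamiltonian(
        basis=[h.basis[i] for i in keep],
        matrix=h.matrix[np.ix_(keep, keep)],
        screening_n=h.screening_n,
        site_ids=h.site_ids[keep],
    )


def group_bands(energies: Sequence[float], tol: float = DEFAULT_BAND_TOL) -> List[np.ndarray]:
    """Chain-cluster ascending energies: a gap > ``tol`` cm^-1 starts a new band.

    Returns index arrays into ``energies`` (assumed ascending).
    """
    energies = np.asarray(energies)
    if energies.size == 0:
        return []
    bands = [[0]]
    for i in range(1, energies.size):
        if energies[i] - energies[i - 1] > tol:
            bands.append([i])
        else:
            bands[-1].append(i)
    return [np.array(b) for b in bands]


@dataclass(eq=False)
class CouplingProfile:
    """Per-band dye coupling (and, once filled, golden-rule rate)."""

    band_center_cm1: np.ndarray
    band_center_nm: np.ndarray
    coupling_cm1: np.ndarray
    rate_ps_inv: np.ndarray  # NaN until rates are computed
    n_states: np.ndarray
    band_indices: List[np.ndarray] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band_nm": self.band_center_nm,
                "band_cm1": self.band_center_cm1,
                "V_cm1": self.coupling_cm1,
                "k_ps_inv": self.rate_ps_inv,
                "n_states": self.n_states,
            }
        )

    @property
    def lowest_band_coupling(self) -> float:
        """Coupling to the lowest-energy (longest-wavelength) band, cm^-1."""
        return float(self.coupling_cm1[0])


def dye_band_couplings(
    h: ExcitonHamiltonian,
    ring_states: ExcitonStates,
    geom: AssemblyGeometry,
    band_tol: float = DEFAULT_BAND_TOL,
) -> CouplingProfile:
    """Root-sum-square coupling of the dye to each ring exciton band.

    <dye|H|k> = sum_i c_ik H(dye, i) over ring basis transitions i; bands group
    near-degenerate ring eigenstates (within ``band_tol``); per band
    V_b = sqrt(sum_{k in b} |<dye|H|k>|^2).
    """
    dye_idx = geom.dye_transition_index()
    if dye_idx is None:
        raise MissingDyeError("assembly has no dye site")
    ring_cols = [i for i in range(h.n) if i != dye_idx]
    h_dye = h.matrix[dye_idx, ring_cols]  # couplings to ring basis transitions
    v_states = ring_states.coefficients.T @ h_dye  # <dye|H|k> per ring eigenstate

    bands = group_bands(ring_states.energies, tol=band_tol)
    centers, couplings, nst = [], [], []
    for b in bands:
        w = ring_states.dipole_strengths[b]
        e = ring_states.energies[b]
        center = float(np.average(e, weights=w)) if w.sum() > 1e-12 else float(e.mean())
        centers.append(center)
        couplings.append(float(np.sqrt(np.sum(v_states[b] ** 2))))
        nst.append(len(b))
    centers = np.array(centers)
    order = np.argsort(centers)  # ascending energy = descending wavelength
    return CouplingProfile(
        band_center_cm1=centers[order],
        band_center_nm=np.array([wavelength_nm(c) for c in centers[order]]),
        coupling_cm1=np.array(couplings)[order],
        rate_ps_inv=np.full(len(bands), np.nan),
        n_states=np.array(nst)[order],
        band_indices=[bands[i] for i in order],
    )
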