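# Methods

## The physical model

The assembly is reduced to its optical degrees of freedom: point transition
dipoles at fixed positions. Six ring sites sit at equal angles on a circle
of radius 1.2 nm in the z = 0 plane; each carries two orthogonal Q-band
transitions, one tangent to the circle (the strong component, along the
conjugation path of a butadiyne-linked porphyrin ring) and one parallel to
the ring axis (the weak out-of-ring-plane component). The dye contributes a
single transition on the z axis pointing along +z. Conformer A places the
dye centre in the ring plane; conformer B shifts it 0.4 nm along the axis
toward one rim. Both conformers are populated, with two-state Boltzmann
weights for an energy gap of 0.7 kJ mol⁻¹ at 298 K (≈ 57:43 A:B).

Couplings are point-dipole with 1/n² solvent screening (n = 1.424,
dichloromethane). The two orthogonal transitions sharing one porphyrin are
set uncoupled: the point-dipole kernel is singular at zero separation and
symmetry makes the interaction vanish. A useful exact consequence of the
geometry: the orientation factor between the axial dye dipole and every
tangential ring dipole is zero for *both* conformers (the tangent is
perpendicular to both the radial separation and the axis), so the dye
communicates exclusively with the axial exciton manifold. The lowest ring
band therefore must carry axial character for any dye–ring coupling to
exist, and the coupling profile across bands consists of one coupled band
plus symmetry-zero entries.

## Calibration

Neither the individual site energies nor the dipole magnitudes of the real
assembly are observable directly; they are fixed by calibration against the
measured band structure. Bounded least squares (from the config start
point, hence deterministic) adjusts

- the axial site energy, so the bright axial exciton band sits at 810 nm
  (the observed lowest Q-band peak of the nanoring),
- the tangential site energy, so the bright tangential band sits at 765 nm
  (a representative second Q-band position; configurable),
- the axial dipole magnitude, so the root-sum-square coupling between the
  dye and the lowest band equals the 25 cm⁻¹ reported for this assembly.

The dye dipole (11 D, typical of a heptamethine cyanine) and the tangential
magnitude (5 D) stay fixed; only the product μ_dye·μ_axial is constrained
by the coupling target, so one factor must be chosen. Targets are matched
to the nearest *bright* band (dipole-strength fraction > 10⁻⁶), and band
centres are intensity-weighted stick positions, which coincide with the
broadened local maxima for bands separated by more than the linewidth.

The dye site energy defaults to 10⁷/725 cm⁻¹ (the excitation wavelength of
the quenching experiment) and its Stokes shift to 10⁷/725 − 10⁷/798 cm⁻¹,
so the donor *emission* used in the transfer overlap sits exactly at the
observed 798 nm emission maximum. Only the emission position enters the
rates; the absorption position only places the dye stick in the spectra.

## Lineshapes and rates

Broadened spectra weight each stick by E·|μ|² and convolve with a unit-area
lineshape on the energy axis — Gaussian by default, FWHM 350 cm⁻¹ per band
(typical room-temperature porphyrin Q-band width; per-config override,
Lorentzian available). The overlap integral of two lines is evaluated as a
Voigt profile at the centre separation, which covers Gaussian, Lorentzian
and mixed pairs in one closed form.

The golden-rule rate in this unit system is k = 4π²·c·V²·J with c in
cm ps⁻¹, V in cm⁻¹ and J in (cm⁻¹)⁻¹. The prefactor follows from
(2π/ħ)|V|²ρ after substituting V → hcṼ and ρ → J̃/(hc), and is verified in
the test suite against exact unitary dynamics of a donor level coupled to a
dense discretized continuum (Weisskopf–Wigner construction): the fitted
survival-decay rate agrees with the closed form to well within 5 %.

Per-realization rates are computed state-by-state (coupling ⟨dye|H|k⟩ of
the dye to each ring eigenstate, overlap at that state's energy) and then
aggregated into bands, so band rates sum exactly to the total. Transfer
time is the inverse total rate; an uncoupled dye yields zero rate and an
infinite, flagged transfer time.

## The disorder ensemble (what the generator emulates)

Static disorder adds independent Gaussian shifts (σ = 250 cm⁻¹, a typical
inhomogeneous width for room-temperature porphyrin assemblies) to every
transition energy — ring and dye alike — per realization; conformers are
drawn by Boltzmann weight; all sampling derives from one seed and is
bitwise reproducible. Only the Hamiltonian diagonal changes between
realizations, so the sampler precomputes the coupling blocks and
re-diagonalizes the 12×12 ring block per draw (5000 realizations in well
under a second).

What the generator does *not* emulate: geometric/orientational disorder
(positions and dipole directions are rigid), correlated energy shifts,
exchange/charge-transfer contributions, vibronic structure, dynamic bath
effects beyond the fixed homogeneous linewidth, and ring→dye back-transfer.
Passing tests therefore validate the exciton/golden-rule machinery under
idealized site-energy disorder, not the full conformational photophysics of
the real assembly.

A consequence worth stating plainly: with Gaussian lineshapes, realizations
whose disordered dye energy detunes the donor emission by ≳ 700 cm⁻¹ from
the axial band transfer more slowly than 50 ps. At the default σ this
affects about 2 % of draws, so the computed sub-50-ps fraction is ≈ 0.98
rather than ≈ 0.99; heavier-tailed (Lorentzian) lineshapes remove this
slow tail entirely but slow the near-resonant ensemble mean. The Gaussian
default was kept because it reproduces the deterministic and mean ensemble
observables most faithfully; the shape is a single config switch.

## Numerical choices

- Eigen-decomposition: `numpy.linalg.eigh` (symmetric); eigenvalues
  ascending; state dipoles are coefficient-weighted basis-dipole sums, so
  total dipole strength is conserved to rounding (sum rule, tested at 1e-6
  relative).
- Band grouping: chain clustering with a 50 cm⁻¹ gap threshold — far below
  the ~600 cm⁻¹ spacing of the Q-band features, far above numerical
  splitting of degenerate pairs.
- Dark states are kept in stick lists with zero weight (strength < 1e-12).
- Calibration optimizer: `scipy.optimize.least_squares`, bounds (0, ∞),
  tolerances 1e-12; re-running on its own output moves parameters by
  < 1e-6 relative.
- Degenerate inputs: coincident dipole origins raise a singular-geometry
  error; r = 0 or 1 in the brightness inversion raises a boundary error;
  zero disorder reproduces the input geometry exactly.
- Ensemble statistics use 2000 realizations per single-conformer ensemble
  and 5000 for the combined ensemble — enough that medians and means move
  by ≲ 2 % between seeds — with seeded bootstrap (500 resamples) for 95 %
  confidence intervals.

## Known limitations

- Point dipoles at 1.2 nm separation overestimate/underestimate couplings
  relative to extended-dipole or transition-charge treatments; the kernel
  is isolated in one function and swappable.
- The axial-band brightness implied by the 25 cm⁻¹ coupling calibration is
  small (μ_axial ≈ 0.65 D), so the simulated 810 nm ring feature is much
  weaker than the real nanoring's; relative Q-band intensities are not a
  calibration target.
- Only two bright ring bands exist in this dipole model; the third observed
  Q-band feature (vibronic in origin) is outside scope, and an
  overdetermined three-band calibration distributes the residual over the
  tangential targets while pinning the 810 nm band.
- The kinetic inversion attributes the entire donor-channel brightness loss
  to energy transfer, ignoring spectral contamination of the 798 nm channel
  by ring emission (which peaks near 910 nm) — quantum yields are carried
  as metadata only.
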