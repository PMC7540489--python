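# ringdye

Frenkel-exciton modelling of a biomimetic light-harvesting assembly: a
near-infrared cyanine dye (Cy7, held in a cyclodextrin rotaxane) threaded
along the axis of a six-porphyrin zinc nanoring. The architecture mimics the
bacterial LH1/reaction-center arrangement — a ring of antenna chromophores
around a central energy trap — and the package answers the photophysical
questions such a system poses: how strongly does the central dye couple to
the ring's exciton bands, why does the absorption spectrum of the complex
look like the sum of its parts, and how fast is dye-to-ring energy transfer?

It is written for molecular photophysicists and supramolecular chemists who
want a transparent, configurable point-dipole exciton model rather than a
quantum-chemistry pipeline.

## Model

Each of the six porphyrins carries two orthogonal Q-band transition dipoles
(one tangent to the ring circle, one along the ring axis); the dye carries a
single transition along the axis. Two conformers are modelled: **A** with
the dye centred in the plane of the zinc centres and **B** with the dye
shifted 0.4 nm toward one rim, Boltzmann-weighted (ΔE = 0.7 kJ mol⁻¹,
298 K). The site basis spans a Frenkel Hamiltonian

    H_ii = E_i ,   H_ij = κ_ij μ_i μ_j / (n² R_ij³) ,
    κ_ij = μ̂_i·μ̂_j − 3 (μ̂_i·R̂_ij)(μ̂_j·R̂_ij)

with energies in cm⁻¹, dipoles in Debye, distances in nm and solvent
screening 1/n² (CH₂Cl₂, n = 1.424). Diagonalization gives exciton states,
stick spectra (weight E·|μ|²) and Gaussian-broadened absorption. Dye→ring
transfer is second-order in the dye–ring coupling (Fermi's golden rule):

    k_b = 4π² c V_b² J_b ,

where V_b is the root-sum-square coupling of the dye to ring band *b* and
J_b the overlap of the donor emission lineshape with the band lineshape.
Ensembles over conformers and Gaussian static site-energy disorder
(σ = 250 cm⁻¹) yield transfer-time distributions; a rate-competition
formula, r = (1/τ_fl)/(1/τ_fl + k_ET), links transfer rates to the measured
fluorescence-quenching observables.

Calibration (`LightHarvestingModel.fit()`) adjusts the ring site energies
and the axial dipole magnitude so the lowest (axial) exciton band sits at
810 nm, the bright tangential band at 765 nm, and the dye–lowest-band
coupling equals 25 cm⁻¹.

## Worked example

```python
from ringdye import LightHarvestingModel

results = LightHarvestingModel().fit()   # calibrate the default conditions
print(results.summary())

dist = results.transfer_distribution("AB", n_realizations=5000, seed=1)
print(dist.summary())
```

The summary table prints the calibrated parameters and headline observables:

```
Conformer A (undisordered):
  lowest band                        810.00 nm
  dye coupling to lowest band         25.00 cm^-1
  golden-rule transfer time           1.052 ps
Quenching inversion (measured r, tau_fl):
  k_ET                               0.2011 ps^-1
  tau_ET                              4.972 ps
  quenching efficiency               0.9949
```

i.e. the calibrated model couples the dye to the 810 nm ring band with
25 cm⁻¹, transfers energy in about a picosecond in the symmetric conformer,
and the measured brightness ratio (0.0051) with the 0.97 ns donor lifetime
inverts to a ~5 ps transfer time — >99 % of the dye emission is quenched by
the ring. The ensemble distribution (`dist.summary()`) adds the
disorder-averaged statistics: a median transfer time of ~1.5 ps, a
conformer-B inverse mean rate near 4.3 ps, and the fraction of realizations
transferring within 50 ps (~0.98), each with bootstrap confidence
intervals.

The same computations are available from the shell:

```bash
ringdye all --out results_dir          # spectrum, couplings, transfer, quenching
ringdye quenching --print-summary      # just the kinetic inversion
```

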