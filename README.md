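# vibexciton

Vibrational exciton modelling and spectral analysis for surfactant
films at aqueous interfaces.

## The problem

One-dimensional surface-sensitive IR spectroscopies (IRRAS, VSFG)
routinely use alkyl/fluoroalkyl band intensities as proxies for how much
surfactant sits at the air/water interface. That reading assumes
Beer–Lambert behavior: band area proportional to surface concentration.
But quasi-degenerate local vibrations on neighboring molecules couple
through their transition dipoles, forming delocalized vibrational
excitons. Coupling redistributes oscillator strength into many weakly
allowed states and shifts it across the spectrum — total intensity is
conserved, but what lands inside the experimental window at detectable
levels is not. Packing density (and hence subphase ionic composition,
which modulates intermolecular spacing) therefore changes apparent band
intensity even at constant coverage.

`vibexciton` is for spectroscopists and modelers who want to quantify
that effect: it builds transition-dipole-coupling exciton Hamiltonians
over synthetic monolayer/cluster geometries, compares coupled against
uncoupled (thermally broadened only) spectra, measures exciton
splittings and delocalization lengths as a function of intermolecular
spacing, and fits surface tensiometry to adsorption isotherms so
spectral areas can be confronted with independent coverage estimates.

## Model

Each of N molecules carries M local modes with frequencies ω₀ (cm⁻¹)
and transition dipoles **μ** (debye). The Frenkel-type exciton
Hamiltonian in the local-mode basis (D = N·M) has the local frequencies
(plus diagonal disorder) on the diagonal, and vacuum point-dipole
couplings off it:

    J_ij = K κ_ij |μ_i||μ_j| / R_ij³ ,
    κ_ij = μ̂_i·μ̂_j − 3 (μ̂_i·r̂_ij)(μ̂_j·r̂_ij) ,

with K = 5034.12 cm⁻¹·Å³·D⁻² derived from CODATA constants at import
time. Diagonalization gives eigenfrequencies and state dipoles
d_k = Σᵢ c_ik μ_i; intensities |d_k|² obey the oscillator-strength sum
rule Σ_k |d_k|² = Σᵢ |μᵢ|².

Supporting analyses:

- Gaussian ensemble broadening of stick spectra (band σ = 2× the
  across-snapshot standard deviation of the band frequency), difference
  spectra ΔI = I − I₀, endpoint-anchored linear-baseline peak areas,
  band centers, 2D energy–intensity histograms, weak-mode fractions,
  and RA = −log₁₀(R_m/R₀).
- Exciton (tunneling) splittings Δω = ω₊ − ω₋ along a uniform
  compression coordinate, (bi-)exponential fits
  A·e^(−αr) + B·e^(−βr), and the containment length
  L = −ln(1−f)/(2β) inside which a fraction f of the squared
  long-range amplitude lives.
- Szyszkowski isotherm γ = γ₀ − a·ln(1 + C/b) and the
  Langmuir–Szyszkowski surface concentration Γ = a/(RT)·C/(b+C).
- Finite-cluster radial distribution functions and nearest-neighbor
  distances from the coordination integral.

## Worked example

A 10×10 arachidic-acid-like sheet (single C–H mode at 2918 cm⁻¹,
0.25 D, random azimuthal orientations) at 25 Å²/molecule:

```python
import numpy as np
import vibexciton as vx

sheet = vx.make_2d_sheet(10, 10, 25.0, vx.aa_ch_mode(),
                         orientation_policy="random", seed=0)
scan = vx.splitting_scan(sheet, np.linspace(1.0, 4.0, 16), "CH2-as")
fit = vx.fit_splitting_decay(scan, model="single")

ens = vx.jitter_ensemble(sheet, pos_sigma=0.3, rot_sigma=0.1,
                         freq_sigma=5.0, n_snapshots=10, seed=1)
sticks_c = [vx.stick_spectrum(vx.diagonalize(vx.build_hamiltonian(s), s))
            for s in ens]
sticks_u = [vx.stick_spectrum(vx.uncoupled_states(s)) for s in ens]
I = vx.broaden_ensemble(sticks_c, (2800.0, 3050.0, 0.5))
I0 = vx.broaden_ensemble(sticks_u, (2800.0, 3050.0, 0.5))
dI = vx.difference_spectrum(I, I0, window=(2900.0, 2936.0))
```

prints (via the obvious f-strings):

```
splitting at 5.0 A spacing: 20.72 cm^-1
exponential decay: A = 188.6 cm^-1, alpha = 0.448 1/A
peak intensity coupled / uncoupled: 0.4437 / 0.4873
weak-mode fraction (10x below brightest): 0.49
Delta-I integral, 2900-2936 cm^-1 window: -0.026
```

Read: at condensed-phase packing the exciton band spans ~21 cm⁻¹ and
decays roughly exponentially with spacing (α ≈ 0.45 Å⁻¹ for this
single-dipole surrogate). Coupling lowers the peak intensity by ~9%
relative to the thermally broadened uncoupled model, about half of all
exciton states end up an order of magnitude weaker than the brightest
one, and the difference spectrum integrates negative over a finite
window — apparent signal loss at constant coverage.

Tensiometry side:

```python
C = np.geomspace(1e-6, 1e-3, 12)
data = vx.synth_tensiometry(72.57, 14.0, 2e-4, C, noise_sd=0.2, seed=5)
f = vx.fit_szyszkowski(data)
```

```
Szyszkowski fit: a = 14.63 mN/m, b = 2.17e-04 mol/L, adj R^2 = 0.9995
surface concentration at 2 mM: 5.397e-06 mol/m^2 (saturation 5.981e-06)
```

## Command line

Config-file driven subcommands (`vibexciton simulate|scan|adsorb|generate|rdf`),
e.g.:

```yaml
# sheet.yaml
seed: 7
output_dir: out
generator: {kind: sheet_2d, nx: 10, ny: 10, area_per_molecule: 25.0,
            orientation_policy: random}
mode_set: {builtin: aa_ch}
ensemble: {n_snapshots: 10, pos_sigma: 0.3, rot_sigma: 0.1, freq_sigma: 5.0}
spectra: {grid: [2800, 3050, 0.5], window: [2800, 3000]}
```

`vibexciton simulate sheet.yaml` writes coupled/uncoupled spectra, ΔI,
an energy–intensity histogram, band centers + weak-mode fraction, and a
manifest with all seeds and the derived coupling constant. Reruns are
byte-identical.

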