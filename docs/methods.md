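# Methods

## Exciton model

The vibrational Hamiltonian is the standard Frenkel-type exciton model
in a local-mode basis. Each molecule contributes its monomer normal
modes (frequency in cm⁻¹, transition dipole vector in debye, dipole
origin in the molecule frame); monomer modes are assumed pre-diagonalized,
so intra-molecular off-diagonal couplings are zero by default
(`build_hamiltonian(..., include_intramolecular=True)` switches them on
for non-normal-mode inputs). Inter-molecular couplings use the vacuum
point-dipole interaction

    J = K [μ̂ᵢ·μ̂ⱼ − 3(μ̂ᵢ·r̂)(μ̂ⱼ·r̂)] |μᵢ||μⱼ| / R³

with R the distance between the (rotated, origin-shifted) dipole
positions in Å. The prefactor K is derived from CODATA constants at
import time (`vibexciton.constants`), K = 5034.1166 cm⁻¹·Å³·D⁻², and is
logged when Hamiltonians are assembled. No dielectric screening is
applied: monomer parameters are gas-phase-like and the relative
permittivity is 1. No periodic boundary conditions: all systems are
finite clusters.

Assumptions and scope: point dipoles only (no transition charges or
higher multipoles), one-exciton space only (no anharmonicity, Fermi
resonances, or two-exciton states), no solvent coupling. Dense
symmetric eigensolver (`numpy.linalg.eigh`); intended basis sizes are
D ≲ 5000. Degenerate eigenvalues are ordered by frequency with ties
broken by descending intensity.

State dipoles are coherent sums d_k = Σᵢ c_ik μᵢ and intensities
|d_k|²; orthogonality of the eigenvectors enforces the
oscillator-strength sum rule, which the test suite checks to 1e-10
relative on random configurations.

## Monomer surrogates

Built-in single-dipole surrogates stand in for ab initio monomer
parameterizations:

- `aa_ch_mode` / `octanoic_ch_mode`: one C–H stretch at 2918 cm⁻¹,
  0.25 D, polarized in the monolayer plane.
- `pfoa_single_mode`: one C–F stretch at 1213 cm⁻¹, 0.5 D, in-plane.
- `pfoa_cf_band_modes`: a synthetic three-band C–F set (1254, 1214,
  1153 cm⁻¹) with mixed in-plane polarizations, for multi-band
  spectral exercises.

These carry `scale_factor = 1.0` because their frequencies are supplied
as effective values; `MonomerModeSet.from_harmonic` applies the usual
harmonic scale factor (default 0.9805) to raw harmonic frequencies.
Quantities that depend on the full monomer normal-mode structure
(absolute splitting amplitudes, multi-exponential decay constants,
absolute delocalization lengths) are parameterization-dependent and are
not claimed to match any particular ab initio data set; the single-dipole
surrogates reproduce orderings and scalings (e.g. the 0.5 D species
splits more than the 0.25 D species at equal spacing, J ∝ R⁻³).

## Synthetic configurations

`make_2d_sheet` places nx·ny molecules on a square lattice in the z = 0
plane with spacing √(area per molecule); the square lattice makes the
area↔spacing identity exact (36 Å² ↔ 6 Å). Orientation policy is
`identical` (all-parallel dipoles) or `random` (independent uniform
rotations about the surface normal — a liquid-expanded-like disordered
monolayer). `make_3d_cell` builds a cubic lattice with orientations
uniform over SO(3), sampled by the normalized-quaternion method.

`jitter_ensemble` emulates MD thermal disorder: isotropic Gaussian
center displacements (default σ 0.3 Å), composition with small random
rotations (uniform axis, Gaussian angle, default σ 0.1 rad), and i.i.d.
per-molecule diagonal frequency offsets (default σ 5 cm⁻¹), over a
default of 25 snapshots. Defaults are condensed-monolayer-scale thermal
fluctuations: sub-ångström positional jitter small against the ~5–6 Å
nearest-neighbor spacing, and site-frequency disorder of a few cm⁻¹,
comparable to inhomogeneous C–H/C–F linewidths. What the generator does
*not* emulate: correlated motions, anisotropic disorder, exchange with
the subphase, conformational (gauche) defects, or any coupling between
positional and frequency disorder. Tests passing on these ensembles
therefore validate the pipeline's mathematics and qualitative coupling
physics, not force-field-level realism.

Seeds are explicit everywhere; the CLI derives child seeds from the
config root seed by fixed increments (generator +0, ensemble +1,
synthesis +2). Identical seeds give bit-identical artifacts.

## Spectral synthesis and analysis

Stick spectra from an ensemble are grouped into bands and broadened
with Gaussians on a uniform grid (default step 0.5 cm⁻¹, the instrument
sampling; default windows 1100–1280 cm⁻¹ for C–F, 2800–3000 cm⁻¹ for
C–H). Band grouping policies:

- `state_index` (default): the k-th line in ascending frequency of each
  snapshot is one band. This preserves exciton band structure in the
  broadened spectrum and is the only policy that keeps a single-mode
  coupled spectrum distinguishable from its uncoupled reference.
- `mode_label`: lines pooled by dominant local-mode character (argmax
  of summed squared eigenvector components per monomer mode label);
  per snapshot the band frequency is the intensity-weighted mean and
  the intensity the pooled sum. Appropriate for multi-mode monomers
  where one Gaussian per monomer mode is wanted.

Width convention: the Gaussian σ-parameter is `width_scale` (default 2)
times the across-snapshot **population** standard deviation (ddof = 0)
of the band frequency, floored at `width_floor` (default 1 cm⁻¹) so
single-snapshot input stays finite. The alternative FWHM reading of a
"2σ width" is available by setting `width_scale = 2/2.355`. Band area
is the ensemble-mean band intensity, so the integral of the broadened
spectrum equals the mean total stick intensity (checked to 1e-4 with
grids extending well past every band).

ΔI = I − I₀ is a pointwise difference on a shared grid, restricted to
an observation window. Because coupled and uncoupled ensembles share
total intensity (sum rule), ΔI integrates to ~0 over an unbounded
window; negative integrals over finite windows quantify apparent signal
loss. Peak areas use trapezoidal integration after subtracting the
straight line through the spectrum values at the window endpoints.
Band centers come from `scipy.signal.find_peaks` prominences. The 2D
energy–intensity histogram counts states per (frequency, intensity)
cell averaged over snapshots, with an optional intensity-weighted
variant and a paired variant that bins I − I₀ matching coupled states
to their dominant basis state.

A caution on lineshape comparisons: with diagonal frequency disorder
and weak coupling, exciton delocalization averages over site disorder
(exchange narrowing) and the coupled lineshape can be slightly
*narrower* than the uncoupled one. "Coupling broadens the spectrum"
holds robustly for positional/orientational disorder and in the
strong-coupling (condensed) regime; the test suite asserts the variance
inequality only there.

## Splittings and delocalization

`splitting_scan` scales a configuration uniformly about its centroid,
builds the single-mode Hamiltonian at each scale, and records
Δω = ω_max − ω_min against the nearest-neighbor center distance. For
N > 2 the band-edge (max − min) definition is used; for a dimer it
reduces to 2|J| exactly. Splittings are invariant under rigid
isometries of the whole configuration (tested to 1e-9 cm⁻¹).

`fit_splitting_decay` fits A·e^(−αr) (single) or
A·e^(−αr) + B·e^(−βr) (double) by bounded trust-region least squares
(`scipy.optimize.least_squares`, tolerances 1e-14), seeded by
log-linear fits on the short- and long-range halves of the grid, with
parameters reported under the convention α ≥ β. `weighting="relative"`
divides residuals by the data — the right loss when the noise is
multiplicative, and it calibrates the reported covariance for that
noise model. Note an identifiability caveat: if the scan range never
reaches spacings where the short-range branch dominates, α carries
little information and tight recovery cannot be expected at realistic
noise levels.

`containment_length(β, f)` returns L = −ln(1−f)/(2β), the distance
containing fraction f of ∫e^(−2βr). The squared-amplitude convention
is deliberate: the fitted exponential describes the wavefunction
amplitude, so containment is measured on its square (the
amplitude-only reading would double the length).

## Adsorption

Szyszkowski: γ(C) = γ₀ − a·ln(1 + C/b), with γ₀ fixed at the measured
subphase tension (default 72.57 mN/m, water near 21 °C) and (a, b)
fitted by bounded least squares; adjusted R² uses p = 2. Surface
concentration: Γ(C) = a/(R_gas T)·C/(b + C) with a converted to J/m²,
T defaulting to 294.25 K; this is exactly the Gibbs adsorption
derivative of the Szyszkowski curve (tested to 1e-6 in the C ≫ b
limit). Units: γ in mN/m externally, C in mol/L, Γ in mol/m²,
R_gas = 8.314 J/(mol·K). `cross_section_fit` regresses band area on Γ;
under Beer–Lambert behavior the slope is an effective cross section and
systematically negative residuals at high Γ flag coupling-induced
depletion. No ionic-activity corrections, counterion binding, or
dynamic surface tension.

## Structure statistics

Finite-cluster RDFs without periodic images: per frame, the unordered
pair-distance histogram divided by the ideal-gas expectation
N(N−1)/2 · shell/domain, with the shell 2πr·dr (2D, lateral
coordinates) or 4πr²·dr (3D) and the domain area/volume taken from the
generator metadata (or passed explicitly). Default r_max is half the
domain extent, which keeps boundary-induced undercounting small; at
larger r the estimator is biased low because no boundary correction is
applied. Features are read from a 5-bin moving average of g (first
interior maximum, first minimum after it), and the nearest-neighbor
distance is where the running coordination integral ρ∫g·shell dr
crosses 1, linearly interpolated inside the crossing bin. Both 2D and
3D normalizations are provided; neither is asserted as the "correct"
reading for interfacial systems.

## Problem sizes and defaults used in the shipped analyses

The shipped tests and example workflows use desk-scale systems chosen
to exercise every code path with comfortable margins: sheets of
24–100 molecules, 3D cells up to 5×5×5, ensembles of 3–25 snapshots,
single- to three-mode monomers (basis dimensions ≤ 500), splitting
scans of 12–16 points, and tensiometry sets of 12 concentrations over
three decades with 0.2 mN/m noise. All randomized checks are seeded.

## Known limitations

- Point-dipole couplings overestimate interactions at sub-van-der-Waals
  spacings where transition-charge or multipole corrections matter.
- Single-dipole monomer surrogates cannot reproduce multi-mode
  interference (intermodal dipole cancellation), so absolute splitting
  amplitudes and decay constants are parameterization-specific.
- The uncoupled reference I₀ shares the coupled model's geometry and
  diagonal disorder but not any coupling-induced frequency shifts; it
  is a baseline, not an observable spectrum.
- RDFs carry finite-size bias near the domain boundary (no edge
  correction); use r well below the half-extent for quantitative work.
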