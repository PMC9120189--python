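# Methods

This note documents the models implemented in `menpsim`, the defaults they
ship with, the design choices made where the design was genuinely open, and
what the synthetic benchmarks do and do not establish about real data.

## Lumped magnetoelectric particle model

The particle is a sphere of radius `r_total` (default 15 nm) with a
magnetostrictive CFO core of radius `r_core` and a piezoelectric BTO shell.
Instead of resolving fields inside the particle, one representative state
(M, S, E, H) is evolved to self-consistency:

1. **Piezoelectric stress.** S_piezo = S₀ − E·e, evaluated at clamped
   strain with the BTO stress-coupling matrix e (C/m²); the Voigt
   convention is 11, 22, 33, 23, 13, 12 with engineering shears. A
   stress-transfer factor κ ∈ [0, 1] (default 1) scales how much of the
   shell stress reaches the core.
2. **Magnetostriction.** ε_me = (3/2)(λ_s/Ms²)·dev(M⊗M), traceless and
   quadratic in M. A `clamp` factor ∈ [0, 1] sets how much elastic
   back-stress (−clamp·c:ε_me, isotropic closure from the core's Young's
   modulus and Poisson ratio) this eigenstrain generates. The default is
   `clamp = 0`: a free nanoparticle deforms with its magnetostrictive
   eigenstrain, which is then stress-free; `clamp = 1` models a rigidly
   constrained core. At these material constants the fully clamped loop has
   a feedback gain of about −4, so the solver halves its damping whenever
   the residual grows; with the default damping 0.5, tolerance 1e−10
   (relative |ΔM|/Ms) and 500 iterations both regimes converge, the free
   regime in a few dozen iterations.
3. **Effective field and magnetization.** H_eff = H + (3λ_s/(μ₀Ms²))·dev(S)·M,
   then M = Ms·L(β|H_eff|)·Ĥ_eff with the thermal Langevin argument
   β = μ₀·Ms·V_core/(k_B·T). Temperature defaults to 300 K. The Langevin
   function uses a Maclaurin branch below |x| < 1e−4 (truncation error
   < 1e−21), keeping it smooth through zero.

Two parameterizations of the low-field slope coexist in the literature
values shipped here: the tabulated CFO initial susceptibility (χ₀ = 70) and
the thermal-Langevin initial slope Ms·β/3. They are not equal and the
package does not force them to be; the thermal parameterization is the
default because it follows from the stated Langevin model, and β can be
overridden to trace an empirical M–H curve.

The composite (particle-average) magnetization is f_core·M_core with
f_core = (r_core/r_total)³; the BTO shell is taken as magnetically inert.
The MENP preset sets f_core so the composite saturation equals the reported
±89.9 kA/m, because the modeled core radius itself was not reported.

Spatially resolved fields are out of scope; `sphere_dipole_field` provides
the analytic uniformly-magnetized-sphere solution (uniform (2/3)μ₀M inside,
point dipole outside) as a surrogate for field maps.

## Harmonic spectroscopy

The drive is H(t) = bias + A·sin(2πft), default 80 kA/m at 25.25 kHz,
sampled at 1 µs over 0–80 µs. That window spans 2.02 drive periods, so raw
FFT bins would leak; the spectrum is instead obtained by trimming to the
largest whole number of periods and solving one joint least-squares fit of
a constant plus sine/cosine pairs at k·f (default K = 9). Amplitudes are
√(a² + b²), normalized to the fundamental. The magnetization response is
memoryless (no hysteresis, no Néel/Brownian relaxation) — appropriate for
superparamagnetic tracers at neuronal time scales.

## Linear magnetoelectric mapping

For physiological fields (tens of V/m) the particle response is linear, so
the forward models use a calibrated slope per core radius:
0.4 mA/V at 12 nm (the calibration constant 0.02 A/m per 50 mV/mm) and
0.497 mA/V at 14 nm (the reported sensitivity-trend endpoint). Intermediate
radii (5–14 nm) follow a monotone power-law interpolation between those two
anchors; these intermediate values are configuration, not calibration, and
can be replaced by a user table.

The angular dependence on the angle θ between E and the bias H-field is
g(θ) = f_min + (1 − f_min)|cos θ| — periodic over 180°, mirror-symmetric
about 90°, with floors from the reported extremes (35.62/539.82 for the
E-field observable, 0.13/10.14 for flux density). Two per-site conventions
are implemented because the source description does not fix a formula:

- `signed_projection` (default): ΔM = slope·(E·ĥ). Bipolar maps whose sign
  tracks the field component along the bias axis.
- `magnitude_floor`: ΔM = slope·|E|·g(θ)·sign(E·ĥ), reproducing the angular
  sweep profile including its orthogonal floor.

The choice is a config field recorded in run outputs.

**Concentration bookkeeping.** Conversions use first-principles arithmetic:
per-particle mass from core/shell volumes and densities (8.3×10⁻¹⁷ g for a
30 nm particle with a 12 nm core), number density = mass concentration /
per-particle mass, particle molarity = number density / N_A. Under this
arithmetic 27.495 µg/mL corresponds to ≈ 0.33 particles/µm³. The published
triple (117.5 µM, 27.495 µg/mL, 1415 particles/µm³) is mutually
inconsistent with any per-particle mass; it is preserved verbatim as the
labeled preset `paper_fig4` with an `inconsistent` flag rather than being
silently recomputed.

## Neuronal forward model

Units: µm, nA, ms, S/m, mV, V/m. With these, the point-source kernel is
φ[mV] = I[nA]/(4πσr[µm]) and the mV/µm → V/m gradient conversion is a
single factor of 1000 applied in one place.

- **Morphologies** are SWC node trees (hand-validated reader/writer: single
  root, existing parents, no cycles, positive radii; errors carry line
  numbers). Synthetic templates: `ball_and_stick` and `branched` (full
  binary dendritic tree of configurable depth with seeded angular jitter),
  both carrying soma/axon/dendrite type codes.
- **Currents.** Membrane biophysics is deliberately not simulated. Each
  non-root compartment carries a charge-balanced biphasic template
  (derivative-of-Gaussian, σ = 0.25 ms) delayed by path-distance over a
  conduction speed (default 300 µm/ms) and attenuated with length constant
  200 µm; its exact negative flows through the parent compartment, so net
  transmembrane current is zero at every instant by telescoping and tip
  compartments carry pure delayed copies (propagation timing is exact).
- **Potential.** Line-source kernel for neurite cylinders, point source for
  the soma sphere; sites inside a compartment are clamped to its surface
  distance. Extracellular conductivity defaults to 0.3 S/m (typical
  cortical value; the source does not state one) and is configurable.
- **E-field.** Central differences on the lattice (one-sided at
  boundaries): exact for affine potentials, second-order otherwise.
- **Zone quantification.** Sites are labeled somatic/axonal/dendritic by
  the nearest compartment type within a 20 µm inclusion zone (ties resolve
  soma > axon > dendrite), and |ΔM| is summarized per zone at the single
  time of maximal spatially integrated |ΔM| within the first 20 ms (mean,
  quartiles, Tukey fences).

## Network voxel

Geometry and connectivity follow the stated architecture exactly: a
200×200 µm column, layers II/III/IV of 150/350/200 µm with E:I counts
895:95, 988:188, 970:170; E→(E,I) connections with p = 0.1 and weight
25·y_norm (y_norm = presynaptic depth / 700 µm, origin at the top of layer
II); I→E connections with p = 0.4·e^(−d/150 µm) and weight 5; no I→I
connections, no autapses. Synaptic kinetics are the stated bi-exponentials
(rise/decay 0.8/5.3 s excitatory at 0 mV reversal, 0.6/8.5 s inhibitory at
−75 mV); the values are used as printed, in seconds — a `tau_units` flag
reinterprets them as milliseconds if the user prefers reading them as a
typo.

Membrane dynamics are a conductance-based leaky integrate-and-fire
surrogate (τ_m = 20 ms, rest/reset −65 mV, threshold −50 mV, refractory
3 ms, dt = 0.1 ms over 140 ms), with synaptic weights entering as
g_scale·weight relative to the leak (g_scale default 1e−4; the printed
weights summed over ~290 inputs per cell would otherwise saturate any
stable regime). Second-scale synaptic kinetics cannot generate fast
population bursts within a 140 ms window, so the default external drive
supplies the burst timing that conductance-based biophysics produced in the
original system: a shared rectified slow oscillation (35 mV at a 35 ms
period, random phase per run — a stand-in for common afferent up-state
volleys), a shared Ornstein–Uhlenbeck modulation (2 mV, τ = 6 ms),
independent Gaussian membrane noise (1 mV·ms^−1/2), and spike-frequency
adaptation (10 mV per spike, τ = 15 ms, initialized at a randomized
partially recovered level) that terminates each burst. These amplitudes
were chosen once so the default configuration fires at roughly 5–20 Hz with
two to three distinct burst epochs per window, and were not revisited.
Consequently the surrogate's burst *timing* is driven, not emergent, and
the published absolute network magnetization amplitudes are explicitly not
reproduced — the voxel pipeline tracks orders of magnitude and linearity,
not those values.

Burst detection smooths the 1 ms-binned population rate (Gaussian σ = 2 ms)
and takes peaks at least 10 ms apart that exceed both mean + 2·SD of the
smoothed trace and twice its mean; the multiplicative floor expresses that
a burst is a multiplicative elevation of population activity and keeps
featureless (Poisson-like) rasters from producing false peaks.

For the field solver each point neuron becomes a two-pole current source:
the biphasic spike template at the soma position and its exact negative
100 µm deeper along the depth axis (a cortical dipole), so every cell is
charge-balanced at every instant. The voxel signal is the per-time mean and
SD of ΔM over lattice sites (µA/m), with a 2-D histogram at 1 ms × 5 µA/m
bins over ±1 mA/m.

## Monte Carlo perfusion

Particles enter at the top face (y = 0), normally distributed in x–z
(SD 50 µm — a quarter of the column width; the source states only "normally
distributed" — truncated to the plane), and step by Δr = v·dt·ŷ +
N(0, √(2·D·dt)) per axis with D = 15 µm²/s, v = 650 µm/ms, dt = 10 µs. At
that step the advection displacement is 6.5 µm (resolved by trilinear
interpolation on the 5 µm lattice) and the diffusion step is ≈ 0.017 µm —
negligible against advection, as the physics implies. A particle crosses
the 700 µm depth in 700/650 ≈ 1.077 ms, which motivates the default 1.0 ms
sampling windows centered on burst peaks. Particles that leave the voxel
contribute zero and drop out of the contributing count (washout); a
`reflect` boundary mode is provided as an alternative. The field frame is
the nearest 1 ms record by default (matching the recording resolution),
with linear-in-time interpolation optional. The 40,000-particle ensemble is
one seeded ensemble per burst window.

## Reproducibility plumbing

A run is declared by a YAML config with defaults for every field; unknown
keys are rejected in strict mode with a dotted path. One global seed
expands to per-stage seeds as child k of `numpy.random.SeedSequence`
(spawn_key = stage index, reduced below 2³¹), so stages can be re-run in
isolation. Each run writes a JSON manifest (config snapshot, version,
timestamps, per-stage seeds, SHA-256 checksums of outputs) before the first
stage and finalizes it after the last; identical configs and seeds produce
identical output checksums. Grids travel as HDF5 with named-axis metadata;
spectra, rasters and traces as columnar text.

Default problem sizes are chosen for desk-scale runs: the single-neuron
stage uses a 20 µm lattice over a 120×200×120 µm³ box, and the network
stage records on a 25 µm lattice; the full 5 µm/237,021-site lattice is
exercised where only geometry is needed and is available everywhere else
by configuration.

## What the synthetic benchmarks show — and what they do not

The test suite verifies the implemented physics against independent
oracles: arbitrary-precision evaluation of the Langevin function, closed
forms for square-wave harmonics and point-source potentials, analytic
gradients, binomial/statistical recovery of connectivity rules, and
z-tests on Monte Carlo displacement statistics. Passing them establishes
internal correctness of the chain, and the SPION harmonic ratios reproduce
the published 32.48/18.98/13.20% to better than 1%.

They do not establish: absolute FEM-derived quantities (flux maxima, the
per-core-size sensitivity slopes as computed outputs, angular-sweep
extremes), absolute network magnetization amplitudes (NEURON/NetPyNE
biophysics), or behavior of real tissue (heterogeneous conductivity,
particle aggregation and binding, vascular geometry, hysteresis of
immobilized particles). The slope table, angular floors and composite
saturation are calibrated to printed values, not derived; conclusions that
depend on their absolute scale inherit that calibration.

## Known limitations

- The lumped solver's E-field response depends on the stress-transfer and
  clamp factors; the FEM sensitivity slopes are not recovered from first
  principles, which is why the forward models use the calibrated slope
  table instead.
- The surrogate network's burst timing comes from its drive; only
  connectivity, kinetics parameters, rates and burst statistics are
  meaningful, not absolute signal amplitudes.
- Soma-as-point-source and center-line distances slightly misestimate
  potentials within a radius of a compartment; sites are clamped to the
  surface distance rather than excluded.
- Molarity conversions treat the suspension as particle molarity; chemical
  (formula-unit) molarity would require a molar mass the model does not
  define.
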