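# Methods

This note documents the models behind `rooteit`, the defaults that matter,
and what the synthetic generators do and do not emulate.

## Geometry and meshing

The imaging domain is a cylinder (soil circle: 6 in diameter, 8 in height;
water: 6 × 7 in), stored in SI meters with inches converted at exactly
0.0254 m/in. The sensor is a ring of 8 sticks, 3 electrodes per stick
(24 total; 2 in long, 0.0625 in diameter, 1 in layer spacing, sticks 2.5 in
apart on the ring). Electrodes are numbered sequentially layer by layer, top
layer first, counter-clockwise from azimuth 0, and each stick's electrodes
share one vertical line (planar alignment).

For the complete electrode model the physical rods are idealized as
rectangular patches on the domain wall at the stick azimuth; the ring
diameter therefore *is* the FEM domain diameter. The effective contact area
of a patch is a modeling parameter: the physical rod dimensions (2 in length
at 1 in layer spacing) would make same-stick patches overlap, which the CEM
cannot represent, so the default patch height is
min(electrode_length, 0.8 × layer_spacing) and the patch width spans the two
mesh columns adjacent to the stick azimuth. Both are configurable
(`contact_height`, mesh resolution).

The mesh is a deterministic structured tetrahedralization: a polar disk
triangulation (center vertex plus concentric rings) extruded through sorted
z-levels, each prism split into three tetrahedra with the minimum-vertex-
index diagonal rule so splits of adjacent prisms conform. Extra z-levels are
inserted at patch edges so electrode patches are tiled exactly. The angular
resolution is rounded up to a multiple of the stick count, which puts every
stick azimuth on a mesh node line. Consequences worth knowing:

- total mesh volume converges to πr²h from below (polygonal cross-section);
  at the default imaging resolution (target edge 18 mm) the deficit is ≈1%;
- the prism-diagonal orientation depends on global node indices, so the mesh
  is *not* exactly invariant under 45° rotation; rotational-symmetry checks
  hold to ≈0.1% at the resolutions used, and tests use a 1% tolerance;
- refinement is global (via `target_edge`), not local to electrodes.

Meshes and images are exchanged as legacy-ASCII VTK unstructured grids
(tetrahedra with per-cell scalars), written and read by the package itself.

## Forward model

P1 tetrahedral finite elements with piecewise-constant conductivity.
The CEM system couples nodal potentials u, electrode potentials U and a
gauge multiplier enforcing ΣU = 0:

    [K + S   B   0] [u]   [0]
    [Bᵀ      D   1] [U] = [I]
    [0       1ᵀ  0] [γ]   [0]

with K the σ-weighted stiffness matrix and S, B, D the contact-impedance
surface couplings (z = 0.01 Ω·m² per electrode by default; the hardware
value is unknown). Currents are ±1 mA on the drive pair; voltages are
reported as (sense⁺ − sense⁻). The matrix is factorized once (sparse LU) and
reused across all drive and adjoint patterns.

Properties. Reciprocity holds to solver tolerance. The exact homogeneity law
of the CEM is joint: scaling σ → cσ *and* z → z/c scales voltages by 1/c;
at fixed contact impedance, σ-only scaling is inverse only to within a few
percent because the contact layers reshape the current distribution near the
drive electrodes. Tests assert the exact joint law and the approximate
σ-only law (≤5%).

The sensitivity of measurement m to element e is computed by the adjoint
method, J[m,e] = −∫ₑ ∇u_drive·∇u_sense dV with the sense field driven by
unit current; it matches central finite differences to ≲10⁻⁵ relative on
coarse meshes (the test bound is 1%).

Only real conductivity (impedance magnitude) is modeled; phase is carried in
the acquisition types but unused by reconstruction.

## Inverse model

One-step Gauss–Newton difference imaging:

    Δσ = (JᵀWJ + λ²R)⁻¹ JᵀW ΔV

- ΔV is the normalized difference (Vᵢ − Vₕ)/Vₕ by default (raw difference
  available); when normalized, J rows are scaled by 1/Vₕ consistently.
- W is the identity unless a measurement covariance is supplied.
- R is the NOSER diagonal diag(JᵀWJ)^p or the identity (Tikhonov).
  The NOSER exponent default is p = 1 — the original NOSER normal-equation
  diagonal. With the fixed default λ = 2.17 and normalized data, p = 0.5
  under-penalizes low-sensitivity elements near the wall and the image peak
  migrates to boundary artifacts; p = 1 recovers a centered inclusion within
  one element diameter. The exponent remains configurable.
- λ defaults to 2.17, the value this sensor geometry was operated with.
- Since both priors are diagonal and elements far outnumber measurements,
  the update is evaluated in measurement space via the Woodbury identity
  (an m×m solve, m ≤ 504) — algebraically identical to the element-space
  normal equations, and tested against the dense formula to 1e−8.
- Condition numbers above 1e12 raise a warning with the estimate.

Reconstructed Δσ is reported in normalized, dimensionless units. Difference
imaging against any reference frame of a series gives time-difference EIT.

## Acquisition model

The impedance converter reports DFT real/imaginary outputs R, X. A gain
factor is calibrated against a 7.5 kΩ reference so that
Z = 1/(gain·√(R²+X²)) returns the reference exactly; this identity holds for
any calibration magnitude. Sweep frequencies are quantized as
f = f_clk·code/2²⁹ (f_clk = 16.776 MHz), so round-trip error is below one
code step (≈31 mHz). Two-pole sweeps drive and sense through the same pair:
off-diagonal entries are FEM transfer impedances including both contact
layers; the self-pair entry Z(a,a) — listed by the instrument but physically
a pure contact path — is modeled as 2z/|Eₐ|. Excitation-level dependence of
measured impedance is an instrument artifact, not physics, and belongs to
the simulator configuration, not the PDE.

How two-pole pair sets map onto the tetrapolar boundary voltages used for
imaging is not fully determined by the hardware description; the package
supports both acquisition styles (impedance tables for regression, frame
pairs for imaging) and converts impedance to boundary voltage as V = Z·I at
the 1 mA stimulation current where needed.

## Synthetic phantoms and datasets

**Imaging generator.** A root is a tapered frustum (tip/top radius ratio
0.25) hanging from the domain top on a vertical axis. Fresh weight maps to
volume through a density of 1.03 g/cm³; elements are included inside-out by
normalized distance to the axis until the volume matches weight/density to
within one element volume, which also makes inclusion volume strictly
monotone in weight. Root conductivity follows a single-dispersion law
σ(f) = σ_low + (σ_high − σ_low)(f/f_c)^p/(1 + (f/f_c)^p), strictly
increasing in f. Background defaults: soil 0.05 S/m, water 0.02 S/m, root
σ_low 0.1 S/m, σ_high 0.3 S/m, f_c 50 kHz — plausible values for moist
substrate and fresh taproot tissue, exposed in configuration because no
measured conductivities are available. Measurement noise is 1% relative
multiplicative Gaussian, seed-deterministic. The study's longest sample
(8.5 in) exceeds the 8 in container; the ordering experiment clips length to
the domain height and preserves volume by widening the frustum.

**Regression generator.** Layer-mean impedances follow the log-linear law
ln Z̄ = a_f − b_f·W with a_f = ln(5000 Ω) − 0.25·ln(f/5 kHz) (impedance
falls with frequency) and b_f = 0.004·(1 + 0.15·ln(f/5 kHz)) g⁻¹
(correlation strengthens toward 100 kHz). Within a layer, a deterministic
sinusoidal electrode-pair pattern (amplitude 10%, arithmetic mean exactly 1)
reproduces the ring structure of pair sweeps. Noise has three seeded
components on the log scale — per-sweep drift (sd), per-layer (sd/2) and
per-entry (sd, averaged over 64 pairs) — all zero when sd = 0, with the
resulting layer-mean log-sd available as `layer_mean_log_sd`. The default
sd = 2% puts the fitted biomass RMSE at the few-gram scale of averaged EIS
replicates. Weights are spread over 62–115 g (the documented drying range)
and lengths co-generated as L ∝ W^⅓.

What the generators do *not* emulate: electrode polarization, soil-moisture
drift between sweeps, electrode-position error, instrument gain oscillation
at low excitation, and multi-root architectures. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
assumptions, not field robustness.

## Regression and diagnostics

Features: impedances are normalized per sample by the sample's maximum over
the analyzed spectrum (values in (0,1]; the normalization base used for the
published models is not recoverable, so the strategy is pluggable), then
layer-wise mean and SD are taken — six features for three layers. OLS uses
the standard t/p per coefficient and overall F-test; RMSE is √(RSS/n) by
default (divisor configurable). Ridge centers features, leaves the intercept
unpenalized, and solves the penalized normal equations in closed form;
α = 0 reproduces OLS on full-rank designs, and the default α comes from
generalized cross-validation on a log grid. Collinearity screening reports
per-feature R², TV = 1 − R², VIF = 1/TV (flagged at TV < 0.1 / VIF > 10) and
pairwise |r| > 0.95 partners. Backward elimination drops the highest-p
coefficient above 0.05 until all pass, then checks the overall F-test and
attaches a warning on failure.

The published models eq1–eq9 are shipped as a versioned registry of
intercepts and coefficients (grams); eq1/eq2 use the 15 and 80 kHz features,
eq3–eq9 the six layer features per frequency. Validation reports compute
100·|actual − predicted|/actual, rounded half-even to two decimals (printed
validation tables mix rounding and truncation; rows where the two disagree
are not used as references).

## Problem sizes and numerical choices

Default imaging runs use ≈15.5k elements / 3.1k nodes (target edge 18 mm),
which resolves the 24-electrode array while keeping a full
simulate-and-reconstruct cycle of four phantoms under ten seconds; test
fixtures use a coarser single-layer ring (≈3.5k elements). Cholesky is used
for the regularized normal equations, sparse LU for the CEM system; NOSER
diagonals of insensitive elements are floored at 1e−12 of the maximum with a
warning. All stochastic steps take explicit integer seeds.

## Known limitations

- Single-frequency real-valued conductivity; no complex admittivity/phase.
- One-step (linearized) reconstruction only; no iterative GN, total
  variation, or learned reconstructors.
- Structured mesh limits electrode-patch geometry to wall-aligned windows.
- The published models' absolute predictions depend on the original
  hardware's normalization base; they are evaluated exactly as printed but
  cannot be re-derived from synthetic data.
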