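# Methods

This note documents the models, parameters, numerical choices, and known
limitations of the `fusht` simulation chain.

## Acoustic model

The source is a uniformly vibrating spherical cap (single-element focused
bowl). The steady-state linear pressure amplitude is the
Rayleigh–Sommerfeld integral

    p(r) = −(ik/2π) ∮ p₀ e^{ikR}/R dS

over the cap, evaluated with the wavenumber of the coupling water
(c = 1482 m/s). Because both the source and the default layered phantom
are rotationally symmetric about the beam axis, the lossless integral is
computed on an (r, z) half-plane and interpolated onto the 3-D voxel
grid; this is exact up to interpolation and reduces the cost by ~two
orders of magnitude. Attenuation is applied as a cumulative axial factor
`exp(−∫ α(z′) dz′)` integrated through the actual 3-D material map, with
α linear in frequency (table units Np/(m·MHz)). Refraction and interface
reflections are neglected: the impedance contrasts between the four media
are below 5%, so reflected energy is below ~0.1%. Nonlinearity,
cavitation, standing waves, and shear propagation are out of scope.

**Quadrature.** The cap is discretised into ~4.1 × 10⁴ area elements
(polar bands with exact band areas × uniform azimuth). The midpoint rule
converges at second order; at this resolution the on-axis profile matches
the closed-form axial solution for a spherical cap to better than 0.6%
pointwise everywhere beyond 5 mm from the apex, and the focal peak moves
by less than 0.5% when the element count is doubled (asserted in tests).

**Calibration.** `surface_pressure` is scaled so that the lossless-water
focal peak equals the requested focal pressure (default 1 MPa), the
in-silico analogue of a hydrophone calibration. The model is linear in
the drive, so a single exact rescale replaces iteration; the probe uses a
narrow on-axis column of the target grid since the lossless peak lies on
the axis.

**Heat source.** All attenuated energy is deposited locally:
`Q = α·p²/(ρc) = 2αI`, the plane-wave absorption relation. Attenuation is
not split into absorbed and scattered parts (the property table does not
separate them). Water (α = 0) receives no heating.

**Focal metrics.** The −3 dB convention is half *intensity* (amplitude ≥
peak/√2). Extents are connected spans around the global peak, with linear
interpolation between voxel centres; lateral through the peak
perpendicular to the axis, axial along it.

### Known discrepancy: axial focal length

For the 44 mm / 31.5 mm bowl at 350 kHz in water, the exact diffraction
integral gives −3 dB focal dimensions of **2.92 mm (lateral) ×
12.10 mm (axial)** — confirmed by two independent routes (closed-form
axial solution; fine-quadrature reference evaluation). The
manufacturer-style quoted dimensions are 3.1 × 15.4 mm. The lateral width
agrees within 6%, but the quoted axial length coincides with the paraxial
estimate 7.1·λ·(F/D)² ≈ 15.4 mm, which substantially overestimates the
axial lobe of a bowl this strongly focused (F-number 0.72). We report the
exact-model value. Downstream, the more compact focus deposits roughly
30–45% less integrated power around the focal region than a 3.1 × 15.4 mm
focus would; see "Thermal behaviour" below.

## Thermal model

Pennes bioheat equation with constant coefficients per medium:

    ρC ∂T/∂t = ∇·(k∇T) + w_b C_b (T_a − T) + Q·u(t)

with arterial temperature T_a = 37 °C and blood specific heat
C_b = 3700 J/(kg·°C) (the soft-tissue value; blood properties are
otherwise unspecified). Perfusion w_b is in kg/(m³·s) exactly as the
property table implies, with no temperature dependence. Water is treated
as a conducting solid (no convection).

**Scheme.** Explicit forward-Euler FTCS in conservative flux form with
harmonic-mean face conductivities at material interfaces, implemented as
a numba kernel (~2 ms per step on the 1.3 M-voxel default grid). The time
step defaults to half the positivity bound computed from the actual face
conductivities and perfusion sink, `dt ≤ ρC/(Σ λ_f/Δx² + w_b C_b)`, which
reduces to the textbook `ρCΔx²/(2dk)` in a uniform medium (~0.088 s on
the default grid). The scheme is verified against: exact discrete energy
conservation (insulated, perfusion-free), the maximum principle, the
closed-form lumped perfusion relaxation (k → 0), an independent fine-grid
1-D two-medium reference solver, and the analytic two-rate relay
oscillator.

**Initial and boundary conditions.** Tissue starts at 37 °C, coupling
water at 23 °C; a 10-minute source-free equilibration precedes treatment.
The two faces perpendicular to the beam axis are Dirichlet-clamped at
their initial values (23 °C on the water face at the apex, 37 °C on the
deep tissue face); all other faces are insulated. Clamping the deep face
at the water temperature would be unphysical since it lies in muscle; a
fully insulated mode exists for verification runs.

**Controller.** An ideal two-state relay emulates the experimental PID
box gating the function generator: strict comparisons (OFF when the
sensor *exceeds* 42.0 °C, ON when it *falls below* 41.5 °C), state
memory inside the band, initial state ON. The sensor is the voxel nearest
the tumor centre, consulted every solver step.

**Thermal dose.** CEM43 with Sapareto–Dewey constants R = 0.50 (≥43 °C)
and 0.25 (<43 °C), both configurable since some literature uses other
sub-breakpoint values. Dose is accumulated streaming from temperature
snapshots every 10 solver steps (~0.9 s of simulated time, configurable);
the sensor temperature changes by ≲0.01 °C per interval at the simulated
heating rates, so the subsampling error is negligible.

### Thermal behaviour of the default scene

With the exact-diffraction focus, a 1 MPa focal drive raises the
tumor-centre sensor at 0.41 °C/s initially (the adiabatic rate Q/ρC) but
equilibrates near **41.4 °C**: lateral conduction out of the compact
focal cigar into the cold coupling water balances the deposition before
the 42 °C relay threshold is reached. The volume-maximum CEM43 of the
default 20-minute treatment is therefore **≈1.2** equivalent minutes
rather than the ≈3.5 that a sustained 41.5–42 °C oscillation would give
(20 min × 0.25^1.25 ≈ 3.5). A focus matching the quoted 3.1 × 15.4 mm
dimensions would deposit ~40% more power and cross the threshold; this
sensitivity — a fraction of a °C in sustained temperature maps onto a
~3× factor in CEM43 through the exponential dose rate — is the main
caveat when comparing simulated dose values between implementations.
Skipping the equilibration entirely changes the picture by less than
0.3 °C, so the initial condition is not the cause.

## Radiotherapy timing

Beam-on time = dose / (base rate × output factor), with the 4.1 Gy/min
base rate and 0.79 output factor of a 5 mm collimator on a small-animal
platform; 2 Gy → 0.617 min and 5 Gy → 1.544 min, matching the console
settings of 0.6 and 1.5 min after rounding to 0.1 min. The shallow
(~3 mm) target depth is carried as metadata; a percent-depth-dose hook is
provided as an optional multiplicative rate factor (default 1) because
the printed times are reproduced exactly by the depth-free formula.

## Growth analysis

Caliper volume `V = ½·L·W²` (length = longest dimension, width
perpendicular; width ≤ length is enforced). Analyses run on raw volumes
— no log transform — matching the mean ± SD reporting convention, on the
day-7 cross-section by default (the published comparisons are single-day;
the arms of this model spontaneously regress at longer follow-up, so a
one-week window is the meaningful one). One-way fixed-effects ANOVA,
then pairwise Welch t-tests (Welch–Satterthwaite df, two-sided) with
Bonferroni multiplier m = 3 by default — the three comparisons of the
combined arm against control, RT-alone, and FUS-HT-alone — configurable
because the published analysis does not state its multiplier.

## Synthetic cohorts

The generator emulates a four-arm study: per animal and day a volume is
drawn from a normal distribution truncated at a 1 mm³ floor, an aspect
ratio a ~ U[1.0, 1.6] is drawn (no shape data is published; subcutaneous
tumors are mildly prolate), and (L, W) are emitted by inverting
V = ½·L·W² with L = a·W. A truncated rather than log-normal distribution
is used because the targets are arithmetic mean ± SD. The underlying
normal parameters are *moment-matched* (2-D root find on the truncated
moments) so the truncated distribution has exactly the target mean and
SD; naive truncation of N(mean, SD) would bias the smallest arm upward
by ~12%. Draws are independent across animals and days — the analysis is
cross-sectional, so no within-animal longitudinal correlation is
modelled. Seeded runs are bit-reproducible.

What passing tests show — and what they do not: the generator reproduces
the published group-level moments and the day-0 homogeneity / day-7
separation structure, so the statistics pipeline is exercised under
realistic effect sizes. It does not model measurement error, operator
bias, growth kinetics, or censoring, so it validates the analysis code,
not biological inference.

## Problem sizes

Defaults were chosen so the full chain runs in minutes on one CPU: the
default grid is 0.4 mm (≈10.6 points per wavelength in water, comfortably
above the 6-point floor the field evaluation enforces) over
40 × 40 × 50 mm (101 × 101 × 126 voxels); the treatment simulation takes
~20,600 explicit steps. The statistical acceptance summaries use 1000
replicate cohorts (2000 for the generator-bias check), which bounds the
Monte-Carlo error on the reported medians and means well below the
decision thresholds involved.

## Known limitations

- Linear acoustics only; no refraction or reflection at tissue
  interfaces (justified by <5% impedance contrast, but not valid for
  bone or gas interfaces).
- Absorption = attenuation over-deposits heat where scattering is
  appreciable.
- Water is a conducting solid; free convection in the coupling bath
  would increase near-skin cooling.
- Explicit time stepping only; fine grids pay a quadratic dt penalty.
- The relay controller is an idealisation of the experimental PID
  hardware (whose gains are not published); pressure-amplitude modulation
  is not modelled.
- The thermal-dose headline value is highly sensitive to the focal
  volume, as quantified above.
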