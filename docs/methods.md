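# Methods

`ringfus` simulates an annular ("racing ring") phased-array ultrasound
transducer intended for non-invasive retinal stimulation. The ring sits on
the cornea like a contact lens; its central hole lets the beam bypass the
strongly absorbing crystalline lens, and the annulus of elements on a
spherical cap focuses and patterns ultrasound on the retina. This note
records the models, the defaults and why, the numerical choices, and the
known limits of what the simulations show.

## Geometry model

The array is a spherical cap of curvature radius `R_c = 12 mm` (adult
eyeball scale) with elements restricted to the annulus between the inner
diameter (9 mm) and outer diameter (11 mm). Coordinates: cap apex at the
origin, beam along +z, sphere centre at `(0, 0, R_c)`, stimulation plane at
`z = 7 mm` (rat-eye retinal depth).

Candidate element sites are a square x–y lattice with spacing equal to the
element pitch (0.075 mm, one wavelength at 20 MHz in water), kept when
`ID/2 <= r <= OD/2` and lifted onto the cap by the sag
`z = R_c − sqrt(R_c² − r²)`. A square lattice is the simplest layout
consistent with a single scalar pitch; no polar layout is provided. The
5596-site lattice is then sparsified to exactly `n_elements = 512` by a
seeded uniform draw without replacement (default seed 0, recorded in every
output), a realised occupancy of ~9.1% — the "10% sparse" design regime.
The design table's element size (0.15 mm) exceeds the pitch, which is not
physically realisable as tiled elements; we therefore model each element as
a **point source at its lattice node** whose strength is proportional to its
radiating area `element_size²`. An alternative `surface_cell` area mode
assigns each site the true cap-surface tile `pitch²/cosθ`, which is what a
dense, non-sparse lattice needs to approximate a continuously driven bowl
(used by the closed-form validation below).

Invariants enforced by construction and by tests: every element on the
sphere to 1e−9 mm, inside the annulus, normals unit-length pointing at the
sphere centre. `ID = 0` is allowed (full cap) for validation geometries.

## Forward model

Pressure at field point `r_m` is the discretised Rayleigh–Sommerfeld sum of
spherical wavelets,

    P(r_m) = (j ρ c k / 2π) Σ_n u_n A_n exp(−j k d_mn) / d_mn ,

assembled as the complex matrix `H` with `P = H U`. Conventions: harmonic
factor `exp(+jωt)` dropped, so stored phase *decreases* with distance and
focusing uses the conjugate phase `+k d`; lengths in mm, frequencies in MHz
(`λ_mm = c[m/s]/f[MHz]/1000`); ρ and c enter only as an overall scale, so
all reported field quantities are relative (dB re grid peak). A cosine
obliquity factor is available (`obliquity=True`) but off by default — the
element model is a pure point source. Power-law attenuation
`a = a0 f^γ` (dB/cm) can multiply the kernel by `exp(−α d)`; it is off by
default in field maps and available for dosimetry pipelines.

Validation: the matrix agrees entrywise to 1e−12 with a scalar double-loop
oracle; a single element decays exactly as 1/d; and a dense (non-sparse)
annular cap under uniform drive reproduces the exact on-axis closed form
for a focused annular radiator (difference of two spherical caps,
`P(z) = ρc·R/(R−z)·(e^{−jkd_in} − e^{−jkd_out})`) within 2% at field points
away from axial interference nulls. Near a null the denominator of a
relative comparison vanishes, so closed-form checks are made where the
field is strong.

Beam metrics: the −3 dB intensity width (FWHM) is measured along each grid
axis through the global intensity maximum with linear interpolation of the
`|P|²` crossings. A peak on the grid border is an error; a crossing outside
the grid marks the axis unresolved (width = +inf). On the reference design
at 7 mm depth the lateral FWHM is ≈ 0.041 mm at 20 MHz and ≈ 0.160 mm at
5 MHz — both far inside the 1.5 mm design envelope, as diffraction
(`D ≈ λ·F#`, F# ≈ 0.7) predicts.

## Multi-focus solvers

With control points few and elements many (`M << N`), the minimum-norm
exact interpolant is `U = H^H (H H^H)^{-1} P`. The iteratively weighted
variant `U = W H^H (H W H^H)^{-1} P` starts at `W = I` and repeatedly
divides the diagonal weight by the current element amplitudes
(`w_n ← w_n / max(|u_n|, ε)`, renormalised to mean 1), equalising drive
amplitudes across the aperture while every iterate still interpolates the
targets exactly. The update rule is fixed, not pluggable; the stopping rule
is a `tol = 1e−6` relative change of amplitudes or 50 iterations. If the
`M×M` normal matrix has condition number above 1e12 a Tikhonov ridge of
`1e−10·trace/M` is added with an audible warning — never silently. The
relative residual is part of every result.

## Holography

The hologram plane (z = 0) and the pattern plane (z = depth) are related in
the far field by a scaled 2-D Fourier transform; `image_to_aperture` /
`aperture_to_image` implement that pair as exact inverses with the
`1/(λz)` far-field scaling on the aperture side. Because 7 mm is not
strictly far-field at 20 MHz, the **angular-spectrum propagator is the
authoritative forward model**: FFT filter `exp(−j dz √(k² − kx² − ky²))`
with evanescent components zeroed, exact for a homogeneous medium. The raw
operator uses no padding (it is then exactly unitary on the propagating
band — round-trip and Parseval tests hold to 1e−10); the synthesis loop
embeds fields in a 2× zero-padded frame to suppress wrap-around.

Phase-only synthesis uses the weighted Gerchberg–Saxton loop: propagate the
phase-only source to the pattern plane; on the support (pixels ≥ 10% of the
target peak) replace amplitudes by `w·I` and update `w ← w·⟨|V|⟩/|V|`
(clamped to [1e−3, 1e3]); **zero the amplitude off the support** — leaving
it free lets sparse targets reach high "uniformity" while parking almost
all energy off-pattern; back-propagate; re-impose unit source amplitude.
Initial phase is the conjugate lens toward the target centroid plus a
seeded ±0.5 rad uniform perturbation (seed 1). Raw GSW uniformity
(`1 − (max−min)/(max+min)` of `|V|` over the support) oscillates at the
1e−3–1e−4 level near convergence, so the loop tracks the incumbent: the
best-uniformity iterate is kept, `uniformity_history` records the incumbent
per iteration (non-decreasing by construction), and the returned hologram
is built from it. Stopping: 50 iterations or < 1e−4 incumbent improvement
over five iterations.

Bridging the planar hologram to the curved array samples the hologram phase
at each element's (x, y) projection (nearest pixel) and subtracts the sag
path-shortening toward the pattern-plane centre,
`Δ = sqrt(r²+z₀²) − sqrt(r²+(z₀−sag)²)`, times k. This is exact for the
plane centre and paraxially accurate elsewhere; the end-to-end test
(hologram → elements → Rayleigh–Sommerfeld field) focuses a requested point
to within one 10 µm grid spacing. For this bridge the hologram plane must
cover the projected annulus: at the default 0.035 mm pixel pitch a 256 px
hologram spans 8.96 mm < OD = 11 mm, so curved-array sampling needs a wider
plane (e.g. 320 px at λ/2 = 0.0375 mm). The `pattern` pipeline reports its
fields from the planar aperture path and says so in its report.

Pattern quality is scored by zero-mean normalised cross-correlation against
the target raster, support uniformity and support energy fraction. On the
built-in 256 px "USC" letters at 20 MHz the converged correlation is ≈ 0.78
(recorded release baseline 0.77) with ≈ 82% of the energy on the letters.

## Dosimetry

Four pure functions: diffraction resolution `D = K λ F#` (K = 1);
sonophore-efficacy pressure scaling `(f2/f1)^β` from
`ε_max ∝ P_A f^{−β}` — β defaults to 0.85, the midpoint of its empirical
0.8–0.9 range, and the printed exponent variants (β/2, 1/(2β)) are
derivable from the returned ratio; power-law attenuation `a0 f^γ` dB/cm
with defaults `a0 = 0.1` dB/cm (vitreous-like), `γ = 1.2`, plus a
calibration helper that pins `a0` to the crystalline-lens figure of 7.8 dB
at 10 MHz given a path length; and the ophthalmic power budget
`P_max = 50 mW/cm² × (side/10)²`. For the 8.96 mm pattern that is
40.14 mW. A stated device budget of 80.3 mW is *within* spec as a bound but
implies ≈ 100 mW/cm² over the same area; the budget record flags that
inconsistency explicitly rather than resolving it.

## Problem sizes and determinism

Default field maps are 1.5 × 1.5 mm at 10 µm (lateral) and
1.5 × 10 mm at 10 × 50 µm (axial); solver tests use 8×32 to 64-element
systems; holography runs at 128–320 px. These sizes keep every simulation
deterministic and reproducible from (spec, seed) alone — the only random
inputs are the sparsification seed and the GSW phase-perturbation seed,
both recorded in outputs.

## Limitations

Continuous-wave, linear, homogeneous-medium acoustics only: no time-domain
pulses, nonlinearity, refraction or scattering at ocular interfaces, and no
piezoelectric/electrical element response (the design table's 1.4 mm
thickness is not simulated). The neural side is reduced to the
sonophore scaling law — no membrane-dynamics ODEs. Synthetic letter/disk
targets are binary and noise-free; passing pattern tests therefore shows
the synthesis loop works on clean rasters, not that a camera-fed system
meets perceptual requirements. The hologram-to-element bridge assumes
phase-only, uniform-amplitude drive and nearest-pixel sampling; amplitude
shading and sub-pixel interpolation are out of scope.
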