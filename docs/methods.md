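# Methods

## Scope and model

`shearwave` implements a shear wave elasticity imaging (SWEI) processing
chain — directional filtering of 4-D displacement fields and
cross-correlation shear wave speed (SWS) reconstruction — together with an
analytic wavefield generator that stands in for a finite-element
elastodynamics solver. The generator is a traveling-pulse superposition:
it reproduces the wave *kinematics* that the filters and estimators key on
(arrival times, propagation directions, impedance-controlled amplitude
ratios, additive tracking noise) but not continuum mechanics (no mode
conversion, no full diffraction, no viscoelasticity).

Units: mm for space, ms for time, kHz for sampling rates, µm for
displacement. Speeds in mm/ms equal m/s, so no unit conversion appears in
the speed maps.

## Synthetic wavefield generator (`shearwave.phantom`)

**Materials.** A material is (E, rho, nu) with
c_T = sqrt(E/(2·rho·(1+nu))). The study materials are a 3 kPa background
and 6 / 12 / 18.75 kPa lesions at rho = 1 g/cm³, nu = 0.495, i.e.
c_T = 1, 1.4, 2, 2.5 m/s. Shear impedance is Z = rho·c_T and the
displacement reflection coefficient at the background→lesion interface is
R = (Z_les − Z_bg)/(Z_les + Z_bg).

**Incident pulse.** The push is a 3-D Gaussian body force with standard
deviations (σx, σy, σz) and amplitude A (study values: σz = 4.25 mm,
z0 = 21 mm, t_on = 80 µs; excitation 1 has σx = σy = 0.21 mm,
A = 0.11 dyn). The generator launches, from the push center r0, the pulse

u(r, t) = C·A · decay(d) · trans(r) · exp( −(t − τ(r))² / 2σ_t(n)² )

with d = |r − r0|, direction n = (r − r0)/d, and:

- σ_r(n) = (Σ_i (n_i/σ_i)²)^{−1/2}, the Gaussian radius of the source
  envelope along n — so the t = 0 snapshot matches the anisotropic source
  envelope (times the decay factor) exactly;
- σ_t = σ_r(n)/c_bg: the temporal pulse width, conserved across
  interfaces;
- τ(r): straight-ray travel time with piecewise speed — the ray's chord
  through the lesion sphere travels at c_les, the rest at c_bg. Peak
  arrival at a background point is therefore d/c_T exactly;
- decay(d) = (d0/max(d, d0))^γ with d0 = max(σx, σy) and γ = 0.5 by
  default (near-cylindrical spreading; configurable);
- trans(r): 1 in the background before the lesion, (1 − R) inside it,
  (1 − R²) beyond it (entry and exit transmission);
- C = 100 µm/dyn, a free calibration putting peak displacement at ~11 µm
  for A = 0.11 dyn, in the range of experimentally tracked ARFI pushes.

**Reflections.** Reflected waves are radiated by small sets of specular
virtual sources on the lesion surface: the pole plus a ring of `n_ring`
points (default 6) at polar angle `ring_angle_deg` (default 40°) on the
near hemisphere (external reflection, amplitude R × incident, re-entering
the background) and on the far hemisphere (internal reflection, amplitude
−R × transmitted, re-entering the lesion). Each source radiates a pulse
with cos² directivity about its specular direction, geometric decay
continuing from the already-propagated distance, and is confined to its
side of the interface. The ring provides the out-of-plane reflected
energy a curved boundary produces; the refocusing "lens" effect of lesion
curvature is not modeled. Reflected amplitude is monotone in the
impedance contrast, reproducing the artifact-severity ordering across the
three lesion stiffnesses.

**Noise.** `add_awgn` adds zero-mean white Gaussian noise with power set
by the requested SNR over the whole 4-D volume (the convention of common
"add noise at given SNR" utilities); the study setting is 25 dB with ten
realization seeds. All randomness is behind explicit integer seeds; the
wavefield itself is deterministic.

**Resampling.** Time traces are cubic-spline upsampled (10 → 50 kHz for
all reconstructions); spatial decimation to coarser isotropic spacing uses
nearest-grid subsampling at integer ratios and linear interpolation
otherwise.

## Directional filters (`shearwave.dirfilt`)

A real field traveling toward +x concentrates its discrete Fourier energy
where sign(k_x)·sign(ω) = −1 (verified functionally: a translating pulse
passes, its time-reverse is rejected). The quadrant filter passes that
quadrant pair, zeroes the complement, and assigns `boundary_value`
(default 0.5, to limit ringing) to the k_x = 0 and ω = 0 lines — and to
the sign-ambiguous Nyquist lines of even-length axes, which are their own
conjugates and must carry symmetric weights for the output to be real.

The 3-D and 4-D filters multiply the quadrant mask by an angular weight
cos^q θ, cos θ = (u·k)/(|u||k|), about u = +x (q = 2 by default; negative
cosines clamp to 0 so an even power cannot pass backward waves; the k = 0
point takes weight 1 and is down-weighted by the quadrant term instead).
Because the one-sided angular factor would break the conjugate symmetry a
real output requires, the product is symmetrized as
max(F(k, ω), F(−k, −ω)): each physical propagation sense occupies two
conjugate half-spaces, and the mirrored maximum passes both while leaving
the DC line at the quadrant boundary value. Filters are built on the
unshifted FFT layout; weights are always in [0, 1], so filtering never
amplifies energy.

Application: 2-D filters transform each depth of the y = 0 plane over
(x, t); 3-D filters transform that plane over (x, z, t); 4-D filters
transform the full volume. The inverse transform's real part is returned,
with the imaginary residue checked against a 10⁻⁶ relative guard.

## Speed reconstruction (`shearwave.sws`)

For each pixel, the displacement-through-time traces of the two pixels
±p/2 away along an axis (full traces, p = 6 with window w = 10 at fine
sampling; p = 4, w = 8 for 0.3 mm-decimated data) are cross-correlated
after mean removal, normalized by the zero-lag energies. The peak lag is
refined with the three-point parabolic (Jacobsen) fit
δ = (C₋₁ − C₊₁)/(2(C₋₁ − 2C₀ + C₊₁)), falling back to the integer lag on
non-negative curvature, and Δt = lag/PRF at the 50 kHz working rate. The
signed component speed is V = p·Δx/Δt. Estimates are invalid when a trace
is constant, the correlation peak sits on the lag boundary, or
|Δt| < one working-rate sample (the speed is then unbounded).

Component maps are fused over the (w−p+1)-wide window with weights CC²/r
(r = Euclidean pixel distance, 1 at the center; invalid estimates get
weight 0). Signed speeds are retained through fusion. A fused component
whose magnitude falls below `cancel_fraction` (default 0.25) of the
weighted-mean magnitude of its constituents is dominated by sign
cancellation — the situation at symmetry planes, where estimates are
antisymmetric and the true component speed is unbounded — and is flagged
invalid rather than passed on as a spuriously slow component.

Components combine through the slowness identity
1/V² = Σ_i 1/V_i² (algebraically identical to
V_2D = VxVz/√(Vx²+Vz²) and V_3D = VxVyVz/√(Vx²Vy²+Vx²Vz²+Vy²Vz²)), with
invalid components simply dropping out of the sum — which implements the
unbounded-component limits of those formulas exactly (one invalid
component reduces the 3-D formula to the 2-D one, two to the remaining
component). The sign is the product of the valid component signs;
magnitude is taken only when the final map is rendered.

Maps are median filtered at a physical size converted to odd pixel
kernels (0.5 mm below 0.3 mm pitch, 1.5 mm at or above), NaN-aware so
invalid pixels do not contribute. Pixels whose w-window leaves the field
are excluded from the validity mask (no padding).

## Image quality (`shearwave.quality`)

CNR = (S_i − S_o)/√(σ_i² + σ_o²) between a circular in-lesion ROI and two
half-circle background regions of the same diameter directly above and
below the lesion, offset from the lesion edge by half the fusion-window
length; percent bias is 100·(ĉ_T − c_T)/c_T per valid pixel of the lesion
ROI. ROI membership is strict (pixel centers strictly inside). The ROI
diameter defaults to 4 mm but is capped at 2·(lesion radius − half
window), keeping the analysis half a window away from the lesion edge
where finite-kernel gradients dominate; at fine sampling (1 mm window)
the cap leaves the 4-mm ROI unchanged, while the desk grid's 2-mm window
yields a 3-mm ROI. `evaluate_experiment` sweeps filter configurations ×
noise realizations and reports CNR plus the bias mean/median/IQR per
image (aggregation across realizations: mean CNR, median/IQR-style
summaries for bias; outliers are retained).

## Problem sizes

The shipped "desk" grid is 0.2 mm isotropic over x ∈ [0, 11.6],
y ∈ [−3, 3], z ∈ [14.6, 27] mm, 10 kHz PRF for 12 ms (upsampled to
50 kHz for estimation), with p = 6 / w = 10 — the same phantom,
excitation, noise and estimator parameters as the full-scale study on a
grid that runs end to end in minutes on one core. The full-scale grid
(0.1 mm, depths 10–30 mm) is provided as `presets.full_scale_grid()` and is
exercised by the same code paths.

## Known limitations

- The generator is kinematic: no diffraction, refraction inside the
  lesion, curvature refocusing, viscoelastic dispersion or speckle
  tracking physics. Passing tests demonstrate the estimator/filter chain
  on fields with correct arrival structure and reflection phenomenology,
  not performance on real tracked ultrasound data.
- After 3-D filtering, the analytic fields' in-lesion estimates are
  nearly noise-free, so the incremental benefit of 4-D filtering on the
  imaging plane is limited to out-of-plane wave rejection; its elevation
  blending of the spherical lesion can slightly widen the in-lesion bias
  spread (at the ~1% level) even as CNR still improves. Fields with
  noise-limited in-lesion signal (as produced by a full elastodynamic
  solver) benefit more from the 4-D filter.
- The quadrant filter assumes a single lateral propagation sense; multi-
  push or compounding sequences would need filter banks, which are out of
  scope.
- Symmetry-plane components are handled by the cancellation gate rather
  than by modeling the sign structure explicitly; `cancel_fraction` is a
  numerical guard (0.25), not a physical parameter.
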