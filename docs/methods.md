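# Methods

`lvmech` estimates subject-specific left-ventricular (LV) material parameters
from one cardiac cycle of cavity pressure and volume, and compares estimates
derived from two emulated imaging modalities.  This note records the model,
its assumptions, the numerical choices, and what the synthetic data do and do
not demonstrate.

## The reduced mechanical model

The full problem this package addresses is classically posed as an inverse
finite-element (FE) problem: a 3D LV mesh with a Fung-type transversely
isotropic passive law and a Guccione-type active-stress law, loaded by cavity
pressure, with material parameters tuned until model pressure-volume behavior
matches measurements.  `lvmech` deliberately replaces the 3D FE state with a
spherically symmetric, exactly incompressible thick wall with circumferential
fibers (f = θ, s = φ, n = r).  This is the package's central modelling
reduction:

- Kinematics: with unloaded radii `Rin < Rout` and deformed inner radius
  `a = (3V/4π)^(1/3)`, volume conservation gives the radial map
  `r(R) = (R³ − Rin³ + a³)^(1/3)`, tangential stretch `λ = r/R`, radial
  stretch `λ⁻²`.  Incompressibility (J = 1) holds exactly by construction,
  so the hydrostatic pressure multiplier of the mixed FE formulation drops
  out of the tangential-minus-radial Cauchy stress differences analytically.
- Constitutive laws: passive `W = (C/2)(e^Q − 1)` with
  `Q = bff·Eff² + bxx(Ess² + Enn² + Esn² + Ens²) + bfx(Efn² + Enf² + Efs² + Esf²)`;
  active fiber PK2 stress `Sa = Tmax·Ca0²/(Ca0² + ECa50(l)²)` with
  `ECa50 = (Ca0)max/√(e^{B(l−l0)} − 1)` and sarcomere length `l = ls0·λ`.
  The printed form of the calcium-sensitivity denominator is typographically
  ambiguous in parts of the literature; the form above is the canonical one
  from the original active-stress law and is isolated in a single function
  (`constitutive.eca50`) so an alternative reading can be swapped in.
- Equilibrium: under transverse isotropy σθθ ≠ σφφ, which breaks exact
  spherical symmetry; the standard thick-shell treatment is used, averaging
  the tangential stresses in the radial equilibrium integral
  `P = ∫_a^b (σθθ + σφφ − 2σrr)/r dr` (the anisotropy error is second
  order).  The integral is evaluated over the reference wall by 32-point
  Gauss–Legendre quadrature; 32- vs 64-point results agree to better than
  1e-4 relative on all tested states (a convergence check is available via
  `cavity_pressure(..., check_quadrature=True)`).

What survives the reduction is the estimation *contract* of the full
problem: cavity pressure is a smooth, strictly increasing function of cavity
volume (passive) and of contractility (fixed volume), which is exactly what
the calibration and estimation stages exploit.  What is lost: regional
heterogeneity, fiber-angle transmural variation, basal/epicardial boundary
conditions, and any deformation measure other than cavity volume.

## Parameter choices

| parameter | default | unit | why |
|---|---|---|---|
| bff, bxx, bfx | 29.9, 13.5, 26.6 | – | literature Fung exponent ratios for ventricular myocardium; a single EDPVR cannot identify four passive parameters, so only C is fitted |
| C (fitted) | init 0.1, bounds 1e-3..200 | kPa | passive stress scale, the fitted passive parameter |
| Ca0, (Ca0)max | 4.35 | µmol/L | canonical active-law constants |
| B | 4.75 | µm⁻¹ | length-sensitivity constant |
| l0, ls0 | 1.58, 1.85 | µm | slack and unloaded sarcomere lengths |
| An, Bn | 28.2, 2.79 | mmHg, – | Klotz single-beat EDPVR normalization constants |
| masking floor | 0.25 | kPa | the relative pressure cost is ill-conditioned near zero pressure (≈1.9 mmHg) |
| convergence threshold | 5% | – | maximum admissible relative pressure error of a fit |
| quadrature | 32 | points | see above |
| mmHg→kPa | 0.1333224 | – | applied in `mechanics` only |

All defaults are configurable and serialized into every fit artifact.

## Calibration and estimation

1. **ED point.**  The end-diastolic sample is the maximum-volume sample of
   the (resampled) waveforms, earliest on ties.  Pressure is linearly
   interpolated onto the volume grid, which is each modality's native
   acquisition grid.
2. **Klotz single-beat EDPVR.**  `V0 = Vm(0.6 − 0.006·Pm)`,
   `V30 = V0 + (Vm − V0)/(Pm/An)^{1/Bn}`,
   `P(V) = An((V−V0)/(V30−V0))^{Bn}` (mmHg).  Inputs with Pm ≥ 100 mmHg are
   rejected (V0 would be non-positive).
3. **Passive calibration with unloading.**  The imaged ED geometry is not
   stress-free; the unloaded wall is recovered by the backward-displacement
   fixed point `Rin ← Rin + ω(a_target − a_model)` (ω = 0.5, tolerance
   1e-5 cm, bracketed root solve as fallback), conserving wall volume
   exactly at every step.  C is then the bounded 1-D minimizer (on log C,
   Brent, relative precision 1e-4) of the summed squared pressure mismatch
   between the model EDPVR and the Klotz curve over 20 volumes spanning
   [Klotz V0, EDV], with the wall re-unloaded inside every objective
   evaluation.  Two numerical choices matter here:
   - the fit grid is anchored at the *target's* zero-pressure volume, not
     the model's unloaded volume.  A grid tied to the moving unloaded state
     collapses toward EDV as C stiffens, where any stiffness matches the
     target trivially — a spurious attractor that makes a naive
     alternating scheme diverge for thin-wall/large-cavity states;
   - a coarse 13-point log-grid bracket precedes the Brent refinement, and a
     minimizer pinned at the C bounds is reported as a convergence failure
     rather than returned.
4. **Contractility estimation.**  At each time point, Tmax minimizes the
   squared relative pressure mismatch `((P − P̃)/P)²`.  Because P̃ is
   strictly increasing in Tmax, the minimizer is found exactly by Brent
   root finding on `P̃(Tmax) − P` with automatic upward bracket doubling
   (start 200 kPa, at most 8 doublings).  Zero is the natural floor: where
   the passive pressure already meets or exceeds the measurement, Tmax = 0
   is returned with the residual.  Points below the masking floor are
   skipped (at most half a cycle may be masked); a fit is *converged* when
   the worst unmasked relative error is below 5%.  Time-to-peak is the
   sample argmax, earliest on ties, without interpolation — relevant when
   comparing a 15-sample grid against a 160-sample grid.

## Surface geometry

Cavity volume of an open imaged surface uses the divergence theorem: the
basal boundary loop (required to lie in the base plane z = 0 within 1e-6 cm)
is closed by a fan cap about its centroid and the enclosed volume is the
signed-tetrahedron sum, positive for cavity-outward orientation; a negative
value signals a flipped mesh.  Wall thickness per AHA-17 segment is the mean
over endocardial vertices of the nearest-point distance to the epicardium
(ray casting along normals was rejected as unstable near the apex);
longitudinal thirds of the base-to-apex extent define the basal/mid/apical
rings, with 60°/60°/90° sectors and the most apical 20% of the apical third
as the apex cap — the apex-cap boundary is a convention of this package.
Sector 1 starts at +x, counterclockwise viewed from the base; the frame is
documented rather than inferred, since imaging frames vary.  Nearest-point
queries use a KD-tree prefilter on triangle centroids with exact
point-triangle distances on the candidate set.

## The synthetic cohort

No imaging data ship with the package; a generator emulates the acquisition
characteristics of a paired 3D-ECHO / cine-MRI swine study with known ground
truth.  Defaults (all configurable, one master seed):

- 7 cases; per case: EDV ~ U(80, 130) mL, EF ~ U(0.42, 0.55), ED pressure
  ~ U(8, 14) mmHg, wall volume ~ U(90, 150) mL, peak Tmax ~ U(40, 120) kPa,
  cycle length ~ U(0.5, 0.7) s.  The EF range reflects anesthetized swine
  (isoflurane depresses contractility) and keeps end-systolic sarcomere
  lengths inside the force-generating range of the active law — at higher
  EF the reduced model's end-systolic volume falls so far below the
  unloaded volume that fibers reach slack length and contractility becomes
  unidentifiable there.
- Volume cycle: piecewise-cosine ejection (first 40% of the cycle),
  end-systolic plateau, cosine filling (last 45%); the dense curve attains
  the configured EDV and EF exactly.
- Contractility truth: `Tmax(t) = peak·sin²(π(t − onset)/duration)` inside
  the activation window, zero outside; the default window spans the whole
  cycle, mirroring fitted contractility waveforms, which are positive
  wherever measured pressure exceeds the passive curve.
- Modality distortions: the MRI-like record samples 15 points/cycle with a
  1 mL volume offset; the ECHO-like record samples 160 points/cycle with
  volume scale 1.006, wall-volume scale 1.091 and a 2 mL offset — the
  systematic wall and EDV differences reported between the modalities in
  paired imaging studies.
- One pressure waveform per case, shared by both modalities (as when a
  separately measured pressure is combined with image-derived volumes), and
  generated by the *forward model itself* from the clean volume curve.

Two design points deserve emphasis:

- **Inverse crime, on purpose.**  The truth is made exactly self-consistent
  with the pipeline: C_true and the unloaded wall come from running the
  same Klotz calibration the pipeline runs (with the ED pressure iterated
  to the fixed point where the recorded value equals the model's own EDPVR
  value at EDV), and pressure is generated by the same forward model the
  estimator inverts.  Recovery tests therefore measure the *pipeline* —
  resampling, calibration, unloading, estimation — not model-form error.
  Consequently, passing them says nothing about how well the reduced model
  represents a real ventricle.  A hook accepts an externally supplied
  pressure CSV for sensitivity studies with a different waveform.
- **Noise is a per-acquisition offset.**  The "volume additive noise sd" is
  realized as one N(0, sd²) draw per case × modality added to the whole
  volume curve, not per-frame white noise: segmentation error within one
  acquisition is dominated by systematic surface-detection bias that is
  strongly correlated across frames.  Frame-level jitter is not modelled;
  one visible consequence is that stroke-volume differences between
  modalities are deterministic given the scale distortions.

## Known limitations

- The reduced wall has no regional information: AHA-17 thickness is
  measured from surfaces but not fed back into the mechanics.
- Ca0 is held at its peak value; all within-beat time dependence is carried
  by Tmax(t), estimated independently per time point (no temporal
  regularization).
- Time-to-peak on a 15-sample grid is quantized to ~40 ms; cohort
  regressions of time-to-peak are discretization-limited by design.
- The generator's waveform shapes are idealized (no respiratory gating,
  valve events, or beat-to-beat variability), and the ECHO-like ESV
  underestimation reported in real paired studies is not separately
  modelled (a single volume scale is applied per modality).

## Problem sizes

The shipped analyses run at desk scale: the default cohort is 7 cases × 2
modalities (about 40 s end-to-end on one core), the recovery study 20 cases
× 2 records, and mesh fixtures use refinement levels 1–3 (up to ~16k
triangles).  All are configuration, not limits of the implementation.
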