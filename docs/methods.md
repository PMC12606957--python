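# Methods

This note records the models, parameter choices and numerical conventions
behind `naear`, and what the synthetic experiments do and do not show.

## Digital phantom

The phantom is parametric solid modelling, not anatomy: a spiral tube for
the cochlea (2.5 turns, base radius 3.2 mm tapering 55%, lumen radius
0.86 mm), an ellipsoid for the vestibule (semi-axes 2.8 × 2.2 × 1.8 mm) and
a 2.5 mm-radius cylinder for the IAM, mirrored about the midline at
±26 mm. At the default 96³ / 1 mm grid the voxelised cochlea is 72 mm³ and
the vestibule 43 mm³ — inside the 63–110 mm³ and 31–59 mm³ ranges produced
by human observers segmenting real ears. Finer cochlear anatomy is
irrelevant at the 2 mm acquisition resolution, where the vestibule spans
about 5 voxels.

**Compartment table** (defaults; mM / ms):

| tissue      | Na⁺  | T1  | T2 | T2* |
|-------------|------|-----|----|-----|
| endolymph   | 1.3  | 60  | 55 | 50  |
| perilymph   | 145  | 60  | 55 | 50  |
| CSF (IAM)   | 145  | 60  | 55 | 50  |
| brain       | 40   | 35  | 20 | 4   |
| bone        | 0    | 20  | 2  | 0.5 |

Sodium relaxation times for inner-ear fluid are not established; the fluid
values are declared assumptions (free-fluid-like, so that fluid T2* ≫ the
2 ms readout while solid-tissue T2* ≪ it), not fits. The perilymph value
145 mM is the midpoint of the 141–148 mM physiological range.

**Hydrops model.** `hydrops_fraction` (per side, default 0.2 per ear for a
normal ear) is the fraction of each structure's fluid voxels assigned to
endolymph, chosen innermost-first by distance from the structure core. The
total fluid voxel count of an ear is therefore exactly independent of the
fraction — hydrops is replacement, not growth — and fraction 1.0 reproduces
complete replacement of the inner-ear fluid by endolymph.

**Off-resonance.** A low-order random polynomial (seeded) scaled to 70% of
the amplitude bound plus a Gaussian-blurred perturbation at bone–fluid
interfaces, clipped to ±150 Hz by default. With TR 14.26 ms the band period
is 70 Hz, so this span produces several visible bands inside the
−100…+200 Hz reconstruction sweep.

## Acquisition model

`bssfp_signal` folds the RF phase increment into an effective per-TR
precession angle θ = 2πf·TR − Δφ and solves the 3×3 steady-state fixed
point of pulse rotation + precession/relaxation exactly (batched linear
solve). The test suite pins it against an independent brute-force Bloch
iteration (800 TRs) to < 1% at band centre and passband. One convention is
worth noting: the off-resonance phase at the echo is taken from the
*principal value* of θ scaled by TE/TR, rather than the raw physical
2πf·TE. This makes the complex signal exactly periodic in off-resonance
with period 1/TR (magnitudes are identical either way); the branch jump
sits at the band centre where the signal phase flips anyway.

Trajectories: Cartesian (full grid, timestamps 0 — the oracle path), radial
(Fibonacci-sphere spokes, analytic |k|² density weights) and cones (polar
angles uniform in cos θ, Archimedean spiral-out per cone, sample spacing
uniform in time over the 2 ms readout). Density compensation for cones uses
the Pipe–Menon fixed point w ← w / C(Cᵀw) evaluated with the gridding
kernel; it was chosen over 3D Voronoi volumes because it is fast, robust
for tens of thousands of samples, and needs no outer-boundary capping. All
weights are normalised to sum to 1 so the Cartesian adjoint coincides with
the inverse DFT. The number of readouts per cycle is a free parameter;
`Trajectory.time_per_cycle_min` reports readouts × TR for comparison with
protocol timings.

The forward model applies per-voxel readout-time evolution —
exp(−t/T2*)·exp(i2π·Δf·t) at each sample timestamp — by time segmentation
(8 bins by default; exact whenever timestamps are constant, e.g.
Cartesian). Noise is i.i.d. complex Gaussian per sample (`noise_sd` is the
SD of each of the real and imaginary parts), from a single uniform receive
coil.

## NUFFT

`naear.nufft` implements type-1/type-2 transforms with Kaiser-Bessel
gridding: 2× oversampling, kernel width 6, Beatty shape parameter, and a
deapodisation computed as the inverse DFT of the sampled kernel itself (so
it is exact for the discrete operator; measured accuracy ~2·10⁻⁵ relative
against a direct DFT). Coordinates that fall on the grid lattice take an
exact FFT path, which is what the 10⁻⁸ Cartesian oracle tests exercise.
Image voxels sit at (index − n//2)·voxel mm; k-space is in cycles/mm.

## Reconstruction

Per offset: demodulate samples by exp(−i2π·offset·t) using their
timestamps (readout-time evolution is what blurs off-resonant voxels, so
demodulation must act in k-space, not as an image phase), reconstruct each
cycle (adjoint NUFFT, or CG on the density-weight-preconditioned normal
equations, tolerance 10⁻⁶, max 20 iterations, warning on non-convergence),
combine F-states over orders {−1, 0, +1} with no 1/N normalisation, and
take the root sum of squares. F-states are computed per offset and then
composited; the order of those two operations is a fixed documented choice.
The sweep stack is [X, Y, Z, offset], ascending Hz, RAS+ affine.

Offset selection offers the reader's manual mode and an automated
sharpness mode: sum of squared central-difference gradients in the ROI
divided by the squared ROI mean (gain-invariant), ties broken toward the
lowest offset index.

`psf_probe` reconstructs a unit point source with readout T2* decay and
interpolates the FWHM of the central profile. With an ideal trajectory and
long T2* this returns the 2 mm nominal voxel; readout-scale T2* broadens
it beyond 2 mm. The absolute broadened width depends on the (unpublished)
tissue T2* and exact cones parameters, so only the direction and
monotonicity are asserted, never a value.

## Registration

Interpolating 3D thin-plate spline (kernel |r|, full degree-1 polynomial
tail, zero smoothing) fit by the standard bordered linear system; the
transform maps fixed (structural) world coordinates to moving (sodium)
sample locations, i.e. pull-back resampling. Duplicate or coplanar
landmarks raise named errors. 9–16 pairs is the intended operating range
(warning outside). Intensities are resampled linearly — the viewer
interpolation of the original workflow is unstated, linear is assumed —
and labels nearest-neighbour. Mask transfer inverts the transform
numerically (exact for the affine part, fixed-point refinement for the
nonrigid part) and reports voxel counts and mm³ before/after.

## Quantification

Medians of even-sized ROIs are midpoints; SD is the population form.
Ratios and summary means are rounded half-up at 1 decimal to match
printed-table conventions. `between_ear_ratio` averages the observers per
ear first, then divides (normal : hydropic, the caller saying which side
is the reference): which ear is "normal" is an *input* label when
reproducing observer tables and an *output* when analysing simulations,
and the two roles are kept in separate code paths.

The laterality rule references each inner-ear structure's visibility to
the ipsilateral IAM fundus, and requires anatomical compatibility ≥ 2 on
the better-seen side only; a relative-visibility gap of ≥ 2 points is
definite, exactly 1 is possible. Eligible structures pointing at opposite
sides with equal strength return "none" (conservative; the case never
occurs in the bundled tables). This gate reproduces all 16 bundled calls.

ICC is the two-way random-effects absolute-agreement form from the ANOVA
mean-squares decomposition, with single- and average-measures variants
both exposed (the form used for the published 0.70 is unnamed; on the
printed 1-dp medians the average-measures form gives 0.689 and the
single-measures 0.526, so the average form is the one that matches within
rounding — documented, not silently chosen). Zero-variance input returns
1.0 with a warning. The IAM-scaled ratio column cannot be recovered
exactly from rounded per-observer scaled values; it is reported but not
asserted. The ICC confidence interval is out of scope.

`grade_visibility_auto` closes the simulation loop with a deterministic
stand-in for visual grading: grade 0 below the noise floor (background
mean + 2 SD), then 1/2/3 by ROI-to-reference median ratio bands < 0.8 /
0.8–1.25 / > 1.25, mirroring the decreased/similar/increased wording of
the visual scale. It is a convenience for synthetic experiments, not a
model of human readers.

## Pipeline and seeding

One global seed expands to per-stage substreams via
`SeedSequence([seed, stage_index])` (first state word, mod 2³¹), so stages
rerun independently and deterministically; every stage writes a JSON
provenance sidecar (config SHA-256, stage seed, package version). Configs
are YAML with strict keys — unknown keys are errors.

## Synthetic-experiment sizes and what they show

The simulation-based tests run at reduced sizes chosen as this package's
standard study conditions: banding slabs at 32³ / 2 mm; end-to-end hydrops
recovery on 64³ / 1.5 mm truth phantoms sampled by a 2 mm cones
acquisition (1000 readouts × 40 samples) and reconstructed at 48³ —
preserving the truth-vs-acquisition resolution split of the full-size
default (96³ / 1 mm truth, 2 mm acquisition). Noise is calibrated at run
time so the normal-ear ROI SNR is ≈ 5 (SNR = noise-free ROI median over
the ROI mean of a noise-only composite at the same noise level).

Passing these tests shows that the pipeline's physics and statistics are
self-consistent: banding is suppressed by the composite, the sweep finds a
uniform phantom's true off-resonance, and severe synthetic hydrops
(fractions ≥ 0.7) lowers the affected ear's median composite signal
reliably at moderate SNR. It does **not** show that real hydropic ears are
detectable at 7 T: the phantom has no motion, no coil-sensitivity
structure, a single-compartment mono-exponential T2* per tissue, idealised
geometry, and a hydrops model in which endolymph sodium stays at 1.3 mM —
an assumption the one known negative participant pattern (a hydropic ear
without signal asymmetry) may specifically violate.

## Known limitations

- No multi-coil/parallel-imaging model; CG-SENSE reduces to CG-NUFFT with
  a uniform coil.
- Gridding accuracy (~10⁻⁵) bounds CG's useful tolerance on non-Cartesian
  data.
- The TPS inverse is iterative for nonrigid warps; extreme deformations
  could fail to converge (not reachable with landmark counts ≤ 16 and
  smooth warps).
- The automated visibility grader's compatibility grade is trivially 3 for
  synthetic masks; compatibility-driven behaviour of the laterality rule
  is exercised only through tabulated observer grades.
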