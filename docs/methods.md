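# Methods

`fdhddot` simulates the image quality of frequency-domain high-density
diffuse optical tomography (FD-HD-DOT) as a function of source modulation
frequency. This note records the model, the numerical choices, what the
synthetic phantom does and does not emulate, and the known limitations.

## Physical model

Light transport is modeled by the frequency-domain photon diffusion
equation on a voxel grid,

    div(D grad Phi) - v mua Phi + i omega Phi = -v Q,
    D = v / (3 (mua + musp)),    omega = 2 pi f,

with `Phi` the complex photon fluence rate, `v = c0 / n` the speed of light
in tissue, and a unit-amplitude monochromatic point source `Q`. Units are
mm and ns throughout; frequencies are entered in MHz (`omega` in rad/ns),
`c0 = 299.792458` mm/ns. Continuous wave (CW) is `f = 0` through the same
code path; the solution is then real and phase quantities are dropped.

Choices the underlying physics leaves open, and their defaults:

- **Refractive index** `n = 1.4` for every tissue (configurable); air 1.0.
- **Boundary condition**: Robin (partial-current) on air-facing faces with
  the internal-reflection parameter from the Groenhuis polynomial fit,
  `A(n = 1.4) ≈ 3.25`.
- **Source model**: isotropic point source one transport length `1/musp`
  beneath the optode position, snapped to the nearest voxel center.

## Phantom and measurement geometry

The five MRI-derived subject head meshes of the original study design are
replaced by a flat five-layer slab — scalp, skull, CSF, gray matter, white
matter — because a slab preserves the depth structure that drives every
image-quality metric while keeping a regular grid for the solver. Default
thicknesses are scalp 4, skull 7, CSF 2, gray 4 mm (white fills the rest of
a 120 × 120 × 60 mm volume at 2 mm voxels); subject-specific thicknesses
are not published, so these are a stated choice. Voxels are assigned to
layers by voxel-center depth, so the realized skull layer is 6 mm at 2 mm
voxels. Depth is measured from the voxel center to the air interface plane
(`(k + 0.5) h`), the convention in which the first gray-matter voxel of the
default stack sits at 13 mm.

Baseline optical properties per tissue and wavelength (690/850 nm) are the
standard literature values (e.g. scalp 690 nm: mua 0.0159, musp 0.8000
mm^-1; CSF musp 0.3000 mm^-1 at both wavelengths).

Optodes interleave on a checkerboard lattice: 13 mm pitch is the unique
regular lattice reproducing the four nearest-neighbor (NN) separations
p, p√5, 3p, p√13 = 13.00, 29.07, 39.00, 46.87 mm of a high-density grid.
The desk-scale default is a 7 × 7 footprint (25 + 24 optodes; the full
study used 324). Channels are classified by separation windows of ±1 mm
around the nominal NN separations; the NN3 and NN4 sets are cumulative and
proxy moderate and strong system dynamic range.

The evaluation region of interest (ROI) is the optode footprint shrunk
laterally by 10 mm (edge effects) intersected with voxels whose summed CW
intensity sensitivity exceeds 1e-5 of its maximum (the optically accessible
depth; ≈33 mm in the default slab).

## Forward solver

The operator is discretized with second-order finite volumes: harmonic-mean
face diffusivities at tissue interfaces, Robin conductances on air faces.
Two code paths solve the identical discrete system:

- a general sparse path (SuperLU, factorization reused across sources) for
  arbitrary labeled phantoms — used by the oracles and small problems;
- a layered-slab fast path that diagonalizes the lateral axes by 2-D FFT
  (periodic lateral boundary) and solves one tridiagonal system in depth
  per lateral mode; one kernel solve yields every optode's field by lateral
  translation. The two paths agree to 1e-10 on slabs with periodic lateral
  boundaries, and the lateral wrap-around is O(1e-5) relative at the
  default extent.

Validation is against closed forms, not another solver: the infinite-medium
Green's function `Phi = v exp(-k r) / (4 pi D r)`,
`k = sqrt((v mua - i omega)/D)` (positive real part), and the semi-infinite
image-source construction with extrapolation length `z_b = 2 A / (3 (mua +
musp))`. Discrete dispersion scales as `(kh)^2`: at 2 mm voxels and
800 MHz the phase error over 35 mm is ≈9°, at 0.8 mm ≈1.4°, so the oracle
comparisons run at 0.8 mm voxels where the solver is well inside the 5%
amplitude / 2° phase tolerance. The 2 mm sweep grid is internally
consistent (the same discrete model generates and inverts the data), so
image-quality metrics are unaffected by the absolute dispersion error.

## Sensitivity (Rytov Jacobian)

Differential data are the complex log of the perturbed over baseline
fluence at the detector; real part = log-amplitude, imaginary part = phase
(wrapped to (-pi, pi]). The derivative with respect to a voxel absorption
change is assembled in the adjoint form

    dln(Phi_s(r_d))/dmua_j = -v_j Phi_s(r_j) Phi_d(r_j) h^3
                              / (v_d Phi_s(r_d)),

with `Phi_d` the detector-launched field — the only tractable route to
~1e4–1e5 voxel columns. The "measurement" is the fluence at the detector's
injection voxel, which makes the adjoint identity exact on the discrete
system; a brute-force single-voxel perturbation oracle confirms entries to
≲0.1% (well inside the 1% contract). Scattering-change columns are
excluded (differential scattering is taken as zero). CW Jacobians drop
phase rows rather than carrying zeros. Phase rows are stored in radians;
noise in degrees is converted at injection.

## Inversion

Per wavelength and channel set, the reconstruction operator is a Tikhonov-
regularized pseudo-inverse with a spatially variant column scaling `L`:

    A# = L^-1 (Ahat^T Ahat + lambda1 I)^-1 Ahat^T,    Ahat = A L^-1,

evaluated in measurement space via the push-through identity
`(Ahat^T Ahat + l I)^-1 Ahat^T = Ahat^T (Ahat Ahat^T + l I)^-1` (verified
entrywise to 1e-8 against the dense voxel-space form on small systems).
`lambda1` is 0.01 × the maximum singular value of `Ahat^T Ahat` (power
iteration, tolerance 1e-6, fixed-seed start); `lambda2_rel` is 0.1.

Two readings of `L` are implemented. The default is the standard spatially
variant form `diag(L) = sqrt(diag(A^T A) + lambda2_rel · max diag)`, which
caps the depth compensation at `sqrt(1 + 1/lambda2_rel) ≈ 3.3×`. The
alternative `diag(L) = diag(A^T A) + lambda2^2` with `lambda2 = 0.1
sigma_max(A^T A)` is dimensionally inhomogeneous: at realistic sensitivity
scales its constant term dominates the diagonal by ~80×, making `L`
essentially uniform — the spatial compensation the parameter exists to
provide disappears, and deep localization at high modulation frequency
degrades (median noise-free LE over 13–25 mm seeds: 9.8 → 7.9 → 18.0 mm
for 0/400/800 MHz, versus 9.1 → 7.1 → 6.6 mm with the sqrt form). The
sqrt form is therefore the default; the literal diagonal form remains a
config switch for sensitivity analysis. Wavelengths are inverted
independently; intensity and phase rows enter one joint operator.

## Spectroscopy

Hemoglobin perturbations (default +3.8 uM HbO2, −1.8 uM HbR) convert to
absorption perturbations through a 2 × 2 extinction matrix in mm^-1 uM^-1.
The embedded values derive from the Prahl/OMLC compilation (base-10
cm^-1 M^-1 × ln10 × 1e-7): HbO2 6.355e-5 / 2.436e-4, HbR 4.725e-4 /
1.592e-4 at 690 / 850 nm. They are configuration, not ground truth —
localization and width metrics are computed on the HbO2 volume's shape,
not its scale. Analyses gate on HbO2; HbR volumes are computed and
exportable but not gated.

## Noise model

Measurement noise standard deviation follows the empirical two-term
exponential in separation with a power-of-ten frequency factor,

    N(r, f) = (a e^{br} + c e^{dr}) · 10^{g (f - 140)},

with separate coefficient sets per wavelength and datum type (intensity in
percent, phase in degrees), normalized to the 140 MHz frequency at which
the distance model was measured. Injection: one standard-normal draw per
channel scales both components (matched random numbers — the strongest
reading of coupled noise; independent draws available by config); percent
becomes additive log-amplitude noise via the small-noise equivalence
(σ/100), degrees become radians. Zero-mean, strictly increasing in r and f.
Noise is redrawn per (seed voxel, frequency, wavelength, realization) with
the documented seed rule `SeedSequence((master_seed, voxel_id, f, λ,
realization))`.

A `noise_scale` factor (default 1.0) multiplies both standard deviations at
injection; it represents effective datum averaging (the model describes a
single measurement sample, while a differential activation datum is an
average over a recording block) and exists for the sensitivity analysis
described under Limitations.

## Metrics and sweep protocol

A point-spread function (PSF) is the reconstructed image of one seed-voxel
perturbation: hemoglobin → absorption → forward data (+ optional noise) →
reconstruction per wavelength → hemoglobin. The PSF is thresholded at half
its (positive) maximum with no connected-component filtering; metrics are

- **LE**: distance from the true perturbation to the value-weighted
  centroid of the thresholded set (unweighted mode available);
- **FWHM**: longest pairwise distance between thresholded voxel centers
  (computed on the convex hull for large sets; identical to the O(n²)
  scan);
- **FVHM**: thresholded voxel count × voxel volume;
- FWHM/FVHM are recorded only when LE ≤ 8 mm; the success **rate** per
  1 mm depth bin uses the strict `LE < 8 mm` reading, and the SR50 depth is
  the first 50% crossing, linearly interpolated between populated bins;
- **FBTV / FBT ratio**: successfully recovered brain-voxel volume per
  frequency and LE cutoff (1–8 mm), and its ratio to the CW value.

The default sweep covers 0–1000 MHz in 100 MHz steps, NN3 and NN4,
noise-free and noise-added arms. Seeds are a 5 × 5 lateral patch of depth
columns (4 mm spacing) around the array center × all ROI depths (≈425
seeds); the noise arm draws 3 realizations per seed, and the noise-arm SR50
is the mean of per-realization SR50 depths — the single-phantom analogue of
averaging across subject head models. Everything is deterministic under the
master seed, and reductions are keyed, so results are independent of
execution order. The full default sweep runs in a few minutes on one CPU.

## What the phantom does and does not emulate

The slab preserves layered optics, the depth-dependent sensitivity
fall-off, the multi-distance overlapping measurement topology, and the
noise structure — the ingredients of the frequency trade-off. It does not
emulate curvature, gyri/sulci, spatially varying layer thickness,
subject anatomy, or cross-subject averaging; absolute depths (e.g. the
SR50 boundary) are therefore not comparable to subject-derived values, and
passing tests support claims about the *trade-off structure*, not about
absolute imaging depth in humans.

## Limitations and findings of the desk-scale study

- **Noise-free behavior** reproduces the expected structure: localization
  improves markedly with modulation frequency (median LE over 13–25 mm
  seeds 9.1 → 7.1 → 6.6 mm at 0/400/800 MHz, NN3), resolution improves
  only modestly, NN4 ≥ NN3 everywhere, and the reliable boundary deepens
  with frequency — up to a turnover at 700–800 MHz (NN4: 18 → 24 mm). The
  turnover is physical: the photon-density-wave attenuation grows with
  omega, shrinking deep phase sensitivity; where it lands depends on
  geometry and optical properties, and in this slab it falls inside the
  examined band rather than at its top.
- **Noise-added behavior**: with the noise model taken at face value per
  single datum, a single-voxel 3.8 uM perturbation is far below the noise
  floor of this 49-optode system (best per-channel SNR ≈ 0.04 at 3 mm
  depth; reconstructed noise exceeds the clean PSF peak 30–100× at all
  depths), so the noise-added success boundary collapses to the shallowest
  depths and the apparent optimum frequency is dominated by the random
  draws. A sensitivity analysis over `noise_scale` shows no scale at which
  this system exhibits both a meaningful boundary depth and an interior
  optimum: at scales giving graceful degradation the boundary decreases
  monotonically with frequency (CW best), because the desk-scale phase
  benefit (+2–6 mm noise-free) is smaller than the phase-noise burden.
  The interior-optimum regime evidently requires the channel count of the
  full-scale system. The noise model itself, its sampling, coupling and
  units are all verified against closed forms.
- The skull layer realizes 6 mm (not 7) at 2 mm voxels; layer assignment
  is by voxel center.
- The literal diagonal regularization form is retained only as a switch
  (see Inversion).
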