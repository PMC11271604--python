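# Methods

`cdbsi` implements a cervix-optimized diffusion basis spectrum imaging (DBSI)
pipeline: a multi-tensor signal model whose basis is motivated by Monte-Carlo
simulation of water diffusion in the cervical microstructure, a per-voxel
nonnegative inversion of that model, synthetic phantoms for round-trip
validation, histology density-map analytics, and cohort-level statistics.
This note records the model assumptions, the tunable parameters and their
defaults, the numerical choices made where the design was open, and the known
limitations.

## Signal model

The diffusion-weighted signal of voxel k-th measurement (b-value b, unit
encoding direction g) is modeled as a nonnegative linear combination of
axially symmetric anisotropic tensors and isotropic tensors:

    S(b, g) / S0 = sum_i f_i exp(-b rd_i) exp(-b (ad_i - rd_i) cos^2 psi_i)
                 + sum_j f_j exp(-b D_j),        f >= 0,

with psi_i the angle between g and the i-th anisotropic tensor's principal
direction.  Units: b in s/mm^2, diffusivities in 1e-3 mm^2/s; exponents are
computed as -(b/1000) D.

The default basis has 375 atoms at the 37 degC reference:

* **150 isotropic atoms** on the uniform grid 0.0-14.9 (step 0.1), split into
  four physiological bands (half-open on the low side): restricted /
  intracellular [0, 0.6), hindered [0.6, 3), free [3, 10), IVIM
  (perfusion-like pseudo-diffusion) >= 10.  The uniform 0.1 step is the
  simplest grid that yields 150 atoms while covering all four bands and
  capping the IVIM band; it places 6 atoms in the restricted band.
* **9 anisotropic (ad, rd) models x 25 directions = 225 anisotropic atoms.**
  Models #2-#3 (ad 1.8-2.0, rd 0.3-0.4) represent muscle fibers, #5-#7
  (ad 1.6-2.1, rd 0.5-0.7) collagen fiber bundles, and the remaining models
  other connective tissue.  Only the muscle/collagen ranges are pinned by the
  tissue working points; the default (ad, rd) values tile those ranges and
  are config-overridable.

Directions are distributed by minimizing the Coulomb energy of antipodal
charge pairs on the sphere (diffusion encoding is sign-invariant) with
multi-restart L-BFGS from a seeded generator; the test suite checks the
25-direction layout against an independent 50-restart projected-gradient
search (energy within 1%).

**Temperature.** Band edges and atom diffusivities are defined at 37 degC and
the whole dictionary scales multiplicatively, so no atom changes compartment
under temperature scaling.  The 37 -> 20 degC coefficient for ex vivo work is
derived from a quadratic least-squares fit of a packaged table of published
water self-diffusion measurements (PGSE NMR values after Holz et al. 2000 and
Easteal et al.; the 25 degC entry is the 2.299e-9 m^2/s benchmark), giving
D(20)/D(37) ~ 0.666.

## Monte-Carlo simulator

Walkers take fixed-length steps l = sqrt(6 D dt) (dt = 1 ms) in uniformly
random 3D directions; impermeable boundaries reflect specularly, with up to
32 bounces resolved per step (the residual sub-step is dropped afterwards — a
vanishingly rare event at the default step sizes).  Phase is accrued along
ideal rectangular bipolar PGSE lobes sampled on the step grid,
phi_j = gamma sum_t G(t) (r_j(t) . g) dt, and the normalized signal is
S = mean_j cos(phi_j).  The gradient amplitude for a requested b-value is set
from the *discrete* quadrature (sum over waveform samples of the random-walk
position covariance), so free diffusion reproduces exp(-b D) exactly up to
Monte-Carlo error; b = 0 rows are exactly 1.

Ensembles are sized at 10 walkers/um^3 of substrate free volume with an
absolute floor of 10^4 walkers for signal synthesis.

Three substrates model the microstructure:

* **Sphere** (cells, radii 5-12 um): walkers inside a reflecting sphere.
  Convexity makes endpoint checks sufficient for collision detection.
* **Crossing solid rods** (collagen): walkers in the pore space of rods packed
  in slabs stacked along y; within a slab rods are parallel, tilted in the
  x-z plane by the slab's angle from the cycle (-10, 0, +10) deg, so slab
  pairs cross at 0-20 deg.  Segment-cylinder intersection (continuous
  collision detection over the nearby slabs/rods) prevents tunneling through
  rods thinner than a step.
* **Parallel hollow tubes** (muscle): walkers inside an infinite reflecting
  cylinder; tubes don't exchange water, so one tube represents the bundle.
  Axial motion is free, hence the tube's axial diffusivity equals the
  intrinsic diffusivity — which is why the fiber substrates carry intrinsic
  diffusivities below free water (intracellular/interstitial water is slower
  than free water).

**Calibrated frozen parameters.** The tissue literature does not pin the PGSE
timing, rod radius/spacing, tube calibre, or intrinsic diffusivity inside
fibers.  These were calibrated once against the substrate working points
(sphere ADC endpoints 0.089 / 0.612; collagen AD/RD 1.371 / 0.357; muscle
AD/RD 1.622 / 0.537, all 1e-3 mm^2/s) and frozen:

| parameter | frozen value | note |
|---|---|---|
| PGSE delta / Delta | 1 / 53 ms | near-narrow pulses on the 1 ms grid; t_d = Delta - delta/3 ~ 52.7 ms keeps the small-radius closed form R^2/(5 t_d) valid within ~2% |
| sphere intrinsic D | 3.0 | free-water value at 37 degC |
| rod radius / spacing / slab height | 1.0 / 2.3 / 2.0 um | water fraction ~0.40, tightly packed |
| rod substrate intrinsic D | 1.45 | interstitial water |
| tube inner radius | 10.8 um | smooth-muscle fiber calibre (~20 um diameter) |
| tube intrinsic D | 1.69 | intracellular water; the single-tensor fit over b <= 2000 reads ~4% below it because the restricted transverse decay is non-monoexponential |

Across seeds the frozen configurations give rods AD 1.36-1.43 / RD
0.352-0.371 and tubes AD 1.62-1.67 / RD 0.539-0.548, inside the +-1 SD
working bands above.

Single-tensor analysis is a log-linear least-squares tensor fit over all
usable measurements; AD is the largest eigenvalue, RD the mean of the two
minor ones, ADC the eigenvalue mean.

## Acquisition scheme

The default protocol is 2 b=0 measurements plus 6 shells (b = 250, 500, 750,
1000, 1500, 2000 s/mm^2) x 12 repulsion-uniform directions = 74 measurements,
mirroring a 74-direction in vivo protocol with b up to 2000 s/mm^2.  FSL
`bval`/`bvec` text files are read and written directly.

## Spectrum inversion and fraction maps

`fit_voxel` normalizes each voxel by its mean b=0 signal and solves the
nonnegative least-squares problem against the 375-atom design matrix, with an
optional mild ridge term lambda = reg * tr(A'A)/(n_atoms K), reg = 0.01 by
default (reg = 0 gives the plain active-set NNLS solution, which the tests
verify against exhaustive support enumeration on small problems).

The raw spectrum is **non-unique**: the scheme has only 7 distinct b-shells
against 150 isotropic atoms, so exact alternative representations exist (a
free-water peak at D = 3.0 re-expressed on hindered-band atoms at machine
precision), and band fractions read directly off the spectrum are arbitrary
precisely at band edges.  Default fraction maps therefore come from a
two-stage fit:

1. **Spectrum scan** — the full NNLS inversion above; its anisotropic weights
   give the dominant fiber direction (principal eigenvector of the
   weight-weighted dyadic sum of atom directions).
2. **Reduced compartment refit** — NNLS on a compact basis with *fixed*
   band-representative diffusivities (cell 0.30, hindered 1.50, free 3.00,
   IVIM 12.0) plus one muscle (1.8, 0.3) and one collagen (1.8, 0.6) column
   oriented along the stage-1 direction.  Fixing compartment diffusivities is
   the standard cure in compartment imaging models; on this small basis the
   problem is well-posed and noiseless round-trips are exact to < 0.003.

`fit_volume(refine=False)` skips stage 2 and reports spectrum band sums
directly.  Non-muscle/collagen anisotropic weight reports as a separate
`other_fiber` channel by default; a switch folds it into hindered for
six-channel output.  Fractions are normalized to unit sum per voxel; voxels
without a positive b=0 signal or with an all-zero spectrum are flagged absent.
Magnitude (Rician) signals are used as-is: at the SNRs of interest the
rectification bias on fractions is small compared with the noise scatter
(verified on phantoms against a moment-based correction), so no bias
correction is applied by default.

**Noise floor.** With 74 measurements at b <= 2000 and SNR 50, the
muscle / collagen / hindered signatures are 0.90-0.96 correlated and the
unconstrained per-voxel standard error of their fractions is ~0.1-0.17;
per-voxel fraction maps at clinical SNR are intrinsically noisy, and the
pipeline's group-level summaries (median of nonzero voxel values per volume)
are the intended operating point.

## Phantoms

`make_cervix_phantom` builds a 24 x 24 x 8 voxel grid (3 mm isotropic, about
2000 tissue voxels) with concentric zones around a central canal void:
subglandular (high cell/collagen) and outer stroma (lower).  The "term"
preset has whole-volume median cell fraction < 5% and collagen 10-15%; the
"preterm" preset has elevated cell fraction with a few 10% hot spots,
collagen < 5%, and higher muscle and free-water fractions.  Fiber directions
are circumferential around the canal.  Signals come from the forward model
with the nearest in-band dictionary atom per compartment (targets default to
the canonical representatives; off-grid overrides probe model mismatch) and
Rician noise sqrt((S + n1)^2 + n2^2), n ~ N(0, s0/snr); the default SNR of 50
is a plausible clinical b0 SNR.  What phantom round-trips demonstrate:
the inversion recovers the generating compartments when the data follow the
model.  What they do not demonstrate: robustness to real-tissue features —
off-model diffusivities, partial voluming, orientation dispersion within a
voxel, motion, or spatially correlated noise.

## Histology analytics

Binary positive-stain masks (classification and registration are upstream and
out of scope) become density maps by non-overlapping window tiling (default
50 x 50 pixels), each cell 100 x positive / pixel count with partial edge
windows using their actual counts.  Downsampling is a pixel-count-weighted
block mean (exact area preservation at integer factors).  Grid correlation
tiles the shared physical frame with 2.5 mm boxes anchored at the origin
(no sub-box offset search), drops boxes with < 50% contour coverage
(configurable), and reports two-sided Pearson r over paired box means.  An
HSV-threshold helper for trichrome blue/scarlet is provided as a convenience
and is not equivalent to a trained chromatic classifier.

## Cohort statistics

Per-subject summaries are medians of nonzero voxel values over the cervical
volume.  Group comparisons use pooled-variance two-sample t-tests (Welch
optional) with one- or two-sided p-values; correlations are two-sided
Pearson.  Group ellipsoids in cell x collagen x muscle space are sample
mean/covariance surfaces at Mahalanobis distance 2; disjointness is decided
numerically by minimizing each ellipsoid's Mahalanobis distance over the
other's surface (multi-start Nelder-Mead, tolerance 1e-6), with a
center-containment guard, returning the signed clearance.  The synthetic
cohort generator draws 10 term + 7 preterm subjects around group-median
working points whose ratios are preterm/term cell ~1.94, muscle ~1.46, free
~1.36 and term/preterm collagen ~1.65, with 10% relative within-group spread —
a deliberately clean surrogate for patient data.

## Known limitations

* No membrane permeability, water exchange, T2 weighting, or susceptibility
  effects in the simulator; gradient lobes are ideal rectangles on the step
  grid.
* One dominant fiber direction per voxel in the refined fit; crossing-fiber
  voxels fold into a single orientation.
* Per-voxel fraction estimates at SNR <= 50 carry ~0.05-0.15 noise scatter in
  the collinear compartments (see noise floor above).
* The histology helpers assume upstream registration; no stain normalization
  or whole-slide IO.
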