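# Methods

`chippet` models a table-top PET scanner for organ-on-chip (OOC) imaging:
four box detectors around a 52.2 mm square bore, each holding two
monolithic LYSO crystals (52 x 13-or-26 x 52 mm) in a 0.1 mm epoxy
envelope, read out by SiPM arrays on five of the six surfaces (the
bore-facing front is bare).  Position estimation inside the monolithic
blocks — rather than crystal pixelation — sets the spatial resolution,
which is the property of interest for imaging sub-millimetre OOC
structures.  This note records the model, its assumptions, the scaled
problem sizes, and what the package's synthetic results do and do not say
about a physical scanner.

## Scanner geometry

Detector placement is a closed square bore: the four front faces sit at
radial distance 26.1 mm and tile the bore completely, so every transaxial
ray from the axis enters exactly one detector.  SiPM channels are laid on
a pitch of 1.0875 x the nominal photosensitive size (3.2625 / 4.35 /
6.525 mm for the 3 / 4 / 6 mm devices); the channel count per axis is
floor(length / pitch), which reproduces the published per-surface counts
of the 26.1 mm detector (back 16x32, left/right 8x32, top/bottom 16x8 for
3 mm SiPMs; five-surface totals 1280 / 720 / 320).  For the 13.1 mm
detector the same rule gives 4 / 3 / 2 channels across the thickness.
Detector-local coordinates are x tangential in [0, 52.2], y the depth
with y = 0 at the bore face, z axial in [0, 104.4] (all mm).

## Phantoms

Four emission models, all inside a PMMA chip (10 x 26 x 76 mm) whose
water interior is 4 mm shorter per side:

* `box` — uniform emission in the 6 x 22 x 72 mm water volume (1000 Bq);
  the training-data phantom.
* `line` — 104 mm water cylinder, 1 mm thick, on the z axis (1000 Bq);
  the sensitivity phantom.
* `grid21` — 21 point sources, 7 (z) x 3 (y), 10 mm spacing, sharing
  1000 Bq; the resolution phantom.
* `ooc_spheres` — four hot spheres (r = 0.4/0.5/0.6/0.7 mm at
  1000 Bq/mm^3) each centred in a cold r = 2 mm sphere (100 Bq/mm^3).
  The cold activity integrates over the full 2 mm sphere (the hot core
  adds on top of the background), giving a 16,537 Bq total.  The axial
  spacing of the four units is 19 mm, chosen so they sit comfortably
  inside the 72 mm water box; the published description distributes them
  "along z" without a number.

Decays form a homogeneous Poisson process at the phantom activity
(radioactive decay of the F-18 inventory is neglected over the <= 10 s
runs).  Randomness everywhere derives from named substreams fanned out of
one master seed (decay / transport / optics / training), so stages can be
re-run independently and bit-identically.

## Gamma transport

A deliberately analytic stand-in for particle-physics Monte Carlo:

* positron range: isotropic displacement with exponential magnitude,
  mean 0.6 mm (F-18 in water); toggleable;
* acollinearity: 0.25 degrees FWHM Gaussian jitter on the opening angle;
  toggleable;
* phantom attenuation: Beer-Lambert survival through the convex
  water/PMMA structures (mu = 0.096 / 0.112 per cm at 511 keV);
* crystal interaction: the chord of the ray through each LYSO box is
  accumulated in order and an exponential free path at
  mu_LYSO = 0.87 /cm decides whether and where the gamma converts.  The
  full 511 keV is deposited at that single site.

The single-site approximation is the model's main bias.  In a full
simulation ~2/3 of 511 keV interactions in LYSO are Compton scatters
whose secondaries can escape one detector and convert in another; a
coincidence counter that asks only for "interactions in two different
detectors" then counts events that this model cannot produce.
Consequently the simulated line-source sensitivity — 25% for 13 mm
crystals, 36% for 26 mm (10,000 decays) — sits below published
full-physics values (34.81% / 40.68%), and the thickness ratio is closer
to the pure-attenuation prediction.  The 13 mm number cannot reach the
published one under this model without an unphysical mu; we report the
model's own value rather than tune toward the published one.

Coincidences are decays whose two gammas convert in two different
detectors; same-detector pairs count as singles.  Randoms use a 10 ns
window; at 1000 Bq they are practically absent, matching the published
observation.

## Light transport and SiPM response

A 511 keV deposit yields Normal(Y*E, 4.8 * sqrt(Y*E)) photons
(Y = 40,000 /MeV).  Each SiPM channel receives photons with probability

    w = Omega / 4pi * exp(-r / lambda_abs) * [cos(theta) >= cos(theta_c)]

where Omega is the exact solid angle of the channel's pitch-square patch,
r the distance to the channel centre, lambda_abs = 400 mm the bulk
absorption length, and theta_c = asin(n_epoxy / n_LYSO) = 55.5 degrees
the total-internal-reflection critical angle of the polished
crystal/coupling boundary (1.5 / 1.82).  The cone cutoff matters: without
it the grazing-incidence tails of the solid angle spread intensity along
the whole surface, which a real dielectric boundary does not transmit,
and centroid-based positioning degrades far beyond what is physical.
Reflections are not modelled (`reflection_boost` can scale recovered
light, default 1.0; `escape_cone_enabled=False` restores the pure
solid-angle weight).  Photon arrivals are one multinomial draw over all
channels plus an escape sink, so the photon budget is conserved exactly.

Channel outputs follow a counting model of the 50 um-pixel devices:
Binomial(arrivals, PDE x fill = 0.37) detection, one generation of
optical crosstalk (7%), afterpulsing as a 1.06 gain, dark counts
Poisson(110 kHz/mm^2 x pitch^2 x 300 ns gate ~ 0.35 per 3 mm channel),
and pixel saturation N_pix (1 - exp(-fired / N_pix)) with
N_pix = 3531 / 6331 / 14331.  Pulse shapes are not simulated: the 300 ns
gate captures >99% of the 36 ns scintillation decay, so integration
reduces to counting.  Patterns are stored as raw channel outputs, zero-
padded to the square sizes 32/24/16 and peak-normalized per event before
estimator input (the published pipeline does not state a normalization).

## Position estimators

**Centroiding baseline.**  (1) intensity-weighted centroid of each
pattern; (2) paired-surface means — left+right -> (y, z), top+bottom ->
(x, y), back alone -> (x, z); (3) per-coordinate mean over the planes
that provide it; (4) stack.  The published description maps the pairs to
planes inconsistently with the geometry ("top-bottom, left-right ...
x-z and x-y"); we implement the geometrically forced mapping above.
All-zero patterns drop out of their plane's average.  On this light
model the baseline reaches ~4.3 mm MAE for 13 mm crystals and ~6.2 mm
for 26 mm (6 mm SiPMs).  Its depth estimate is weak by construction —
surface centroids barely encode y — which matters downstream (below).

**Convolutional regressor.**  A compact CNN (three 3x3 conv layers of
16/32/32 channels, stride 2 after the first, global average pooling and
a 64-unit head) maps the stacked (C, S, S) patterns to the three local
coordinates, trained with MAE loss and Adam at learning rate 3e-4, batch
256.  Layers are implemented directly on NumPy (im2col convolutions,
gradients verified against finite differences in the suite); large
pretrained backbone families are outside this package's CPU scope.
Targets are standardized per coordinate during training.  On the scaled
profile (8,000 box-phantom decays -> ~8,000 samples, 6 mm SiPMs, 2,000
steps) the regressor reaches ~1.8 mm validation MAE — well under half
the centroiding error on the same samples, mirroring the published
order-of-magnitude gap, though not its absolute values, which depend on
full optical physics and GPU-scale training (~10^6 samples, 5x10^5
steps).  The error shrinks with interaction depth toward the
instrumented back surface, the same anisotropy trend as the published
depth analysis.

MAE is reported as the mean over samples and the three coordinates of
the absolute error; the mean Euclidean ("positioning") error is carried
alongside, with depth profiles in 3.25 mm bins (4 bins at 13 mm, 8 at
26 mm).

## Reconstruction

Each coincidence contributes one LOR between the two predicted positions
mapped to world coordinates.  LORs are projected onto the chip plane
(y-z; configurable) and binned into a 400 x 400 (rho, theta) histogram
with rho in [-40, 40] mm — the published pipeline fixes the bins but not
the range; 40 mm covers the chip half-diagonal with margin — and theta
in [0, pi).  Bin centres align with scikit-image's rotation-centre
convention, and reconstruction runs five sweeps of scikit-image's SART
(bilinear projector, relaxation 0.15).  Degenerate and out-of-range LORs
are dropped and counted.  Pixel size is 0.2 mm.

With ground-truth interaction positions the 21-point grid reconstructs
with ~0.4 mm FWHM per point, bounded by binning blur — the chain itself
does not limit resolution.  With the centroiding estimator the picture
is different, and worth stating plainly: the estimator's depth-blindness
collapses the y information of LORs between the two y-facing detectors,
and the per-axis averaging compresses tangential coordinates by ~2x, so
the three y columns of the grid blur toward each other and a 50%-of-max
peak count resolves ~13-15 of the 21 sources rather than all of them
(counts at 50,000 decays fluctuate up to the low twenties because noise
splits merged blobs; more statistics settle near 13).  Resolving all 21
requires an estimator at the ~1 mm level, i.e. the trained regressor at
full scale.  This is a faithful property of the centroiding baseline,
not of the reconstruction chain.

## Image metrics

Profiles through known source positions are Gaussian-smoothed (sigma
0.5 px) before any peak measurement.  FWHM is measured per axis by
linear interpolation of the half-max crossings and averaged over axes;
it is undefined on flat profiles.  SNR of a hot sphere is
10 log10(peak / cold-RMS) per profile, clamped to [0, 60] dB — the
published analysis reports dB without defining the estimator, and this
definition reproduces its "0 dB for invisible sources" behaviour;
absolute dB values are therefore not comparable.  Peak counting smooths
the image (same sigma), thresholds at a fraction of the maximum
(default 50%) and enforces a Euclidean minimum separation (default
5 mm), keeping brighter peaks first.

## Problem sizes and determinism

Default desk-scale sizes: 10,000 decays for sensitivity runs, 50,000 for
the grid reconstruction, ~8,000-decay datasets and 2,000 training steps
for the estimator comparisons.  The paper-scale profiles (10^5-10^6
samples, 5x10^4-5x10^5 steps) remain configurable.  Every stage is
deterministic under a fixed master seed: identical seeds give
byte-identical datasets, sinograms and images.

## Known limitations

* No Compton chains or inter-crystal scatter: sensitivity is biased low
  (see above) and light patterns are slightly narrow.
* No optical reflections: side surfaces carry less position information
  than a full optical simulation would give them; the centroiding
  baseline suffers most.
* The 2D (rho, theta) scheme reconstructs one plane; axial structure
  outside the chip plane is projected into it.  A `--plane` option
  reconstructs the other coordinate planes.
* SiPM pulse shapes, energy windows, dead time and Fresnel refraction
  are not modelled.
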