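# Methods

This note documents the models implemented in `mifish`, the defaults
that matter, and what the synthetic data do and do not capture.

## Coding scheme

The default design places 16 probes on the chr2 q-arm: 11 probes every
3 Mb from 55 Mb to 85 Mb, then 5 probes stepping 20 Mb to 185 Mb, each
spanning 66 kb (BED-style 0-based half-open intervals; a probe's point
position is its midpoint). Ten probes are dual-color (all ten unordered
pairs of a488/tmr/a594/cy5/a700, 350 oligos per dye) and six are
single-color (one per dye including ir800, 700 oligos, hence ~2x
brighter dots). The dye-to-position assignment is a fixed layout chosen
so that consecutive probes never share a dye and probes sharing a dye
sit at least 9 Mb apart. This property matters: the decoder suppresses
same-color dots closer than 0.50 um as split signals, so a design with
same-dye neighbors would let that filter delete genuine loci. Real
deposited coordinates can be supplied via a BED-like file instead.

Channel naming follows the public-dataset dialect (cy5 = AT647N,
tmr = AT542, ir800 = AF790). Dichroic-cube groups: {dapi, tmr, cy5,
ir800}, {a594, a700}, {a488}.

## Synthetic scenes

Each simulated cell is one ellipsoidal nucleus (semi-axes
6.2 x 5.4 x 3.1 um, typical of adherent RPE-1 cells) rendered into a
40 x 128 x 128 voxel stack at 200 x 130 x 130 nm. The two chromosome
copies are modeled as chains: successive loci are displaced by
isotropic Gaussian steps with per-axis sd

    sd = s * (gap in Mb)^nu,    s = 400 nm/Mb^0.5, nu = 0.5,

which puts the median 3D distance of 3-Mb pairs near 1 um, in the
range reported for few-Mb separations in interphase chromatin. Two
confinements act on the chain: the nucleus itself, and a spherical
chromosome territory of radius 3 um around each allele's center —
unconfined random walks with 20-Mb steps would scatter loci far beyond
any real chromosome territory (and beyond the 40-px cluster radius the
decoder uses). Allele territory centers are placed antipodally along a
random direction with guaranteed >= 7 um separation so that homolog
clustering is well posed. An optional per-probe radial bias pushes
B-compartment loci toward the lamina by a fraction of their remaining
radial distance.

Dots are rendered as 3D Gaussians integrated over voxels (erf
products), with per-channel lateral sigma from the predicted FWHM table
(FWHM_nm = 282-438 across a488-ir800; sigma = FWHM / 2sqrt(2 ln 2)) and
axial sigma 2x the lateral sigma in nm — a fixed anisotropy factor
standing in for the elongated widefield PSF. Sensor noise is
Poisson(signal + background) followed by additive Gaussian read noise
(sigma = 5 counts), clipped at zero. Defaults: background 100 counts,
2500 photons per dye for dual-color dots (5000 for singles); dual-color
probes emit at the *same* true position in both channels. The DNA
stain renders filled nuclei, 2x intensity for G2 cells.

What the simulation does **not** emulate: split FISH dots (a probe
fragmenting into several dots), off-target oligo binding, spatially
varying background, depth-dependent aberrations, touching nuclei, and
aneuploidy. Tests passing on these scenes therefore demonstrate the
correctness of the algorithms under the stated generative model, not
robustness to every real-data artifact; the split-dot filter in
particular is exercised by constructed cases rather than by the
generator.

## Detection and localization

Candidates are 6-connected strict local maxima of a lightly smoothed
copy of the image (Gaussian, 0.5x the expected spot sigma — pure noise
suppression), scored by the response of a difference-of-Gaussians
filter with narrow sigma = 1.72x the expected spot sigma and wide/narrow
ratio 1.6. Maxima with DoG response below the threshold (default 3.0
counts, ~7x the DoG-filtered noise floor of the default background, at
which rendered background fields yield zero false positives) are
discarded; surviving candidates closer than max(2 px, sigma) to a
stronger one are deduplicated. Finding maxima on the image rather than
on the DoG map keeps dots a few pixels apart separable — the broad DoG
kernel would fuse them.

Each candidate is localized in two stages. Stage 1 fits a
pixel-integrated 2D Gaussian (x, y, plane photons, background, sigma)
to the candidate's focal plane over a patch of radius ceil(3.5 sigma);
under the Gaussian-noise assumption the ML functional is a sum of
squares, minimized with `scipy.optimize.least_squares` (trust region;
the choice of optimizer over e.g. Nelder-Mead simplex is purely
numerical). Stage 2 bilinearly interpolates the axial profile at the
fitted (x, y) and fits a 1D Gaussian for z. Total photons are the
plane photons divided by the axial fraction of the fitted z-Gaussian in
that plane. Non-converging or degenerate fits raise and the dot is
dropped; fitted dots outside [0.5x, 2x] the predicted FWHM are
rejected. Fitting matters: snapping to voxel centers alone costs
~74 nm mean 3D error at this voxel size, while the fit reaches a few nm
on bright dots and scales as sigma/sqrt(N) in the shot-noise regime.

## Chromatic correction

Bead fields are matched across channels by mutual nearest neighbors
(3D, z scaled by the 200/130 voxel anisotropy). Displacement relative
to the cy5 (AT647N) reference is modeled per channel as a 2nd-order
polynomial of the *observed* lateral position (basis 1, x, y, x^2, xy,
y^2; each axis fitted independently by ordinary least squares) plus a
constant axial shift. Regressing on observed coordinates makes
"subtract the prediction from an observed dot" the exact inverse on the
calibration beads. Correction is applied to dot coordinates, not by
resampling images — equivalent for point data and exactly testable.
Reported MSEs are in pixel units with z in axial-pixel equivalents
scaled by the anisotropy.

## Nuclei and radial position

Nuclei are segmented from the DNA stain by global Otsu threshold,
per-plane hole filling, 26-connected labeling and a 20-um^3 minimum
volume. G1 gating applies Otsu to the distribution of integrated DNA
intensity across the dataset (G1 = lower mode); a unimodal
distribution (e.g. a simulated pure-G1 dataset) makes this split
meaningless, so the pipeline exposes `assume_g1` for pre-gated data.
Lamina distance uses two anisotropic Euclidean distance transforms:
d_E to the nuclear edge, and d_C to the "center set" — voxels in the
top percentile (default 99th) of the in-mask d_E distribution. The
normalized position d_E / (d_E + d_C) is 0 at the lamina, 1 at the
deepest point. Note the center is a *set*, not a point: for a sphere
of radius R the center set is a ball of radius r_c = 0.01^(1/3) R, so
the normalized value for a dot at radius r is (R - r)/(R - r_c), which
reduces to (R - r)/R only as the percentile approaches 100.

## Decoding

Per G1 nucleus, dots are split into two homolog clusters by k-means
(k = 2, best of 10 seeded restarts, coordinates in lateral-pixel units)
with a 40-px radius outlier filter; centroids closer than 1 um are
flagged as possibly merged. Within a cluster the 10 brightest dots per
channel (2 for ir800) are candidates. Dual-color probes are decoded
from inter-channel candidate pairs closer than the channel-pair
threshold — 0.25 um when both dyes share a dichroic cube, 0.55 um
otherwise. Probes encountered exactly once in the initial pair list
are assigned first (the count is static: recounting after each
assignment lets spurious pairs masquerade as unique); remaining probes
take the globally shortest surviving pair, ties broken by intensity sum
then stable ids. Assigning a dot suppresses *dimmer* same-color dots
within 0.50 um from other dual probes' lists — a split fragment carries
a fraction of the probe's oligos and cannot out-shine the primary dot,
and the dimmer-only condition protects genuine neighbors. Single-color
probes then take the brightest not-yet-selected dot of their channel
(they are 2x brighter by construction), and assigned dots farther than
5 um from every other assigned dot are dropped as outliers.

The randomized null re-assigns dual probes by drawing the first dot at
random and re-drawing (up to `n_random` times) until a partner within
0.55 um exists; the whole assignment is reiterated `n_reiterate` times
and allocations are ranked lexicographically by: total dot intensity,
number of doubly-allocated dots, number of pairs within 0.55 um,
number of failed probes, number of same-channel dots closer than
0.25 um. The combination rule for these priorities is our choice
(ranking, highest priority first).

Against simulation ground truth, a probe counts as correctly decoded
when all its assigned dots lie within 500 nm of the probe's true
position — half the typical nearest distance between same-channel loci
(same-dye probes are >= 9 Mb apart), so the tolerance separates "right
dot, imperfectly localized" from "wrong dot". Under the default scene
model at high brightness the decoder reaches ~95% probe-assignment
accuracy; the residual losses are same-channel dots that merge below
the diffraction limit and the mis-assignments that cascade from them.

## Geometry and validation

Present probes of one allele, in genomic order, are interpolated with a
natural cubic spline under chord-length parameterization, sampled 50
points per segment. Curvature is evaluated analytically from the
piecewise polynomials as k = |r' x r''| / |r'|^3, normalized per
structure by its maximum, and summarized by strict local maxima above
0.1 (plateaus yield none by construction; natural end conditions
distort the outermost segments, so closed-form checks evaluate the
interior). Dual-color probes contribute the midpoint of their dot pair
as the probe position.

Distance statistics aggregate per-pair Euclidean distances over
clusters into medians (pairs with fewer than a configurable minimum of
samples, default 5 for correlations, are excluded as unstable). A FISH
contact is a pair distance <= 1 um (inclusive). Contact matrices are
plain binned text files; A/B compartments come from the sign of a
supplied eigenvector track under a declared sign convention, with
|value| <= 0.01 left unassigned. On matched synthetic data (contacts
computed as the <=1 um fraction over a large ground-truth sample) the
expected sign structure holds: median distance vs contacts strongly
negative, FISH contact frequency vs contacts strongly positive, the
randomized null weaker than the decoder, and lamina-biased probes
closer to the nuclear edge.

## Problem sizes

Default test and validation runs use 40 x 128 x 128 voxel single-cell
fields: 50 cells (100 clusters) for the high-brightness decoding check,
30 cells for the realistic-brightness histogram and the concordance
analysis, 600 cheap (truth-only) structures for matched contacts, and
1000 patches per condition for the localization experiment. These
sizes give stable statistics for every quantity checked while keeping a
full run on a laptop-class machine in minutes.

## Known limitations

* Only diploid, two-cluster nuclei are decoded; aneuploidy and merged
  homolog territories are flagged, not resolved.
* No multi-emitter fitting: two same-channel dots closer than ~2.5 px
  merge into one detection.
* The axial PSF is a fixed 2x anisotropy, not a depth-dependent model.
* Image-space resampling for chromatic correction is not implemented
  (coordinate-space correction only).
* Eigenvector extraction from raw contact data is out of scope; the
  track is an input.
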