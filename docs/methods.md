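# Methods

This note documents the models, parameter choices and known limitations of
the beefmetrics measurement suite.

## Color-image preprocessing

Background elimination assumes a bright steak on a near-black background:
Otsu's threshold on the red channel, hole filling, and retention of the
largest connected component.  The Otsu implementation scans all 256 cut
points `t` for the classes `v < t` / `v ≥ t`, minimizing within-class
variance with ties broken toward the smallest threshold; a constant raster
raises a degenerate-input error naming the intensity.

Meat vs. non-meat (fat, bone) combines per-channel Otsu votes from u and L of
CIE Luv (D65 white point — stated explicitly because the u/L thresholds
depend on it) and G of RGB, restricted to the steak mask.  Polarity
convention: meat is the darker class in G and L and the higher class in u.
The default combination is a majority vote (≥ 2 of the available channels);
AND/OR are available.  A channel may only vote when its two Otsu class means
are separated by more than a per-channel noise floor (G: 12, L: 5, u: 8 raw
units): a plain Otsu split always "succeeds" on pure noise, so without the
floor a steak consisting entirely of fat would be split down the middle of
its noise distribution.  With all channels below the floor the meat mask is
returned empty with a warning; with all channels strictly constant a
degenerate-input error is raised.

The shared edge-preserving smoother is Perona–Malik anisotropic diffusion
(exponential conduction, explicit 4-neighbour scheme).  Defaults: 15
iterations, conduction coefficient 30 on the 8-bit scale, step 0.15 (the
stability bound of the scheme is 0.25).  The filter never produces values
outside the input range.

## Rib eye segmentation

The level-set field φ is negative inside the contour and is initialized as a
signed distance function saturated at ±8 px, with the zero level shifted half
a pixel onto the pixel boundary so the discrete gradient is ≈ 1 right across
the interface.  The evolution combines the double-well distance-regularization
term R(φ), the edge-weighted curvature term and the balloon (area) term with
a smoothed Dirac of width ε = 1.5.

Defaults per stage (time step 5, regularization weight 0.04, so their product
0.2 respects the < 1/4 stability bound; length weight 5; σ = 1.5 px for the
edge indicator):

| stage | edge map              | area weight | check every | stop |
|------:|-----------------------|------------:|------------:|------|
| 1     | non-meat binary map   | −3 (expand) | 20 iters    | area change < 0.5 % per check, max 400 |
| 2     | min(both maps)        | −1.5        | 10 iters    | same rule, max 300 |
| 3     | min(both maps)        | 0           | —           | exactly 10 iterations |

Negative area weight expands the contour (interior φ < 0 convention).  The
initial region is obtained by discarding meat components under 1 % of the
steak area and eroding with a 3×3 cross until a single component remains.
The stage-2 stopping threshold (0.5 % interior-area change per check) is
exposed as `area_growth_stop` and can be calibrated on labeled data.

A moving front leaves a shallow φ-plateau in the swept region — the
double-well dynamics only maintain unit gradient in a ~2 px vicinity of the
interface — so each stage re-establishes the capped signed distance on
return (plus 3 pure regularization iterations to relax staircase kinks).
The rebuild changes neither the zero level nor the interior area, and the
distance-regularity contract (|∇φ| ∈ [0.8, 1.2] on ≥ 95 % of a 5-px band) is
then met after every stage.

On the phantom suite the final contour sits systematically ~1 px inside the
true meat/fat interface (the curvature term shrinks against the edge well),
giving a ≈ 3.5 % under-estimate of the area of a 120×70 px ellipse — within
the 5 % acceptance band but a known bias.

## Backfat profiling

The inner curve is the convex hull of the detected meat; the outer (target)
curve is the boundary of the union of the steak region and the hull region,
locally pushed outward by a 2 px dilation wherever it would touch the hull so
the curves never intersect.  The hull is densified to ~1 px spacing and
resampled to control points every 50 px.  Each point marches outward along
its normal (recomputed each iteration from the evolving polyline, orientation
kept consistent) in 1 px steps, freezing when its distance to the target
boundary drops below one step; thickness is the cumulative Euclidean path
length.  The distance-to-boundary is sampled bilinearly from the Euclidean
distance transform of the target region minus half a pixel (the EDT measures
to outside pixel *centers*; the continuous boundary runs half a pixel
closer — without the correction all thicknesses carry a +0.5…1 px bias).
Points are inserted when active neighbours spread beyond twice the nominal
spacing and merged below a third of it; a point that cannot reach the target
within 500 iterations raises an error listing the stuck indices.

The measurement axis is the major principal axis of the rib eye mask (second
central moments) through its centroid — near-isotropic masks trigger a
degenerate-direction warning and fall back to the x-axis.  At 1/2 and 3/4 of
the axis length, perpendicular rays are cast to both sides; the side whose
chord through the backfat band (target region minus hull region) is longer
is taken, and the mark thickness is that of the nearest evolved control
point.  The reported profile runs between the two marks along the arc that
traverses the band.  Thicknesses are in pixels; a physical scale converts to
mm only when provided.

## Ultrasound ROI detection

The subcutaneous fat band is the Otsu-bright labeled component with centroid
in the upper third of the frame and the highest width/height bounding-box
ratio, detected on the raw frame (diffusion is reserved for rib detection).
Ribs are found by normalized cross-correlation between the diffused frame
and a synthetic template — a Gaussian-blurred bright semicircular arc
(radius 0.4 × width) over a dark shadow column, column-symmetric by
construction — followed by non-maximum suppression in a 31×31 window.  The
two strongest maxima with correlation ≥ 0.7 and horizontal separation
≥ W/4 are the ribs; the floor 0.7 cleanly separates measured rib-peak
correlations (≥ 0.86 across the phantom suite) from the strongest peaks of
diffused structureless speckle (~0.6).  The 80×80 ROI is centered
horizontally between the ribs and vertically midway between the fat band's
bottom row and the mean rib depth; a zone shorter than 80 px raises an error
so the caller can fall back to a manual ROI.

## IMF% estimation

The 42-entry descriptor (authoritative order in
`beefmetrics.features.FEATURE_NAMES`): gradient mean/std at Gaussian scales
1 and 2 px (4); co-occurrence correlation/homogeneity/contrast/energy at
offsets (0,1), (1,0), (1,1), (1,−1), (0,2) with 32 gray levels, symmetric and
normalized (20); gray-level mean, contrast ratio (max−min)/(max+min) and
entropy (3); histogram percentiles 20/40/60/80 and skewness (5); the
variance coefficient (std/mean) of the non-DC Fourier power spectrum and its
10/30/50/70/90 percentiles (6); and
correlation/homogeneity/contrast/energy of the co-occurrence of the uniform
LBP(8,1) code image (4).  All entries are finite for any valid patch
(degenerate statistics fall back to 0, e.g. skewness of a constant patch).

The regression pipeline standardizes features (z-score) before the PCA: the
raw feature scales span about six orders of magnitude (Fourier power vs.
co-occurrence energy) and both PCA and the RBF kernel are scale-sensitive.
PCA keeps k = 10 components (a variance-target option exists).  The SVR uses
the RBF kernel exp(−γ‖u−v‖²) with γ ∈ {2⁻¹⁰ … 2³} and termination tolerance
∈ {1e−4, 1e−3, 1e−2} grid-searched by 5-fold cross-validation (RMSE
criterion) on the training split only; the regularization constant is fixed
at 1 (varying it, or replacing the SVR by ridge regression, did not change
held-out error on the phantom suite — the regressor is not the accuracy
bottleneck).  The color-image variant descriptor uses per-channel means,
per-channel above-Otsu pixel counts and the 8 lowest non-DC Fourier
magnitudes of the masked, zero-padded luminance.

## Phantom generators

Steak phantoms place an elliptical rib eye, two satellite muscles joined to
it by a connective-fat web (the convex hull of the meat — a real steak is one
connected piece), thin fat seams (4 px dilation), and a backfat band attached
to the rib eye's upper arc with a prescribed thickness function t(s)
(constant or linear ramp), rendered in meat/fat colors with additive Gaussian
noise (σ = 6).  Ground truth rasters are exactly the drawn geometry; the
rasterized ellipse area is within 0.5 % of πab.

Ultrasound phantoms compose a dark background (level 60), a bright horizontal
fat band in the upper third, two rib echoes (bright arc over an acoustic
shadow), and an inter-rib muscle zone whose texture carries the latent IMF
scalar through two channels: a diffuse echogenicity increase of 3.5 % per
IMF unit (marbling raises muscle echogenicity in B-mode imaging) and a field
of bright specks at 0.004 specks/px per IMF unit.  A speck-count channel
alone is Poisson-limited — at realistic counts its placement noise exceeds
half an IMF unit, more than the assay noise being simulated — hence the
diffuse channel carries most of the signal.  Speckle is multiplicative: the
sum of squares of two low-pass-filtered Gaussian fields (Rayleigh-like
envelope, correlation length 1.2 px), normalized to unit mean and blended at
weight 0.3.  This emulates the appearance and first-order statistics of
B-mode speckle, not any probe's physics: no point-spread function,
attenuation or depth-dependent gain.  Grouped datasets draw one latent IMF
scalar per animal (uniform on [0.5, 9.5]), render four frames per animal with
jittered geometry, and label each frame 2 + 0.8·IMF + N(0, 0.3), mirroring a
chemical lipid assay with ~0.3 % error.

What passing on phantoms does and does not show: the pipelines demonstrably
recover known geometry and a known latent under controlled contrast, noise
and connectivity assumptions; real carcass images add lighting gradients,
color casts, cut-surface artifacts and touching muscles, and real ultrasound
adds probe-dependent speckle, shadowing and anatomy variation, none of which
the phantoms model.  Phantom results are a correctness check of the
algorithms, not a field-performance claim.

## Evaluation protocol

ε₁ is reported as a magnitude (absolute value).  The repeated split protocol
draws seeded random 2/3–1/3 partitions (whole animals kept on one side when
groups are given).  Split sizes follow the convention that the training side
strictly exceeds the fraction: train = ⌊n·f⌋ + 1 capped at n − 1, which for
n = 153 gives the conventional 103/50 split.  The IMF recovery experiment
runs 69 animals × 4 frames with 100 repetitions; rib eye and backfat suites
use 20 phantom seeds and the ROI reliability suite 100 — sizes chosen so the
whole validation runs in minutes on one CPU while keeping quantile estimates
stable.

## Known limitations

* The rib eye contour carries a ~1 px inward bias (≈ 3.5 % area for a
  120×70 px ellipse).
* The backfat profile is sampled at the 50 px control-point spacing; very
  local thickness variation between control points is smoothed over.
* The ROI placement assumes both ribs and the fat band are visible, as the
  acquisition protocol guarantees; it has no recovery strategy for missing
  structures beyond the manual-ROI fallback error.
* Thresholds (NCC floor 0.7, channel noise floors, stage-2 growth stop) are
  calibrated on the phantom suite and would need re-calibration on real
  acquisitions.
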