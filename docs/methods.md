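# Methods

This note documents the models, parameter choices and numerical
conventions behind `whalesat`, and what the synthetic experiments do and
do not demonstrate about real imagery.

## Scene model

A scene is a dual-resolution stack: eight multispectral (MS) bands at a
2 m ground sample distance (GSD) and one panchromatic band at 0.5 m,
both unsigned integers in [0, 2047]. The sensor's radiometry is 11-bit;
the delivered product's bit depth is not documented for our reference
imagery, so `dn_max = 2047` is a configuration default rather than a
claim. Band 5 is the coastal band (400–450 nm); the remaining band
names follow the WorldView2 passbands arranged so that band 1 is red
and band 8 is NIR2, consistent with the false-colour display convention
(bands 1-8-5) used for this kind of imagery.

Raster conventions: 0-based (row, col); origin at the upper-left
corner; row increases southward; pixel-centre coordinates. MS and pan
grids cover the identical world extent (pan dimensions are exactly 4×
the MS dimensions). Annotations travel in world metres so one file
serves both grids. Rasters are GeoTIFF (tifffile with ModelPixelScale /
ModelTiepoint tags and a JSON band table in ImageDescription); only a
local metric frame is supported — map projections are out of scope.

## Water-column attenuation model

Real radiative transfer in a turbid coastal water column is not
modelled. The one empirical fact the simulator must reproduce is the
band cross-section behaviour of whale-like features: all nine bands
respond to a surface feature, while a submerged feature registers in
the coastal band alone. The simplest monotone model consistent with
that is a two-way Beer–Lambert law per band:

    ΔDN(band, d) = ΔDN₀ · exp(−K_d(band) · d)

where `ΔDN₀` is the whale's surface contrast (default 150 DN over a
300 DN water background), `d` the depth in metres, and `K_d` an
effective two-way diffuse attenuation coefficient. Defaults (1/m):
coastal 0.20, blue 0.45, green 0.55, yellow 0.80, pan 1.30, red 1.60,
red-edge 3.0, NIR1 5.0, NIR2 6.0. These values are **model parameters,
not measurements**: they are ordered like clear-water attenuation
spectra (far-blue least attenuated, infrared essentially opaque within
a metre) and scaled so that all three qualitative visibility regimes
are realisable inside a 0–12 m depth range — all-band visibility near
the surface, weak-pan visibility around 1–2 m, and a non-empty
"coastal-band-only" window. With the default noise levels
(MS σ = 8 DN, pan σ = 18 DN) the coastal-only window, obtained by
solving `ΔDN(band5, d) ≥ 2σ_MS` against `ΔDN(b, d) < σ_b` for every
other band, is 6.5–11.2 m. No claim is made that real sensors see 11 m
deep; the depth at which whales remain visible in real scenes is an
open question that the original study explicitly deferred.

## Synthetic scenes

The generator emulates the situation the census method was designed
for — a cloud-free, calm-sea acquisition over a breeding aggregation —
with one seeded generator per scene and a fixed draw order (background,
whales, confounders) so partial configs stay reproducible.

* **Background**: per-band Gaussian sensor noise around the water mean
  (pan noisier than MS, reflecting the panchromatic band's higher noise
  ratio), plus a weak shared low-frequency texture field (amplitude
  3 DN, correlation length 40 m) standing in for sediment and
  illumination gradients. No wave glint by default — the method is for
  calm-sea scenes; an optional pan salt-speckle term exists for
  robustness experiments.
* **Whales**: flat-top ellipses (length 5–15 m, aspect 0.25–0.45,
  uniform orientation), with per-band contrast from the attenuation
  model, plus a single-pixel callosity deposit (+80 DN, area-diluted in
  MS) at the head end — the brightest pixel of the footprint in pan.
  The flat profile is deliberate: with the optimizer's
  tie-toward-higher-threshold rule, a tapered radial profile would let
  the ratio plateau extend to thresholds where only the callosity
  survives, which contradicts how whale-level thresholds behave; a
  flat body makes the plateau end at the body DN. Thin ellipses that
  slip between pixel centres light their centre pixel, since a ≥5 m
  whale always covers its central pixel area. An optional pair flag
  renders a touching mother-and-calf pair recorded as one annotation,
  mirroring the ambiguity a manual digitizer faces.
* **Seabird clusters**: 8–17 bright dots on a jittered 3 m grid within
  ±10 m, each dot one or two explicit pan pixels; dot DN is
  area-diluted (a bird is smaller than even a pan pixel), so dots read
  dimmer than a whale back and drop out of whale-level thresholds, and
  a cluster never forms a pan component larger than 3 pixels.
* **Bubble slicks**: diffuse elongated patches at 1.5× the MS noise SD.
* **Boats**: high-aspect hulls 20–30 m long, brighter than any whale,
  with a stern-to-bow brightness ramp (uniform hulls + noise shatter
  into whale-sized fragments at mid-histogram thresholds, which no real
  textured hull does) and a sub-pixel foam wake.
* **Rocks**: bright patches rendered identically in every band — the
  signature that distinguishes a static reflector from a submerged,
  attenuated whale.

Placement is rejection sampling with a 20 m minimum centroid
separation, bounded at 1000 retries ("placement failure" beyond that).

What passing tests on these scenes do **not** show: robustness to sun
glint, swell, turbidity gradients, surface-active whales (rolling, tail
slapping, blows), or radiometric artefacts of real deliveries. The
generator's role is to make every pipeline stage testable with known
truth, not to certify performance on real imagery.

## Threshold optimization

Whales are multi-pixel features; noise produces isolated single
pixels. The optimizer exhaustively scores every candidate DN threshold
by `ratio = n_multi / max(n_single, 1)` (multi = component of ≥ 2
pixels, 8-connected by default) and returns the maximizer, breaking
ties toward the higher threshold to minimize residual noise. Default
candidates are every integer DN from the background median to the grid
maximum, excluding thresholds whose foreground fraction exceeds 2 % —
whale cover in a census scene is orders of magnitude below that, and
near the median the statistic degenerates into counting
noise-percolation blobs. The component counts in the returned result
are re-checkable by running the labeller at the chosen threshold.

A band whose *best achievable* ratio is below 1 is noise-dominated
(singles outnumber multi components everywhere); its threshold
detections are still usable as a primary candidate list, but are not
trusted as cross-band support evidence during classification.

## Shape filter and detection classes

Components become candidate objects with second-moment measures
(scikit-image regionprops) scaled by the grid GSD. The size/shape rule
keeps whale-like objects: major axis within [5, 16] m and aspect
(major/minor) at most 7. Numerical tolerances, all with stated reasons:

* one-GSD tolerance on both length bounds — rasterized-ellipse moment
  lengths read up to about one pixel long or short;
* a one-pixel floor on the minor axis before computing aspect — a
  collinear pixel set has zero second moment but is physically one GSD
  wide;
* aspect rejection only for components of ≥ 10 pixels — below that the
  moment aspect of an eroded genuine whale is indistinguishable from a
  streak (the default cap of 7 reflects that a true aspect-4 whale can
  measure near 5–6 after rasterization);
* objects *larger* than the window (boats, slicks, wakes) are rejected
  outright; objects *smaller* than it — including valid single pixels
  from deep whales — are kept but flagged, feeding the `possible`
  class.

Classification formalizes the manual three-class protocol. For each
detection: no surface evidence but coastal-band support → `band5_only`
(submerged); shape-passing with surface evidence and non-weak contrast
→ `probable`; everything else → `possible`. "Surface evidence" is a
panchromatic counterpart within the 10 m match radius *or* a
footprint-mean contrast of ≥ 2 robust background SDs in any non-coastal
MS band (with a 3 DN floor so quantization residue never counts); the
second clause matters because a whale a metre down is still obvious in
the blue/green bands even when pan, with its higher noise and stronger
attenuation, misses it. All classification inputs are explicit
configuration so users can tighten them.

## Unsupervised and supervised classifiers

k-means uses deterministic initial means evenly spaced between the
per-band data minimum and maximum (as the comparison method describes —
no random initialization, hence no seed), minimum-distance assignment,
and mean updates until movement < 1e-3 or 100 iterations; empty
clusters are dropped deterministically with a warning. ISODATA wraps
the same update loop with per-pass post-steps: discard clusters below
`min_cluster_size`, split clusters whose widest per-band SD exceeds
`split_sd` (means offset ± one SD along that dimension), merge mean
pairs closer than `merge_dist`. With the post-steps disabled it is
pixel-identical to k-means by construction. Cluster label grids become
candidate masks by taking every non-modal cluster whose mean intensity
exceeds the robust (median/MAD) water level by 2 SDs, restricted to
pixels above the water level; the modal cluster is always water.

Maximum likelihood assigns each pixel the class with the highest
multivariate-Gaussian log-likelihood under user-supplied signatures
(mean + covariance per class); singular covariances are
ridge-regularized (ε = 1e-6 of the mean diagonal) with a warning. On
scenes with broad, overlapping signatures it produces more false
positives than single-band thresholding — the qualitative ordering the
census comparison reported.

## Matching and metrics

Detections are matched to reference annotations one-to-one, greedy by
ascending centroid distance, cut at a 10 m radius (about a whale
half-length plus MS-pixel slack; the original assessment matched
visually and states no tolerance). Greedy matching is order-stable and
within one pair of the optimal assignment at realistic densities — a
test bounds the discrepancy against the Hungarian solution. A matched
detection inherits the *reference* class for counting; unmatched
detections are false positives.

Metric denominators reproduce the published assessment table exactly
from its count rows: match percentages over the manual grand total
(91), "% of probable" over the manual probable total (55), "% false
positives" over the method's own total signals, "% good" = 100 − "%
false positives". Percentages are rounded half-up to one decimal; this
convention regenerates all 20 published percentage cells, including the
case where the running text rounds differently from the table
(24/101 = 23.76 → 23.8).

## Problem sizes

Tests and the acceptance script use 128×128-pixel MS scenes (256 m
square, 512×512 pan) with 20 whales, and 20 scene replicates per
stochastic statistic — large enough that every regime of the threshold
optimizer (noise floor, whale plateau, confounder regimes) is populated,
small enough that the full suite runs in well under a coffee break.

## Known limitations

* The attenuation model is phenomenological; `K_d` defaults are chosen
  for regime coverage, not fitted to water optics.
* Global thresholds only; a spatially adaptive threshold might behave
  differently over turbidity gradients.
* The `possible` class of the manual protocol mixes contrast, shape
  and context criteria that are not fully specifiable; the formal rule
  here (shape-fail, single-pixel or weak contrast) is a stated
  approximation.
* Rock rejection by multi-epoch change detection, texture/object-based
  analysis, pansharpening and abundance estimation are out of scope.
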