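# Methods

## Problem and model

The package estimates how much of a beach is covered by stranded
*Sargassum* from ordinary geotagged photographs. The estimator is a
three-stage pipeline: (i) conditional-GAN translation of the photograph
into a palette-colored "segmented image"; (ii) k-means hardening of
that continuous image into the three classes Sargassum / Sand / Other;
(iii) the coverage statistic and its spatial aggregation.

Treating segmentation as image-to-image *translation* (rather than
per-pixel classification) lets a small paired dataset (hundreds to a
thousand images) train a usable model: the adversarial loss supplies
the structural prior that a per-pixel loss alone lacks. The price is
that the output is not a label map — colors near, but not at, the
palette — which is exactly why the k-means stage exists.

### Translator

The generator is a UNet: `d = log2(input_size)` stride-2 convolution
blocks (4×4 kernels, padding 1, LeakyReLU 0.2) down to a 1×1
bottleneck, mirrored by `d` stride-2 transposed-convolution blocks
(batch norm, ReLU, dropout p = 0.5 on the first three), skip
connections concatenating mirror-level encoder features, and a final
stride-1 convolution to 3 channels through tanh. At full scale the
encoder widths are 64–128–256–512 (saturating at 512); weights are
initialized from N(0, 0.02).

Two normalization details are deliberate choices. The first encoder
block carries no batch norm by default — the convention of this
architecture family — with a `first_block_batchnorm` switch for the
variant reading in which the first block is normalized. The innermost
encoder block also skips batch norm: at a 1×1 bottleneck the spatial
dimensions contribute nothing to the batch statistics, which makes
normalization degenerate at small batch sizes.

The discriminator is a PatchGAN over the channel concatenation of the
source photo and a candidate target: stride-2 blocks, a stride-1 block,
and a stride-1 single-channel head, all 4×4/pad-1; the output is a grid
of patch logits (30×30 for 256-px inputs, 6×6 for 64-px). Losses are
binary cross-entropy on logits: the generator minimizes
`adversarial_weight · BCE(D(x, G(x)), 1) + l1_weight · mean|G(x) − y|`
(defaults 1 and 100), the discriminator `BCE(real, 1) + BCE(fake, 0)`.
Setting `adversarial_weight = 0` reduces training to pure L1
regression, which the test suite uses as a controlled baseline.
Optimizer: Adam, lr 2e-4, β₁ = 0.5. Masks enter the network as their
palette-RGB rendering scaled to [−1, 1]; translation therefore targets
the colored segmented image, not one-hot labels. Dropout is the only
stochastic element; it may remain active at inference
(`inference_dropout`, default on), but all evaluation and determinism
checks run with it off.

The tensor backend is a small in-package numpy layer library
(`_nn.py`): im2col convolutions and their adjoints (the transposed
convolution is implemented exactly as the adjoint of the strided
convolution), explicit backward passes, float32 throughout. Layers are
reentrant — `forward` returns an explicit cache consumed by
`backward` — because one GAN step forwards the discriminator three
times before any backward.

### Desk-scale preset

The full 256-px architecture is intended for GPU training on real
photographs. For CPU-scale experiments the package provides
`desk_scale_specs(size, base)`: the same topology at reduced width
(widths grow from `base` and saturate at `4·base`; the discriminator
depth shrinks so its receptive-field stack still fits the input). The
synthetic study in the acceptance checks trains 64-px scenes at
`base = 16` — about 0.76 M generator parameters — for 25 epochs over
200 pairs, roughly five minutes on one CPU core. These sizes are the
package's own scaled-down study conditions; the published full-scale
experiment (1,000 real images, 800/200 split) is not reproducible
without the real photo archive and a full training run.

### Quantization

k-means with k = 3 on raw RGB pixel colors (no color-space conversion).
Identical colors are collapsed into weighted points first; this leaves
the objective unchanged and makes the fit invariant to pixel order.
Two regimes:

* **Tiny inputs** (k^distinct ≤ 20 000, i.e. ≤ 9 distinct colors at
  k = 3): solved *exactly* by enumerating all assignments of distinct
  colors. Restarted Lloyd can land in local optima on adversarial tiny
  configurations, and exhaustive enumeration is cheaper than a single
  Lloyd run there.
* **Real images**: k-means++ seeding, Lloyd iterations until the
  maximum centroid shift is below `tol` (default 1e-4, max 100
  iterations), best of 5 restarts by objective. Empty clusters are
  re-seeded at the point farthest from its centroid, keeping k = 3.

Cluster-to-label assignment is the minimum-total-cost bijection between
centroids and palette colors under squared Euclidean distance (all 3!
matchings enumerated); ties break toward giving the lowest cluster
index the earliest label in (Sargassum, Sand, Other). Images with fewer
than 3 distinct colors fall back to nearest-palette-color labeling with
a logged warning, so the pipeline still emits a mask for pathological
photos.

### Coverage and mapping

`coverage = 100 · n_sargassum / (n_sargassum + n_sand)`; Other pixels
are excluded from the denominator. The result is undefined (`None`)
when the mask has no beach pixels, and also when the beach fraction of
the image falls below `min_beach_fraction` (default 0.05) — an
automatic proxy for the manual exclusion of uninformative close-up
photos; the default is a package choice, not a published value.
Undefined photos never enter map aggregation.

Mapping projects photo coordinates to UTM (zone auto-selected from the
mean longitude; Mahahual → 16 N) and bins them into `cell_size_m`
squares (default 30 m, the Landsat OLI/TIRS pixel size). The projection
is the standard WGS84 transverse-Mercator series, implemented in the
package and verified in tests by round-trip identity, the
central-meridian/false-easting anchor, and distance consistency against
an independent haversine computation. Cells are half-open
`[x0, x0+s) × [y0, y0+s)` with the grid origin snapped to multiples of
the cell size; true Landsat-scene alignment is scene-dependent, so an
explicit origin override (`origin_x`, `origin_y`) supports alignment to
a user-supplied geotransform. Cell means are unweighted across photos.
Bins are the five intervals [0, 20], (20, 40], (40, 60], (60, 80],
(80, 100] — closure chosen so every value in [0, 100] has exactly one
bin — with default colors #1a9641, #a6d96a, #ffffbf, #fdae61, #d7191c.
Exports are RFC 7946 GeoJSON (WGS84) polygon and point layers plus a
CSV; feature order is deterministic by cell id. Shapefile output is not
provided; GeoJSON covers the GIS hand-off.

### Evaluation metrics

One-vs-rest per class from the 3×3 pixel confusion matrix (rows =
actual). F1 is the harmonic form 2PR/(P+R); a non-standard
half-harmonic variant `PR/(P+R)` exists behind `harmonic=False` purely
for exactness-of-record, and no table rendered by the package uses
it — the harmonic form is the only one consistent with the aggregate
rows the package produces. Zero-denominator conventions: any metric
with a zero denominator is 0, except the IoU of two empty sets, which
is 1. Macro averages are unweighted class means; weighted averages use
support (ground-truth pixel count) weights. Rounding for table
rendering is decimal half-up to 2 places, applied only at presentation
time. Box plots use linear-interpolation quartiles and Tukey
1.5·IQR whiskers; descriptive summaries report mean, sample sd
(ddof = 1), min, quartiles, max.

## Synthetic data

`make_scene` emulates the dominant composition of usable beach
photographs: horizontal bands — Other (sky/sea) on top, a Sargassum
wrack line, Sand at the bottom — with smooth random band boundaries
(Gaussian noise low-passed at `texture_scale`, zero-meaned so realized
class fractions track the request within 0.03) and band-limited color
texture of standard deviation `color_jitter_sd` (default 8) around the
palette colors. `make_coast` scatters photos evenly along a
great-circle coastline segment with small lateral jitter (3 m), a
position-dependent mean coverage profile, and Gaussian observation
noise (default 5 percentage points), clamped to [0, 100]. Defaults
place the coast at the Mahahual study area coordinates.

What the generator does *not* model — water transparency, shadows,
rocks mixed with wrack, mixed textures, perspective — is precisely what
drives the real study's outliers. Passing synthetic tests therefore
demonstrates that the pipeline machinery (training dynamics,
quantization, coverage arithmetic, mapping) is correct and that the
model family can learn scenes of this structure; it does not certify
real-photo accuracy, which depends on the real archive and full-scale
training.

## Numerical choices and edge cases

* Mask palette: Sargassum (123, 63, 0) brown, Sand (255, 221, 0)
  yellow, Other (128, 128, 128) gray; any bijective palette is
  accepted, the fixed default makes fixtures bit-exact. Mask reading
  maps pixels to the nearest palette color; pixels farther than
  `tolerance` (default 8, per-channel max distance) from every entry
  raise a palette error naming the offender. Masks are always written
  as PNG.
* EXIF GPS precedence: EXIF wins over a sidecar CSV on conflict, with a
  logged warning. "No GPS block" is a missing value; an unreadable GPS
  block is a parse error — distinct conditions.
* Seeds: every stochastic component (splits, scene generation, weight
  init, batch order, dropout, k-means) takes an explicit integer seed;
  training derives independent init/loop streams from one seed.
  Fixed-seed runs are bit-reproducible, including byte-identical CSV
  and GeoJSON artifacts when inference dropout is off.
* Degenerate inputs: empty datasets, empty masks, images under 8×8,
  non-power-of-two generator inputs, and undefined coverages raise or
  propagate explicit signals rather than producing silent numbers.

## Known limitations

* No photorealism in the generator, hence no claim about real-photo
  accuracy at desk scale (see above).
* The per-photo coverage ignores perspective: a percentage of image
  pixels is not a percentage of ground area; the 20 %-interval binning
  deliberately coarsens the map to absorb such distortions.
* UTM grid cells approximate, but do not replicate, the Landsat pixel
  lattice unless an explicit origin override is supplied.
* Biomass/volume estimation is out of scope; coverage is an areal
  proxy.
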