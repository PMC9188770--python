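# sargamap

Estimation and mapping of beach *Sargassum* coverage from geotagged
photographs.

Massive strandings of pelagic *Sargassum* (S. fluitans, S. natans) on
Caribbean beaches are hard to monitor from satellites: coastal scenes
are heterogeneous, clouds and sun glint produce false positives, and
the usable spatial resolutions (30 m and coarser) blur the beach
itself. `sargamap` implements a ground-level alternative for coastal
researchers and beach-management agencies: crowdsourced beach
photographs with GPS geotags are segmented automatically, reduced to a
per-photo coverage percentage, and aggregated into a choropleth map.

## Method

1. **Image-to-segmentation translation.** A conditional GAN translates
   each RGB photograph into the *segmented-image domain*: a UNet
   generator (stride-2 convolution encoder C64–C512, transposed-
   convolution decoder with dropout on the first three blocks, skip
   connections, tanh output) against a PatchGAN discriminator
   (C64–C128–C256–C512 on channel-concatenated source/target pairs,
   emitting a grid of per-patch real/fake logits). Losses:

   - generator: `L_G = BCE(D(x, G(x)), 1) + λ · mean|G(x) − y|`, λ = 100
   - discriminator: `L_D = BCE(D(x, y), 1) + BCE(D(x, G(x)), 0)`

   trained with Adam (lr 2·10⁻⁴, β₁ = 0.5). Dropout is the model's only
   source of randomness and may stay active at prediction time.
2. **k-means quantization.** The continuous translated image is hardened
   into three classes — *Sargassum*, Sand, Other — by k-means (k = 3)
   on pixel colors, minimizing `Σᵢ Σ_{x∈cᵢ} ‖x − μᵢ‖²`, followed by a
   minimum-cost matching of centroids to the mask palette.
3. **Coverage.** Other pixels are discarded; Sargassum + Sand pixels are
   taken as 100 % and `coverage = 100 · n_sargassum / (n_sargassum + n_sand)`.
4. **Mapping.** Photos are projected to UTM and grouped into 30 m grid
   cells (the Landsat OLI/TIRS pixel size); each cell carries the mean
   coverage of its photos, binned into five 20 % intervals colored dark
   green → dark red.

Evaluation uses the per-pixel confusion matrix: precision, recall,
F1 = 2PR/(P+R), IoU (Jaccard), accuracy, and macro / support-weighted
averages, plus box-plot (Tukey) summaries of per-image scores.

A synthetic beach-scene generator (banded sky–wrack–sand scenes with
controllable class fractions, plus geotagged photo sets along a
synthetic coastline) makes the whole pipeline runnable and testable
with no external data.

## Worked example

```bash
sargamap --seed 5 synth --out demo --n-pairs 8 --size 16
cat > demo.yaml <<EOF
project: demo
out: demo_run
seed: 5
input_size: 16
inference_dropout: false
train: {epochs: 2, batch_size: 4, base_filters: 8}
EOF
sargamap pipeline --config demo.yaml
```

which prints the pooled evaluation table for the run and the artifact
location:

```
              precision  recall  f1-score  support
   Sargassum       0.29    0.01      0.02      684
       Other       0.18    0.07      0.10      811
        Sand       0.23    0.73      0.36      553
    accuracy                         0.23     2048
   macro avg       0.23    0.27      0.16
weighted avg       0.23    0.23      0.14
artifacts in demo_run
```

(two epochs on eight 16-px images barely moves the network — the table
columns are the point here: per-class precision/recall/F1 with pixel
supports, accuracy, and the macro / weighted average rows)

and leaves in `demo_run/`: predicted masks (`masks_pred/*.png`), the
coverage manifest (`coverage.csv`, one row per photo with latitude,
longitude, and coverage percentage), evaluation tables
(`metrics/report.csv`), and GIS-ready layers (`map/grid.geojson` — 30 m
cells with `mean_coverage`, `n_photos`, `bin`, `color`;
`map/photos.geojson` — photo points with presence flags). A two-epoch
toy run just demonstrates the plumbing; a realistic desk-scale run is
`--n-pairs 200 --size 64` with 25 epochs, which reaches weighted F1
≈ 0.99 on held-out synthetic scenes in a few minutes on one CPU.

Library use mirrors the CLI:

```python
import sargamap as sg

pair = sg.make_scene(sg.SceneSpec(height=64, width=64, seed=7))
mask = sg.quantize(pair.rgb, sg.KMeansSpec(seed=7))
print(sg.coverage(mask, "demo").coverage_pct)  # e.g. 51.04
```

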