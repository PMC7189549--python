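# plaquescope

Quantitative scoring of amyloid-beta pathology in whole-slide images of
immunostained brain tissue.

Neuropathologists rate Aβ burden on a four-level ordinal scale (none <
sparse < moderate < frequent) per deposit morphology — cored plaques,
diffuse plaques, and cerebral amyloid angiopathy (CAA). `plaquescope`
implements the computational counterpart: a sliding-window tile classifier
produces per-morphology *confidence heatmaps* of a slide, and each heatmap
is reduced to a scalar

```
CNN score = (# blobs in the thresholded, morphologically cleaned heatmap)
            / (region area in heatmap pixels)
```

Scores can be restricted to annotated gray matter, computed for fixed-area
(~4 mm², 10×-objective-sized) fields of view with top-n convergence
analysis, and compared across cohorts grouped by ordinal rating, diagnosis
(control / pure AD / AD with TDP-43 or Lewy body co-pathology) or
NIA-Reagan level using ANOVA + Tukey HSD, t-tests, Kruskal–Wallis and
Spearman rank correlation.

A first-class synthetic-data module generates slide images, heatmaps,
labeled training tiles and cohorts with *planted ground truth* (deposit
counts, masks, ordinal levels), so every stage of the pipeline is testable
end-to-end without institutional data. See `docs/methods.md` for the model
conventions, generator design and validation study designs.

## Package layout

| module | contents |
|---|---|
| `plaquescope.synthetic` | slide/heatmap/tile/cohort generators with ground truth |
| `plaquescope.preprocessing` | Reinhard color normalization, LCH tissue segmentation, tiling |
| `plaquescope.cnn` | six-conv-block multilabel classifier (numpy), training, sliding-window heatmaps |
| `plaquescope.scoring` | threshold → open/close → blob labeling → density score; gray-matter restriction; percent change |
| `plaquescope.fov` | field-of-view window scores, greedy non-overlapping top-n, convergence tables |
| `plaquescope.cohort_stats` | diagnosis/Reagan grouping rules, ANOVA+Tukey, t-test, Kruskal–Wallis, Spearman |
| `plaquescope.pipeline` | end-to-end orchestration, annotation loading, score IO, run manifests |
| `plaquescope.experiments` | canned validation experiments (rank-structure recovery, gray-matter shift) |
| `plaquescope.plots` | grouped boxplots (±1.5·IQR whiskers, significance stars), FOV overview images |
| `plaquescope.cli` | `plaquescope run / synth / score / fov / stats` |

## Worked example

Score a 12-slide synthetic cohort whose planted deposit densities rise
with the assigned ordinal level (noise_sd 0.5 deposits/mm²), end to end:

```yaml
# demo_cohort.yaml
cohort:
  n_slides: 12
  noise_sd: 0.5
  slide_kwargs: {width_px: 2048, height_px: 2048}
fov: {window_size_px: 32, window_stride_px: 8}
output_dir: demo_run
seed: 7
```

```
plaquescope run -c demo_cohort.yaml
```

This writes tidy CSVs plus a manifest with SHA-256 checksums of every
output (re-running with the same config and seed reproduces identical
checksums). The per-slide score table starts:

```
slide_id,pathology,region,blob_count,region_area_px,cnn_score
slide_000,cored,whole_tissue,0,9801,0
slide_000,cored,gray_matter,0,5841,0
```

(slide_000 was assigned level "none", so no deposits were planted and its
score is exactly 0). The statistics report shows the planted ordering is
recovered:

```
pathology,metric,value
cored,spearman_vs_level,0.989070710094
cored,anova_F,289.833333333
cored,anova_p,1.69387888301e-08
```

i.e. whole-tissue cored-plaque scores correlate with the planted ordinal
level at Spearman rho = 0.989, and the four level groups separate with
ANOVA F = 290 (p = 1.7e-8). The field-of-view convergence table for cored
plaques:

```
n,spearman
1,0.949247822527
3,0.980231652482
...
WT,0.989070710094
max_vs_WT,0.965852333338
```

reads: the single densest ~field correlates with severity at rho = 0.949,
averaging the top 3 non-overlapping fields improves this to 0.980, and the
whole-tissue score is best at 0.989 — the same qualitative ordering seen
when comparing traditional densest-field scoring against whole-slide
quantification.

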