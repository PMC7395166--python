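# berry3d

3D point-cloud phenotyping of **strawberry shape uniformity**.

Strawberry uniformity — how rotationally symmetric a berry is about its
growth axis — is a key fruit-quality trait in breeding programmes, yet it is
traditionally scored by eye on a 1–9 scale, which is subjective and
low-throughput. `berry3d` computes eight objective uniformity metrics from a
3D point cloud of a single berry sitting on a dark-blue foam holder, as
produced by Structure-from-Motion photogrammetry of a turntable rig. It is
aimed at phenomics pipelines in berry breeding: hundreds of clouds in, one
CSV row of metrics per berry out.

## The metrics

After pre-processing (see below) the berry body sits at the origin in
millimetres with its growth axis on z. From it:

| Metric | Definition | Ideal |
|---|---|---|
| `CV_A` | coefficient of variation (σ/μ) of the convex-hull areas of 100 side-view projections of the equatorial band (middle 50 % of body height), rotated 3.6° apart | 0 |
| `Max_A/Min_A` | max/min ratio of those areas | 1 |
| `CV_D` | CV of the principal-orientation angles of the 100 side views (axial angles, measured about their circular-mean axis with a +90° offset) | 0 |
| `L/W` | aspect ratio of the principal-axis-aligned bounding box of the largest of 100 horizontal slices | 1 |
| `CIR` | circularity `4πA/p²` of the largest slice's convex hull (A area, p perimeter) | 1 |
| `STR` | straightness of the centre axis: polyline length through the slice centroids over the middle 80 % of body height (80 slices), divided by the end-to-end distance | 1 |
| `CV_C` | CV of 16 patch curvatures; patches are seeded every 22.5° around the largest-slice contour, each patch value being the mean of the upper half of its members' average curvatures `(|k₁|+|k₂|)/2` from local quadric fits after moving-least-squares smoothing | 0 |
| `Max_C/Min_C` | max/min ratio of those 16 patch curvatures | 1 |

Pre-processing converts colours to HSV, removes stray reconstruction noise
by hue thresholding, centres the cloud on its centroid, aligns the principal
(largest-covariance-eigenvalue) axis with z with the holder pointing down,
segments berry from holder by hue, and rescales so the holder's z-extent
equals its known physical height (38 mm) — converting the arbitrary SfM
units to millimetres.

## Worked example

The package ships a parametric synthetic-berry generator, so everything can
be tried without imaging hardware:

```python
from berry3d import BerrySpec, generate, run_single

spec = BerrySpec(profile="berry", lobe_amplitude=0.2, lobe_count=2,
                 n_points=20_000, seed=103)     # a two-lobed berry
cloud, truth = generate(spec)                   # coloured cloud + ground truth
rec = run_single(cloud)
print(rec.cv_a, rec.max_min_a, rec.cir, rec.cv_c)
```

prints (deterministically):

```
0.12533739191420967 1.4989395087519035 0.9441027313251871 0.29143492998508375
```

The two lobes (radius modulated by `1 + 0.2·cos 2θ`) make opposite side
views differ by a factor `1.2/0.8 = 1.5` in width — recovered as
`Max_A/Min_A = 1.499`. The slice hull bridges the lobe waists, so `CIR`
drops to 0.944, and the lobed surface spreads the patch curvatures
(`CV_C = 0.291`). A perfectly uniform berry scores 0 / 1 / 1 / 0 on these.

From a shell, the same pipeline runs over a directory of PLY files:

```sh
berry3d fixtures --out fixtures/          # write 6 synthetic test berries
berry3d run --input fixtures/ --out metrics.csv
berry3d dump-config > run.yaml            # all tunables, editable
```

`metrics.csv` has one row per cloud with the eight metrics, body height,
point count, quality flags and a hash of the effective configuration; a
failed cloud yields an error row instead of aborting the batch.

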