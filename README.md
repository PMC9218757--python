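# rgbdfruit

Locate and recognize green, near-background-colour spherical fruit (think
Gala or Granny Smith apples before ripening) in registered RGB-D image
pairs, without training data or a classifier.

Colour alone cannot separate a green apple from the canopy behind it.
`rgbdfruit` therefore fuses two independent cues:

1. **Center location from depth.** A fruit facing the camera is a convex
   depth bowl, so its depth gradient field ∇D = (∂D/∂x, ∂D/∂y) points
   radially outward from the fruit center. Rotating every vector 90°
   clockwise turns that diverging field into a vortex, and the scalar
   vorticity (curl) ω = ∂v/∂x − ∂u/∂y of the rotated, direction-emphasised
   field peaks exactly at the fruit center, while cluttered background
   circulation averages out. Fruit centers are the thresholded,
   non-maximum-suppressed peaks of a scale-normalized multi-scale
   vorticity response.
2. **Region segmentation from colour.** The RGB frame is partitioned into
   SLIC superpixels using the combined Lab/spatial distance
   `Dis = sqrt(dc² + (ds/S)²·m²)`; each block contributes one feature
   point (mean R−B, mean G−B). The blocks are clustered by density-peak
   clustering: local density ρᵢ from a Gaussian kernel density estimate
   (no hand-set cutoff distance), separation δᵢ to the nearest denser
   point, automatic center selection by double sorting (densest blocks
   first, most separated among them second), one-pass chain assignment
   along nearest-denser-neighbour links, and pruning of all but the
   largest clusters by pixel coverage.

The segment component that contains a detected center is that fruit's
region. The radius is the maximum of the center-to-boundary distance
profile for an isolated fruit, or the minimum over the profile's local
maxima when several centers share one component (overlapping fruit).
Output is one fitted circle per fruit.

Because the data the approach was designed around (Kinect V2 orchard
pairs) is not public, the package ships a synthetic scene generator
(`rgbdfruit.synthetic_scenes`) that renders close-range RGB-D frames with
exact ground truth: convex fruit in depth with sensor noise and holes,
near-colour canopy backgrounds (fruit/foliage/branch means within 15
intensity units per channel), and single / branch-occluded / overlapping
configurations.

## Worked example

```
rgbdfruit simulate --n 3 --seed 7 --out-dir demo/scenes
for d in demo/scenes/scene_*; do
    rgbdfruit detect --rgb $d/rgb.png --depth $d/depth.png \
        --out-dir demo/dets/$(basename $d)
done
rgbdfruit evaluate --detections-dir demo/dets --truth-dir demo/scenes
```

prints

```
category           n  matched   rate %
occluded           1        1   100.00
overlapping        2        2   100.00
single             1        1   100.00
total              4        4   100.00
mean center error: 3.14 px; mean radius error: 10.18%
```

Three simulated scenes contained four fruit (one single, one occluded by
a branch, one overlapping pair); every one was recognized — a detection
counts when its center lies inside the true circle and the circle IoU is
at least 0.5 — with centers on average 3.1 px off and radii 10% off.
Each detection run also writes `detections.csv`/`.json` (center_x,
center_y, radius_px per circle), an `overlay.png` with the fitted circles
drawn on the RGB frame, and a `manifest.json` recording the exact
configuration and seed, so a run can be reproduced bit for bit.

The same pipeline is available as a library:

```python
from rgbdfruit import PipelineConfig, detect_fruits, read_rgbd_pair

rgb, depth = read_rgbd_pair("rgb.png", "depth.png")
result = detect_fruits(rgb, depth, PipelineConfig())
for det in result.detections:
    print(det.center, det.radius)
```

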