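# hemseg

Automatic detection of retinal hemorrhages in color fundus photographs.

Hemorrhages (HEs) are dark blood leaks in the retina and an early sign of
diabetic retinopathy. Two kinds are notoriously hard for automatic
screening: HEs adjoined to blood vessels (which share their dark, smooth
appearance) and HEs at the retinal rim, where they blend into the black
frame outside the camera's field of view. `hemseg` implements a detection
pipeline built around those two cases:

1. **Enhancement** — CLAHE, gradient-adaptive gamma correction, and a
   nonlinear (fuzzy) unsharp mask on the green channel.
2. **Calibration** — the field-of-view disc is estimated, and the black
   background plus a thin border ring are saturated to white, so rim
   lesions become dark objects on a bright surround.
3. **Seed points** — an inverted-Gaussian matched filter
   `1 − exp(−r²/2σ²)` (high response at dark blob centers), thresholded by
   a co-occurrence-matrix entropy criterion, then morphologically opened to
   break the vasculature.
4. **SWAT segmentation** (smart-window adaptive thresholding) — per seed,
   a window is repeatedly partitioned into R intensity regions by
   maximizing the between-region variance
   σ_B² = Σ_z ω_z (μ_z − μ_T)², with R grown until the effectiveness
   η = σ_B²/σ_T² reaches 0.8 (R ≤ 20). The darkest stratum is kept, the
   two largest components are retained, the one nearest the window center
   is selected, and the window grows directionally (left/top −5 px,
   right/bottom +10 px) on sides the object touches, bounded by a search
   space (FOV dilated by 80 px), until the object fits.
5. **Classification** — shape, edge, texture, color and contour features
   feed an SVM that separates hemorrhages from vessels and illumination
   shades; evaluation reports sensitivity SE = TP/(TP+FN) and specificity
   SP = TN/(TN+FP).

A built-in synthetic fundus generator (`hemseg.synth`) produces images
with known lesion ground truth — including vessel-attached and
border-touching lesions — so the whole pipeline is testable without any
dataset download. See `docs/methods.md` for the model details and the
generator's design.

## Worked example

Generate a synthetic fundus image and run the detector on it:

```bash
hemseg synth --out demo/ --n 1 --seed 5
hemseg detect demo/sample_000.png --out-dir demo/det
```

or from Python:

```python
from hemseg.synth import SynthConfig, generate_sample, save_sample
from hemseg.pipeline import detect

save_sample(generate_sample(SynthConfig(rng_seed=5)), "demo", stem="fundus")
report = detect("demo/fundus.png", out_dir="demo/det")
print(report["n_seeds"], report["n_candidates"])
```

This prints `13 7`: the matched filter proposed 13 seed windows, and SWAT
segmented 7 distinct candidate objects after deduplication. The first
candidate rows (also written to `demo/det/candidates.csv`) look like:

```
object_id  seed_id  v1   v2   v3   v4   area  center_distance  converged
0          0        66   125  110  165  362   0.0              True
1          1        126  169  183  221  1333  0.5              True
2          2        317  207  357  251  605   0.0              True
```

`(v1, v2, v3, v4)` are the final window vertices (left column, top row,
right column, bottom row) after growth; `area` is the segmented object's
pixel count; `center_distance` is its minimum distance to the window
center (0 for an object covering it); `converged` says the window stopped
because the object no longer touched any side. `demo/det/overlay.png`
shows the boxes on the image. With a trained model passed to `detect`,
each candidate also carries an HE / non-HE label; `hemseg evaluate` runs
the full synthetic training/evaluation study and prints SE/SP.

The stagewise subcommands (`preprocess`, `calibrate`, `seeds`, `segment`)
expose every intermediate product as PNG/CSV for inspection.

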