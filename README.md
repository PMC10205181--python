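# sparkmap

Correlative analysis of Ca²⁺ sparks and nanoscale RyR2 channel organization
in cardiomyocytes.

Spontaneous Ca²⁺ sparks — transient (~30–100 ms), localized (1–6 µm FWHM)
release events from clusters of type-2 ryanodine receptors (RyR2) — can be
recorded as 2D TIRF time series and, after fixation, the *same cell's* RyR2
channels can be mapped at ~10 nm resolution with DNA-PAINT. `sparkmap`
implements the full computational chain that links the two modalities:

1. **Spark detection and quantification** (`sparkmap.sparks`) — baseline
   estimation, detection of dF/F₀ excursions, symmetric 2D Gaussian fits,
   the 1.0–6.0 µm FWHM / R² retention filter, and spark mass
   `1.206 · (F/F₀) · FWHM³`.
2. **Localization microscopy** (`sparkmap.paint`) — single-molecule event
   fitting, 5 nm/px density rendering, RyR2 punctum detection, and cluster
   segmentation by a global threshold capturing 80% of the above-background
   labelling intensity.
3. **Registration** (`sparkmap.align`) — averaging ~10 Ca²⁺ frames into a
   low-noise reference, upscaling to the rendering grid, and sub-pixel
   normalized cross-correlation; plus simulations of the expected
   registration error (<100 nm at 250 nm resolution, SNR 17) and of the
   ~25-fold resolution gain of the rendering over TIRF.
4. **Spark-footprint statistics** (`sparkmap.footprint`) — RyR2 count,
   unique-cluster count, nearest-neighbour (NND) and three-nearest (3ND)
   distances inside a circular window of diameter equal to each spark's
   FWHM; mass-to-count ratios, quadratic mass-vs-count fits, Mann–Whitney U
   and Bartlett comparisons, per-cluster spark-mass maps.
5. **Recurring spark sites** (`sparkmap.sites`) — quadtree density
   segmentation of spark centroids over 15 s windows and site–cluster
   overlap.
6. **Null models** (`sparkmap.nullmodels`) — uniform randomization of RyR2
   or spark positions within the cell footprint, with histogram/KS
   comparisons.
7. **Synthetic scenes** (`sparkmap.synthetic`) — ground-truthed generator of
   sarcomeric RyR2 maps (intra-cluster NND calibrated to 38.23 nm, 90%
   labelling efficiency), DNA-PAINT tables and SNR-17 spark movies, so the
   whole chain is testable without raw imaging data.

`sparkmap.pipeline` orchestrates everything end to end, and a `sparkmap`
CLI exposes `simulate`, `detect-sparks`, `paint`, `align`, `footprint`,
`sites`, `null` and `run` subcommands.

## Worked example

Run the full correlative workflow on a synthetic healthy-like cell:

```bash
sparkmap run --seed 11 --out out/
```

which logs (with `-v`) and writes, among other outputs:

```
stage=sparks in=36 out=35
stage=paint in=6482 out=427
stage=align in=None out=1
stage=footprint in=35 out=35
stage=sites in=35 out=2
```

Here 36 spark candidates were detected in the 15 s movie and 35 survived
the FWHM/R² filter; 6 482 DNA-PAINT localizations rendered into 427 RyR2
puncta in 33 segmented clusters; the Ca²⁺ reference was registered to the
rendering with a recovered shift of (316.7, −215.0) nm against a simulated
true offset of (300, −200) nm — a 22 nm registration error. The footprint
summary (`out/summary.json`) reports a mean of 17.4 RyR2 puncta and 1.2
qualifying clusters under each spark, and two recurring spark sites were
segmented within the 15 s window. `out/samples.csv` holds the per-spark
table (`spark_id, ryr_count, cluster_count, nnd_nm, tnd_nm, mass,
mass_ratio`).

The same objects are available from Python:

```python
from sparkmap import pipeline, synthetic

cfg = pipeline.RunConfig(seed=11, scene=synthetic.ctrl_like(11),
                         movie=synthetic.SparkMovieParams(seed=11))
res = pipeline.run_correlative(cfg, "out/")
res["samples"].head()
```

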