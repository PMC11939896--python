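# chromaflow

Smartphone colorimetric quantification of kidney-function biomarkers —
uric acid, creatinine and albumin — from photographs of a reagent-filled
flow cell.

A reagent reacts with blood serum to produce a colored product
(quinoneimine for uric acid, the yellow Jaffe complex for creatinine, the
green bromocresol-green complex for albumin) whose depth of color tracks
the analyte concentration. A phone camera photographs the flow cell under
diffused LED light; this package turns those photographs into
concentrations:

1. **Imaging** — each frame is standardized to a common resolution,
   optionally gray-world white-balanced, cropped to a 50 × 50-pixel region
   of interest over the flow cell, and spatially averaged to one mean RGB
   triple.
2. **Photometry** — the blank (reagent-only) frame supplies the incident
   intensity *I₀*; a sample frame supplies the transmitted intensity
   *I_t*; absorbance follows the Beer-Lambert law on the assay's
   measurement channel:

   *A* = −log₁₀(*I_t* / *I₀*)

3. **Adaptive calibration** — every session re-derives its own factor:
   a water frame must show |*A*| ≈ 0 (contamination gate), the blank sets
   the baseline, and a single standard of known concentration *C*_std
   gives *F* = *C*_std / *A*_std. Unknowns are then *C* = *A*·*F*.
   Because the phone's gain, the LED intensity and the reagent batch all
   cancel either in the blank ratio or in the standard ratio, the result
   is device-, brand- and lighting-independent.
4. **Metrics** — the validation statistics of clinical chemistry:
   LoD = *n*·sd/slope, %CV = 100·sd/mean (intra/inter repeatability),
   spike recovery % = (measured − baseline)/spike × 100, cross-condition
   average variation %, and method-comparison summaries against a
   reference analyzer.

No public image dataset exists for this kind of device, so the package
includes a forward model (`synthgen`) that renders flow-cell frames with
Beer-Lambert channel attenuation, per-device gains, illumination scale and
gradient, and Gaussian sensor noise — every pipeline stage is testable
end-to-end without hardware.

## Worked example

Simulate a noise-perturbed dataset, calibrate, and measure:

```bash
chromaflow simulate --assay uric_acid --concentrations 2,4,8,12,20 \
    --replicates 1 --single-scene --noise-sd 0.5 --out data --seed 42
# wrote 8 images (1 scene(s)) to data

chromaflow calibrate --assay uric_acid \
    --water data/s00_water.png --blank data/s00_blank.png \
    --standard data/s00_standard.png --store store.json
# calibrated uric_acid: factor 19.9832 mg/dL/AU

chromaflow measure --assay uric_acid --manifest data/manifest.csv \
    --store store.json --use-stored --out results.csv
# wrote 5 result(s) to results.csv
```

`results.csv` then contains (abridged):

```
    value  units  absorbance    inference  in_linear_range  true_concentration
 2.001900  mg/dL    0.100179 no_reference             True                 2.0
 4.000425  mg/dL    0.200190 no_reference             True                 4.0
 8.005346  mg/dL    0.400604 no_reference             True                 8.0
12.003548  mg/dL    0.600683 no_reference             True                12.0
19.956121  mg/dL    0.998647 no_reference             True                20.0
```

The calibration factor ≈ 20 mg/dL per AU is the reciprocal of the
standard's absorbance slope (the 8 mg/dL uric-acid standard renders at
0.4 AU), and each estimate recovers its ground truth to well under 1 %
despite pixel noise and 8-bit PNG quantization. `inference` compares the
value against the assay's serum reference interval where one is defined
(creatinine 0.6–1.3 mg/dL, albumin 3.7–5.8 g/dL); `in_linear_range`
flags results outside the assay's validated range (uric acid
1–30 mg/dL, creatinine 0.1–20 mg/dL, albumin 0.1–8 g/dL).

Exit codes: 0 ok, 2 usage, 3 must-calibrate (no stored factor, or
`--use-stored` not given), 4 water-check failure, 5 I/O error.

`chromaflow report` regenerates the validation summaries (variation,
recovery, repeatability, method comparison) from CSV inputs; see
`chromaflow report --help`.

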