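# aortacad

Screening of contrast-enhanced axial CT slices for signs of aortic
disease. The pipeline has four stages:

1. **Segmentation** — the contrast-filled aortic lumen is extracted per
   slice by inclusive HU-range thresholding (default 200–500 HU) and
   8-connected component labeling, then linked slice-to-slice by seeded
   nearest-centroid tracking (labels: ascending / descending).
2. **Shape classification** — each cross-section's boundary is tested
   for circle-likeness with a gradient-pair criterion: boundary pixel
   pairs must have opposed Sobel gradient angles, a gradient aligned
   with the chord between them, and a chord passing through the
   centroid. If fewer than 60% of boundary pixels participate in a
   satisfying pair, the object is flagged as a dissection candidate.
3. **PAU detection** — connected components of pixels strictly above
   the lumen HU range lying inside the filled aortic contour are
   flagged as penetrating-aortic-ulcer candidates.
4. **Evaluation** — per-object decisions are tallied into TP/FP/TN/FN
   with sensitivity and specificity reported to 4 decimals.

A synthetic phantom generator (`aortacad.phantom`) produces slice stacks
with ground truth — healthy disks, flap-split or elliptical dissection
cross-sections, and hyperintense wall-adjacent blobs — so every stage is
testable without patient data.

## CLI

```sh
# generate a 30-slice phantom (10 healthy, 10 dissection, 10 PAU)
aortacad make-phantom --out ph --n-slices 30 --kind mixed --noise-sd 8

# a config file carries the seeds and any non-default parameter
cat > cfg.yaml <<EOF
seeds: {descending: [64, 64]}
hu_range: [200, 500]
circle_threshold: 0.6
EOF

# run both diagnostic pipelines; truth enables confusion summaries
aortacad run-all --input ph/series --out results \
    --config cfg.yaml --truth ph/truth.csv
```

Outputs: `report.csv` (one row per slice and vessel: circle score,
shape label, PAU candidate count, peak HU), overlay PNGs for flagged
slices, `summary_<task>.csv` confusion tables, and a run log recording
every parameter. Other subcommands: `segment`, `detect-dissection`,
`detect-pau`, `evaluate`.

## Defaults

| parameter | default |
|---|---|
| lumen HU range | 200–500 (inclusive) |
| PAU threshold | HU > 500 (strict) |
| circle-likeness threshold | 0.60 (inclusive) |
| pair angle tolerance | 10° |
| centroid-line tolerance | 2 px |
| min lumen component | 50 px |
| min PAU component | 3 px |
| tracking continuity limit | 20 px |

The aortic arch is out of scope: its cross-section needs multiplanar
reconstruction, so arch objects are never labeled and unlinkable
components are reported as `unlinked`; tracking failures are reported
as gaps rather than dropped.
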