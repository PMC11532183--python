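# fibroquant

Quantification of liver fibrosis from Sirius-Red (SR)-stained biopsy
sections, for hepato-pathology image analysts working on MASH
(metabolic dysfunction-associated steatohepatitis).

Semi-quantitative fibrosis staging (NASH CRN: F1a/F1b/F1c/F2/F3/F4) is
reproducible only moderately between pathologists and compresses a
continuous process into a handful of categories, which makes small
treatment-induced changes invisible. `fibroquant` measures fibrosis on a
continuous scale instead:

- **ECA** (Estimated Collagen Area): the percentage of tissue pixels that
  are SR-positive collagen,
  `ECA = 100 · |collagen| / |tissue|` — the digital analogue of the
  Collagen Proportionate Area;
- **EnC** (Entropy of Collagen): the mean local Shannon entropy of the SR
  optical density, `EnC = mean_p H(hist_w(OD_q)(p))` over tissue pixels,
  where `OD_q` is the 8-bin quantized SR optical density and `hist_w` the
  histogram over a 9×9 window — low EnC means uniform, compact collagen;
  high EnC means disordered, fragmented fibrosis.

Around those two features the package provides: OD-space collagen
segmentation (with Otsu or explicit thresholds and configurable stain
vectors), a ~30-feature ROI battery with heatmap rendering, Fleiss-kappa
inter-rater agreement with Landis–Koch bands, stage-wise ANOVA + Tukey
statistics, a paired pre/post treatment-response classifier (a patient is
an *AI responder* when ECA and EnC both strictly decreased), and a
synthetic SR-slide generator with exact ground-truth masks so the whole
pipeline is testable without any real whole-slide image.

## Worked example

Generate a synthetic biopsy with a known 5.7% collagen fraction (an
F3-like slide), then measure it:

```sh
$ fibroquant synth --out demo.png --fraction 0.057 --disorder 0.3 --seed 7 --size 512
wrote demo.png (true fraction 0.0570)
$ fibroquant features --in demo.png --out demo_features.csv
ECA 5.70%  EnC 0.079
```

The measured ECA recovers the generator's ground truth exactly (the
segmentation is pixel-perfect on noiseless synthetic slides); the EnC is
low because a noiseless slide is textureless outside collagen edges.
`demo_features.csv` holds the full extended battery for the slide.

Classify the packaged paired pre/post-treatment cohorts (9 study + 8
validation pairs):

```sh
$ fibroquant response --fixtures
{
  "n_pairs": 17,
  "histo_decrease_percent": 29,
  "histo_no_change_percent": 47,
  "histo_increase_percent": 24,
  "ai_responder_percent": 53,
  "ai_non_responder_percent": 24,
  "ai_not_conclusive_percent": 24,
  "ai_congruous_change_percent": 76,
  ...
}
```

Read: histopathology calls 29% of patients responders (stage decreased)
and is not conclusive for 47% (stage unchanged), while the joint ECA+EnC
rule calls 53% responders and finds a congruous fibrosis change in 76% of
patients — the continuous features detect treatment effects the categorical
stage cannot.

Other verbs: `fibroquant segment`, `fibroquant agree --ratings ratings.csv
[--coarse]`, `fibroquant stats`, `fibroquant run` (full pipeline with a
JSON config; outputs carry the config hash and runs are byte-reproducible
under a fixed seed).

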