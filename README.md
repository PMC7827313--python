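# hevscape

Automated morphometry of lymph-node **high endothelial venules (HEVs)** and
their perivascular stroma from multiplex immunofluorescence images — the
vascular remodeling readouts that distinguish tumor-draining lymph nodes of
invasive breast cancer from non-invasive disease and healthy controls.

HEVs (PNAd⁺/Claudin-5⁺ venules of the T-cell zone) are the entry ports for
naïve lymphocytes; in invasive cancer they dilate, their cuboidal
endothelium thins, PNAd expression becomes discontinuous, and the
CCL21⁺/αSMA⁺ fibroblastic reticular cells lining them lose CCL21 and
heparan sulfate while CCL21-saturated lymphocytes accumulate nearby.
`hevscape` measures all of this per vessel and per node:

* **Regions** — LN tissue from DAPI (intensity window 6–255), tumor foci
  from cytokeratin (35–255), metastatic burden (% of LN area), and the
  CCL21-defined paracortex with a 200 µm exclusion zone around tumor and
  fat. Vessels are zoned PARACORTICAL / MA (≤ 200 µm from a focus) /
  IM (inside a focus) / EXCLUDED.
* **Vessel morphometry** — lumen diameter *d* as the inscribed-circle
  diameter (2 × max distance-transform on the lumen medial axis, averaged
  over ≤ 3 medial-axis maxima), dilation class
  (closed → NON, *d* < 10 µm → INT, *d* ≥ 10 µm → HIGH), endothelial
  thickness (2 × EDT along the wall medial axis; thin if < 3 µm), and PNAd
  perimeter coverage with a discontinuity flag (coverage < 0.9 **and** a
  contiguous ≥ 10 µm negative arc).
* **Perivascular scoring** — angular coverage of CCL21 / αSMA / heparan
  sulfate in a 10 µm ring outside the wall, categorized
  CONTINUOUS (≥ 0.8) / PARTIAL / NONE (≤ 0.1); per-LN CCL21 morphology
  (reticular vs. immune-cell) from the fraction of CCL21⁺ area in
  lymphocyte-shaped blobs; CD3 co-positivity of the CCL21⁺/αSMA⁻ blobs
  around highly dilated vessels (100% / >50% / <50% / 0%).
* **Cohort statistics** — per-LN aggregation (HEVs/mm² paracortex, class
  fractions, category fractions by zone) and a normality-gated battery:
  ANOVA + Holm-Sidak or Kruskal-Wallis + Dunn (Holm), t / Mann-Whitney /
  Wilcoxon, Spearman for correlations.
* **Synthetic cohorts** — a generator that renders multichannel LN images
  (elliptical vessel annuli, reticular stroma, tumor foci, CCL21-rimmed
  lymphocyte blobs, additive noise) with exhaustive ground truth, plus four
  packaged group profiles (organ donor, DCIS, invasive carcinoma without /
  with nodal metastasis) whose generative probabilities encode the
  published group-level fractions.

See `docs/methods.md` for the measurement model, every threshold and its
rationale, and what the synthetic data does and does not demonstrate.

## Worked example

Simulate a tiny two-node cohort, analyze it, and read the tables:

```bash
# mini.yaml = packaged "od" profile with lns: 2, vessels_per_ln: 10, image_px: 700
hevscape simulate --profile mini.yaml --seed 11 --out sim
hevscape run --manifest sim --out analysis
```

which prints

```
wrote 2 LN images to sim (profile mini, seed 11)
analyzed 2 LNs, 20 vessels -> analysis
```

and writes `analysis/vessels.csv` (one row per vessel), `analysis/lns.csv`
(one row per node) and `analysis/run_manifest.json` (every threshold used).
The per-LN table for this run:

```
     ln_id  n_paracortical  paracortex_area_mm2  hev_per_mm2  pct_dilated  pct_high ccl21_morphology
mini_ln000              10                 0.08      124.557         10.0      10.0        RETICULAR
mini_ln001              10                 0.08      124.574         10.0       0.0        RETICULAR
```

Each node contributed 10 paracortical HEVs over 0.08 mm² of CCL21⁺
paracortex (≈ 125 HEVs/mm²); 10% of vessels are dilated — the organ-donor
profile's generative rate — and CCL21 staining has normal reticular (FRC)
morphology. In `vessels.csv`, a row like

```
mini_ln000  2  PARACORTICAL  0.0  NON  8.54  1.0  CONTINUOUS
```

is a non-dilated vessel (closed lumen, diameter 0), fully PNAd-continuous
(coverage 1.0) with continuous perivascular CCL21.

Group comparisons on a finished cohort table:

```bash
hevscape stats --table analysis/lns.csv --design design.yaml --out tests.csv
```

where the design YAML lists endpoints, e.g.
`- {endpoint: pct_dilated, kind: groups, group_col: group}`.

## Library use

```python
import numpy as np
from hevscape import AnalysisConfig, load_profile, generate_ln, analyze_ln

profile = load_profile("idc_met_pos")
sample = generate_ln(profile, np.random.default_rng(1), ln_id="ln0")
records, ln_row, regions = analyze_ln(sample.image, AnalysisConfig(),
                                      ln_id="ln0", group=profile.name)
```

`records` are per-vessel `VesselRecord`s (masks, diameter, class, scores),
`ln_row` the aggregated per-LN row, and `sample.truth` the generator's
ground truth for comparison.
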