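# Cancer-free organ donors: 15 LNs, ~10% dilated HEVs, intact stroma.
name: OD
lns: 15
vessels_per_ln: 110
p_class: {NON: 0.90, INT: 0.06, HIGH: 0.04}
diameter_range_by_class:
  INT: [5.5, 8.5]
  HIGH: [13.0, 28.0]
p_thin_by_class: {NON: 0.0, INT: 0.03, HIGH: 0.10}
p_pnad_discont_by_class: {NON: 0.01, INT: 0.03, HIGH: 0.10}
ccl21_score_probs_by_class:
  NON: {CONTINUOUS: 0.90, PARTIAL: 0.08, NONE: 0.02}
  INT: {CONTINUOUS: 0.85, PARTIAL: 0.12, NONE: 0.03}
  HIGH: {CONTINUOUS: 0.80, PARTIAL: 0.15, NONE: 0.05}
asma_score_probs: {CONTINUOUS: 0.70, PARTIAL: 0.30, NONE: 0.0}
hs_loss_probs_by_class:
  NON: {CONTINUOUS: 0.90, PARTIAL: 0.08, NONE: 0.02}
  INT: {CONTINUOUS: 0.88, PARTIAL: 0.09, NONE: 0.03}
  HIGH: {CONTINUOUS: 0.85, PARTIAL: 0.11, NONE: 0.04}
p_lymphocyte_phenotype: 0.0
cd3_category_probs: {"100": 0.40, ">50": 0.35, "<50": 0.20, "0": 0.05}
metastasis: null
image_px: 1792
um_per_px: 0.5
noise_sd: 8.0
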