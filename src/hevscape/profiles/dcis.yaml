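# Non-invasive ductal carcinoma in situ: 19 LNs, ~34% dilated HEVs,
# CCL21 largely confined to aSMA+ FRCs; immune-cell CCL21 morphology rare (5%).
name: DCIS
lns: 19
vessels_per_ln: 110
p_class: {NON: 0.66, INT: 0.20, HIGH: 0.14}
diameter_range_by_class:
  INT: [5.5, 8.5]
  HIGH: [13.0, 28.0]
p_thin_by_class: {NON: 0.0, INT: 0.05, HIGH: 0.15}
p_pnad_discont_by_class: {NON: 0.01, INT: 0.05, HIGH: 0.12}
ccl21_score_probs_by_class:
  NON: {CONTINUOUS: 0.80, PARTIAL: 0.18, NONE: 0.02}
  INT: {CONTINUOUS: 0.75, PARTIAL: 0.20, NONE: 0.05}
  HIGH: {CONTINUOUS: 0.70, PARTIAL: 0.22, NONE: 0.08}
asma_score_probs: {CONTINUOUS: 0.70, PARTIAL: 0.30, NONE: 0.0}
hs_loss_probs_by_class:
  NON: {CONTINUOUS: 0.85, PARTIAL: 0.12, NONE: 0.03}
  INT: {CONTINUOUS: 0.80, PARTIAL: 0.15, NONE: 0.05}
  HIGH: {CONTINUOUS: 0.75, PARTIAL: 0.18, NONE: 0.07}
p_lymphocyte_phenotype: 0.05
cd3_category_probs: {"100": 0.40, ">50": 0.35, "<50": 0.20, "0": 0.05}
metastasis: null
image_px: 1792
um_per_px: 0.5
noise_sd: 8.0
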