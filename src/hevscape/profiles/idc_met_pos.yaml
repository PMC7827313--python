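# Invasive ductal carcinoma with nodal metastasis: 25 LNs, ~49% dilated
# paracortical HEVs, a metastatic focus per section with MA/IM vessels
# (CCL21-none 35% / 87%), 55% of LNs with immune-cell CCL21 morphology.
name: IDCmet+
lns: 25
vessels_per_ln: 70
p_class: {NON: 0.51, INT: 0.24, HIGH: 0.25}
diameter_range_by_class:
  INT: [5.5, 8.5]
  HIGH: [13.0, 28.0]
p_thin_by_class: {NON: 0.0, INT: 0.10, HIGH: 0.35}
p_pnad_discont_by_class: {NON: 0.02, INT: 0.08, HIGH: 0.30}
ccl21_score_probs_by_class:
  NON: {CONTINUOUS: 0.70, PARTIAL: 0.25, NONE: 0.05}
  INT: {CONTINUOUS: 0.60, PARTIAL: 0.30, NONE: 0.10}
  HIGH: {CONTINUOUS: 0.30, PARTIAL: 0.28, NONE: 0.42}
asma_score_probs: {CONTINUOUS: 0.65, PARTIAL: 0.35, NONE: 0.0}
hs_loss_probs_by_class:
  NON: {CONTINUOUS: 0.70, PARTIAL: 0.22, NONE: 0.08}
  INT: {CONTINUOUS: 0.55, PARTIAL: 0.30, NONE: 0.15}
  HIGH: {CONTINUOUS: 0.25, PARTIAL: 0.40, NONE: 0.35}
p_lymphocyte_phenotype: 0.55
cd3_category_probs: {"100": 0.35, ">50": 0.30, "<50": 0.20, "0": 0.15}
metastasis:
  n_foci: 1
  focus_radius_um: [85.0, 110.0]
  ma_per_focus: 12.0
  im_per_focus: 4.0
  p_ccl21_none_im: 0.87
  p_ccl21_none_ma: 0.35
  p_class_ma: {NON: 0.51, INT: 0.24, HIGH: 0.25}
  p_class_im: {NON: 0.60, INT: 0.25, HIGH: 0.15}
image_px: 2304
um_per_px: 0.5
noise_sd: 8.0
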