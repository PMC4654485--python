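{
  "summary": "Provenance of the shipped 91-parameter registry. The published supplementary reaction/parameter tables were not available as machine-readable input, so the registry was recovered by constrained calibration: class-median priors for turnover/translation/level parameters, literature-scale oxygen-sensing constants, and least-squares fitting of the remaining free parameters against the quantitative anchors printed in the validation experiments.",
  "contingency": "The two validation fold-changes below are calibration constraints that the shipped configuration then reproduces, not blind predictions.",
  "anchors": [
    {"quantity": "total intracellular VEGF fold-change", "condition": "2% O2, 24 h", "target": 3.5, "reproduced": 3.50},
    {"quantity": "VEGF protein fold-change", "condition": "1% O2, 8 h", "target": 2.0, "reproduced": 2.00},
    {"quantity": "total HIF-1a overshoot peak time", "condition": "2% O2", "target_range_h": [5, 14], "reproduced_h": 7.8},
    {"quantity": "total AGO1 relative expression", "condition": "2% O2, 48 h", "target": "below 1 after a delay", "reproduced": 0.83},
    {"quantity": "tumor-screen VEGF suppression (saturating dose, 0.5-2% O2)", "target": ">= 3-fold", "strategy": "AGO1 overexpression"},
    {"quantity": "PAD combined-therapy VEGF enhancement", "target": "> 2-fold"}
  ],
  "free_parameter_subsets": [
    {"stage": "oxygen sensing / HIF module", "parameters": ["kf_phd2_o2", "kr_phd2_o2", "kf_fih_o2", "kr_fih_o2", "k_hyd_phd2", "k_hyd_fih", "kf_dimer", "kf_hif_import", "a_ttp_hif_mrna", "kd_ttp_mrna", "kd_ttp", "Vm_ttp", "K_ttp", "basal_ttp"], "anchored_to": "HIF overshoot near 10 h with decline; monotone O2 gradation; TTP-siRNA overshoot lengthening"},
    {"stage": "let-7 / AGO1 / Dicer arm", "parameters": ["Vm_let7", "kp21", "basal_let7", "kf_let7_ago1", "kr_let7_ago1", "kd_let7_free", "kd_let7_ago1", "kd_ago1", "kd_dicer", "k_pbody_ago1", "k_pbody_dicer", "ks_ago1_mrna", "ks_dicer_mrna"], "anchored_to": "delayed AGO1 decline in hypoxia; let-7 induction; p-body shuttling of overexpressed AGO1 mRNA within hours"},
    {"stage": "miR-15a / VEGF arm", "parameters": ["ks_pre_mir15a", "kd_pre_mir15a", "kcat_dicer_mir15a", "kf_mir15a_ago1", "kr_mir15a_ago1", "kd_mir15a_free", "kd_mir15a_risc", "kf_vegf_risc", "kr_vegf_risc", "k_pbody_vegf", "Vm_vegf", "K_vegf", "n_vegf", "kd_vegf", "basal_vegf", "a_ttp_vegf_mrna"], "anchored_to": "the two VEGF fold anchors; free-VEGF-mRNA fraction decreasing with O2; screen fold directions"}
  ],
  "final_refit": {
    "free_parameters": ["Vm_vegf", "kd_vegf", "basal_vegf"],
    "objective": "squared relative error of the two VEGF fold anchors",
    "method": "scipy.optimize.least_squares (trf, log-parameters)",
    "residuals_at_optimum": [-2.5e-05, -0.00064]
  }
}
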