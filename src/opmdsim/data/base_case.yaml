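# Base-case model parameters with low/high deterministic-sensitivity ranges.
# Annual probabilities are converted to 1-month cycle probabilities inside the
# model via constant-hazard compounding.  Rows whose published range is
# 0.5x-2x the base-case estimate are written out explicitly (clipped to 1).

# --- initial lesion-state mixture among detected OPMDs ---
prevalence_malignant: {value: 0.05, low: 0.02, high: 0.075}
prevalence_mild: {value: 0.1154, low: 0.05, high: 0.17}
prevalence_moderate: {value: 0.0440, low: 0.03, high: 0.06}
prevalence_severe: {value: 0.0288, low: 0.015, high: 0.05}
p_early_given_cancer: {value: 0.2731, low: 0.13655, high: 0.5462}

# --- natural history (annual probabilities unless noted) ---
p_regress_mild_benign: {value: 0.04, low: 0.02, high: 0.08}
p_mild_to_moderate: {value: 0.0003, low: 0.00015, high: 0.0006}
p_mt_moderate: {value: 0.035, low: 0.0175, high: 0.07}
p_mt_low_risk: {value: 0.029, low: 0.0145, high: 0.058}
p_mt_high_risk: {value: 0.040, low: 0.02, high: 0.08}
p_mt_severe: {value: 0.084, low: 0.042, high: 0.168}
p_early_to_late: {value: 0.046, low: 0.023, high: 0.092}
p_late_to_mets: {value: 0.391, low: 0.1955, high: 0.782}
p_death_mets: {value: 0.127, low: 0.0635, high: 0.254}

# --- care-seeking, adherence, procedures ---
p_surgical_mortality: {value: 0.002, low: 0.001, high: 0.004}  # per procedure
p_visual_exam_no_screen_localized: {value: 0.13, low: 0.065, high: 0.26}  # annual
p_present_visual_no_screen_symptomatic: {value: 0.30, low: 0.15, high: 0.45}  # annual
adherence_surveillance: {value: [0.92, 0.82, 0.72], low: 0.5, high: 1.0}  # per visit
adherence_biopsy: {value: 0.92, low: 0.5, high: 1.0}
p_rebiopsy_prior_benign: {value: 0.20, low: 0.10, high: 0.40}

# --- test operating characteristics ---
sens_pococt_benign_mild: {value: 0.90, low: 0.86, high: 0.92}
spec_pococt_benign_mild: {value: 0.57, low: 0.52, high: 0.62}
sens_pococt_mild_moderate: {value: 0.90, low: 0.86, high: 0.92}
spec_pococt_mild_moderate: {value: 0.66, low: 0.61, high: 0.71}
sens_pococt_low_high: {value: 0.91, low: 0.87, high: 0.93}
spec_pococt_low_high: {value: 0.62, low: 0.57, high: 0.67}
sens_pococt_moderate_severe: {value: 0.92, low: 0.89, high: 0.94}
spec_pococt_moderate_severe: {value: 0.65, low: 0.60, high: 0.70}
sens_visual_cancer: {value: 0.71, low: 0.60, high: 0.85}
spec_visual: {value: 0.97, low: 0.93, high: 0.98}
sens_visual_dysplasia: {value: 0.50, low: 0.25, high: 0.75}
sens_biopsy: {value: 0.98, low: 0.90, high: 1.0}
spec_biopsy: {value: 1.0, low: 0.90, high: 1.0}
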