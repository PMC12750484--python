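feature_id,coefficient,ci_low,ci_high,method,source
secretion_amount,0.87,0.73,1.0,cohen_weighted_kappa,literature (earlier two-rater pediatric bronchitis instrument)
secretion_color,0.86,0.69,1.0,cohen_weighted_kappa,literature (earlier two-rater pediatric bronchitis instrument)
mucosal_edema,0.48,0.27,0.69,cohen_weighted_kappa,literature (earlier two-rater pediatric bronchitis instrument)
erythema,0.40,0.19,0.62,cohen_weighted_kappa,literature (earlier two-rater pediatric bronchitis instrument)
mucosal_ridging,0.54,0.25,0.83,cohen_weighted_kappa,literature (earlier two-rater pediatric bronchitis instrument)
mucosal_pallor,0.64,0.44,0.83,cohen_weighted_kappa,literature (earlier two-rater pediatric bronchitis instrument)
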