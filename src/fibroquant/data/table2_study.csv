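# Study cohort: histopathological stage, ECA (%) and EnC in paired
# pre-/post-treatment biopsies of 9 MASH patients.
# weight_change_pct is a SYNTHETIC stand-in column: per-patient weight
# changes were not published; only patients 2 and 6 are reported to have
# lost more than 10% of body weight between biopsies, so exactly those two
# rows are below -10 and the remaining magnitudes are invented.
patient_id,cohort,stage_pre,stage_post,eca_pre_pct,eca_post_pct,enc_pre,enc_post,weight_change_pct
1,study,F4,F3,8.6,6.3,1.56,1.38,-3.2
2,study,F3,F2,5.8,3.9,0.87,0.84,-12.4
3,study,F3,F2,6.5,6.6,1.16,1.33,1.5
4,study,F3,F3,9.6,8.0,1.48,1.42,-6.8
5,study,F1a,F2,2.0,2.7,0.86,0.95,0.9
6,study,F3,F3,9.8,4.8,2.04,1.42,-14.1
7,study,F3,F3,5.8,5.9,1.08,1.29,-2.1
8,study,F3,F4,3.2,13.4,1.25,1.92,4.3
9,study,F3,F3,5.2,5.0,1.04,0.98,-8.5
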