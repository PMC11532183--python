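# Validation cohort: histopathological stage, ECA (%) and EnC in paired
# pre-/post-treatment biopsies of 8 MASH patients.
# weight_change_pct is a SYNTHETIC stand-in column: per-patient weight
# changes were not published; no validation patient reached the >10%
# weight-loss threshold, so every value here lies above -10 and the
# magnitudes are invented.
patient_id,cohort,stage_pre,stage_post,eca_pre_pct,eca_post_pct,enc_pre,enc_post,weight_change_pct
1,validation,F2,F3,3.48,5.06,0.99,0.74,-7.2
2,validation,F3,F3,5.75,5.00,1.94,1.69,-1.4
3,validation,F3,F2,5.18,5.09,1.66,1.46,-4.8
4,validation,F1a,F2,1.33,3.34,0.67,0.60,2.6
5,validation,F3,F3,6.17,2.04,0.69,1.21,-9.1
6,validation,F3,F3,6.10,1.55,1.86,0.90,-3.0
7,validation,F3,F3,3.86,4.13,1.48,0.75,0.8
8,validation,F4,F2,9.03,1.87,1.64,0.74,-5.5
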