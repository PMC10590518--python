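concept_code,category,weight
COND_001,myocardial_infarction,1
COND_002,congestive_heart_failure,1
COND_003,peripheral_vascular_disease,1
COND_004,cerebrovascular_disease,1
COND_005,dementia,1
COND_006,chronic_pulmonary_disease,1
COND_007,rheumatologic_disease,1
COND_008,peptic_ulcer_disease,1
COND_009,mild_liver_disease,1
COND_010,diabetes,1
COND_011,diabetes_with_complications,2
COND_012,hemiplegia_paraplegia,2
COND_013,renal_disease,2
COND_014,any_malignancy,2
COND_015,moderate_severe_liver_disease,3
COND_016,metastatic_solid_tumor,6
COND_017,aids_hiv,6
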