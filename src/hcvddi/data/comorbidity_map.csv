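category,icd10_prefix
myocardial_infarction,I21
myocardial_infarction,I22
myocardial_infarction,I25.2
congestive_heart_failure,I09.9
congestive_heart_failure,I11.0
congestive_heart_failure,I13.0
congestive_heart_failure,I13.2
congestive_heart_failure,I25.5
congestive_heart_failure,I42.0
congestive_heart_failure,I42.5
congestive_heart_failure,I42.6
congestive_heart_failure,I42.7
congestive_heart_failure,I42.8
congestive_heart_failure,I42.9
congestive_heart_failure,I43
congestive_heart_failure,I50
congestive_heart_failure,P29.0
peripheral_vascular_disease,I70
peripheral_vascular_disease,I71
peripheral_vascular_disease,I73.1
peripheral_vascular_disease,I73.8
peripheral_vascular_disease,I73.9
peripheral_vascular_disease,I77.1
peripheral_vascular_disease,I79.0
peripheral_vascular_disease,I79.2
peripheral_vascular_disease,K55.1
peripheral_vascular_disease,K55.8
peripheral_vascular_disease,K55.9
peripheral_vascular_disease,Z95.8
peripheral_vascular_disease,Z95.9
cerebrovascular_disease,G45
cerebrovascular_disease,G46
cerebrovascular_disease,H34.0
cerebrovascular_disease,I60
cerebrovascular_disease,I61
cerebrovascular_disease,I62
cerebrovascular_disease,I63
cerebrovascular_disease,I64
cerebrovascular_disease,I65
cerebrovascular_disease,I66
cerebrovascular_disease,I67
cerebrovascular_disease,I68
cerebrovascular_disease,I69
dementia,F00
dementia,F01
dementia,F02
dementia,F03
dementia,F05.1
dementia,G30
dementia,G31.1
chronic_pulmonary_disease,I27.8
chronic_pulmonary_disease,I27.9
chronic_pulmonary_disease,J40
chronic_pulmonary_disease,J41
chronic_pulmonary_disease,J42
chronic_pulmonary_disease,J43
chronic_pulmonary_disease,J44
chronic_pulmonary_disease,J45
chronic_pulmonary_disease,J46
chronic_pulmonary_disease,J47
chronic_pulmonary_disease,J60
chronic_pulmonary_disease,J61
chronic_pulmonary_disease,J62
chronic_pulmonary_disease,J63
chronic_pulmonary_disease,J64
chronic_pulmonary_disease,J65
chronic_pulmonary_disease,J66
chronic_pulmonary_disease,J67
chronic_pulmonary_disease,J68.4
chronic_pulmonary_disease,J70.1
chronic_pulmonary_disease,J70.3
rheumatic_disease,M05
rheumatic_disease,M06
rheumatic_disease,M31.5
rheumatic_disease,M32
rheumatic_disease,M33
rheumatic_disease,M34
rheumatic_disease,M35.1
rheumatic_disease,M35.3
rheumatic_disease,M36.0
peptic_ulcer_disease,K25
peptic_ulcer_disease,K26
peptic_ulcer_disease,K27
peptic_ulcer_disease,K28
mild_liver_disease,B18
mild_liver_disease,K70.0
mild_liver_disease,K70.1
mild_liver_disease,K70.2
mild_liver_disease,K70.3
mild_liver_disease,K70.9
mild_liver_disease,K71.3
mild_liver_disease,K71.4
mild_liver_disease,K71.5
mild_liver_disease,K71.7
mild_liver_disease,K73
mild_liver_disease,K74
mild_liver_disease,K76.0
mild_liver_disease,K76.2
mild_liver_disease,K76.3
mild_liver_disease,K76.4
mild_liver_disease,K76.8
mild_liver_disease,K76.9
mild_liver_disease,Z94.4
diabetes_without_complication,E10.0
diabetes_without_complication,E10.1
diabetes_without_complication,E10.6
diabetes_without_complication,E10.8
diabetes_without_complication,E10.9
diabetes_without_complication,E11.0
diabetes_without_complication,E11.1
diabetes_without_complication,E11.6
diabetes_without_complication,E11.8
diabetes_without_complication,E11.9
diabetes_without_complication,E12.0
diabetes_without_complication,E12.1
diabetes_without_complication,E12.6
diabetes_without_complication,E12.8
diabetes_without_complication,E12.9
diabetes_without_complication,E13.0
diabetes_without_complication,E13.1
diabetes_without_complication,E13.6
diabetes_without_complication,E13.8
diabetes_without_complication,E13.9
diabetes_without_complication,E14.0
diabetes_without_complication,E14.1
diabetes_without_complication,E14.6
diabetes_without_complication,E14.8
diabetes_without_complication,E14.9
diabetes_with_complication,E10.2
diabetes_with_complication,E10.3
diabetes_with_complication,E10.4
diabetes_with_complication,E10.5
diabetes_with_complication,E10.7
diabetes_with_complication,E11.2
diabetes_with_complication,E11.3
diabetes_with_complication,E11.4
diabetes_with_complication,E11.5
diabetes_with_complication,E11.7
diabetes_with_complication,E12.2
diabetes_with_complication,E12.3
diabetes_with_complication,E12.4
diabetes_with_complication,E12.5
diabetes_with_complication,E12.7
diabetes_with_complication,E13.2
diabetes_with_complication,E13.3
diabetes_with_complication,E13.4
diabetes_with_complication,E13.5
diabetes_with_complication,E13.7
diabetes_with_complication,E14.2
diabetes_with_complication,E14.3
diabetes_with_complication,E14.4
diabetes_with_complication,E14.5
diabetes_with_complication,E14.7
hemiplegia_paraplegia,G04.1
hemiplegia_paraplegia,G11.4
hemiplegia_paraplegia,G80.1
hemiplegia_paraplegia,G80.2
hemiplegia_paraplegia,G81
hemiplegia_paraplegia,G82
hemiplegia_paraplegia,G83.0
hemiplegia_paraplegia,G83.1
hemiplegia_paraplegia,G83.2
hemiplegia_paraplegia,G83.3
hemiplegia_paraplegia,G83.4
hemiplegia_paraplegia,G83.9
renal_disease,I12.0
renal_disease,I13.1
renal_disease,N03.2
renal_disease,N03.3
renal_disease,N03.4
renal_disease,N03.5
renal_disease,N03.6
renal_disease,N03.7
renal_disease,N05.2
renal_disease,N05.3
renal_disease,N05.4
renal_disease,N05.5
renal_disease,N05.6
renal_disease,N05.7
renal_disease,N18
renal_disease,N19
renal_disease,N25.0
renal_disease,Z49.0
renal_disease,Z49.1
renal_disease,Z49.2
renal_disease,Z94.0
renal_disease,Z99.2
any_malignancy,C00
any_malignancy,C01
any_malignancy,C02
any_malignancy,C03
any_malignancy,C04
any_malignancy,C05
any_malignancy,C06
any_malignancy,C07
any_malignancy,C08
any_malignancy,C09
any_malignancy,C10
any_malignancy,C11
any_malignancy,C12
any_malignancy,C13
any_malignancy,C14
any_malignancy,C15
any_malignancy,C16
any_malignancy,C17
any_malignancy,C18
any_malignancy,C19
any_malignancy,C20
any_malignancy,C21
any_malignancy,C22
any_malignancy,C23
any_malignancy,C24
any_malignancy,C25
any_malignancy,C26
any_malignancy,C30
any_malignancy,C31
any_malignancy,C32
any_malignancy,C33
any_malignancy,C34
any_malignancy,C37
any_malignancy,C38
any_malignancy,C39
any_malignancy,C40
any_malignancy,C41
any_malignancy,C43
any_malignancy,C45
any_malignancy,C46
any_malignancy,C47
any_malignancy,C48
any_malignancy,C49
any_malignancy,C50
any_malignancy,C51
any_malignancy,C52
any_malignancy,C53
any_malignancy,C54
any_malignancy,C55
any_malignancy,C56
any_malignancy,C57
any_malignancy,C58
any_malignancy,C60
any_malignancy,C61
any_malignancy,C62
any_malignancy,C63
any_malignancy,C64
any_malignancy,C65
any_malignancy,C66
any_malignancy,C67
any_malignancy,C68
any_malignancy,C69
any_malignancy,C70
any_malignancy,C71
any_malignancy,C72
any_malignancy,C73
any_malignancy,C74
any_malignancy,C75
any_malignancy,C76
any_malignancy,C81
any_malignancy,C82
any_malignancy,C83
any_malignancy,C84
any_malignancy,C85
any_malignancy,C88
any_malignancy,C90
any_malignancy,C91
any_malignancy,C92
any_malignancy,C93
any_malignancy,C94
any_malignancy,C95
any_malignancy,C96
any_malignancy,C97
moderate_severe_liver_disease,I85.0
moderate_severe_liver_disease,I85.9
moderate_severe_liver_disease,I86.4
moderate_severe_liver_disease,I98.2
moderate_severe_liver_disease,K70.4
moderate_severe_liver_disease,K71.1
moderate_severe_liver_disease,K72.1
moderate_severe_liver_disease,K72.9
moderate_severe_liver_disease,K76.5
moderate_severe_liver_disease,K76.6
moderate_severe_liver_disease,K76.7
metastatic_solid_tumor,C77
metastatic_solid_tumor,C78
metastatic_solid_tumor,C79
metastatic_solid_tumor,C80
aids_hiv,B20
aids_hiv,B21
aids_hiv,B22
aids_hiv,B24
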