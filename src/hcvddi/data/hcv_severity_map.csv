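category,icd10_prefix
decompensated_cirrhosis,K70.4
decompensated_cirrhosis,K71.1
decompensated_cirrhosis,K72
decompensated_cirrhosis,I85.0
decompensated_cirrhosis,I85.9
decompensated_cirrhosis,I86.4
decompensated_cirrhosis,I98.2
decompensated_cirrhosis,K76.5
decompensated_cirrhosis,K76.6
decompensated_cirrhosis,K76.7
decompensated_cirrhosis,R18
compensated_cirrhosis,K74
compensated_cirrhosis,K70.3
chronic_hepatitis_c,B18.2
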