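subject_id,age,sex,status
S01,78,Male,MCI
S02,80,Male,Healthy
S03,70,Male,Healthy
S04,73,Female,Healthy
S05,74,Male,MCI
S06,77,Female,Healthy
S07,87,Female,Healthy
S08,85,Female,Healthy
S09,82,Female,MCI
S10,71,Female,Healthy
S11,72,Female,MCI
S12,65,Male,MCI
S13,75,Male,Healthy
S14,71,Female,MCI
S15,76,Male,Healthy
S16,75,Female,MCI
S17,83,Male,Healthy
S18,76,Male,MCI
S19,80,Female,Healthy
S20,79,Male,Healthy
S21,75,Male,Healthy
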