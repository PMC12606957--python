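participant,age,sex,md_laterality,symptom_duration
A,78,M,left,17 years
B,62,F,right,36 months
C,68,M,left,40 years
D,33,F,left,48 months
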