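participant,structure,observer,eh_mean,eh_sd,eh_median,eh_scaled,normal_mean,normal_sd,normal_median,normal_scaled,reported_ratio,reported_iam_scaled_ratio
A,cochlea,1,6.4,2.7,6.2,0.7,8.4,3.8,7.9,1.7,1.5,2.0
A,cochlea,2,5.4,2.1,6.0,0.6,10.1,4.5,10.1,1.4,1.5,2.0
B,cochlea,1,7.0,1.3,7.7,0.9,5.5,2.9,6.4,0.8,0.8,0.8
B,cochlea,2,6.0,3.2,7.1,1.1,5.7,2.6,5.9,0.7,0.8,0.8
C,cochlea,1,5.5,2.5,4.7,0.4,4.9,1.1,5.1,0.5,1.2,1.2
C,cochlea,2,4.8,2.8,3.6,0.4,3.9,1.9,4.5,0.5,1.2,1.2
D,cochlea,1,6.3,3.0,5.2,0.6,5.9,3.9,8.2,1.7,1.3,2.8
D,cochlea,2,3.5,1.5,3.5,0.3,4.3,3.1,2.9,0.5,1.3,2.8
A,vestibule,1,6.3,3.3,5.7,0.6,9.1,4.8,10.3,1.3,2.1,2.9
A,vestibule,2,4.6,1.1,4.6,0.4,9.5,5.0,11.7,1.6,2.1,2.9
B,vestibule,1,6.3,2.4,7.1,0.8,5.6,2.7,5.9,0.8,0.8,0.7
B,vestibule,2,9.5,5.0,9.7,1.3,6.0,2.3,7.0,0.8,0.8,0.7
C,vestibule,1,4.4,2.3,3.2,0.3,6.0,3.3,7.9,0.7,1.9,1.9
C,vestibule,2,4.1,1.7,3.3,0.4,5.2,2.4,4.3,0.5,1.9,1.9
D,vestibule,1,6.5,4.4,6.9,0.8,5.6,3.0,5.1,1.1,1.1,2.2
D,vestibule,2,4.6,3.0,4.3,0.4,5.8,3.7,7.7,1.4,1.1,2.2
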