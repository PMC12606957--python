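participant,timepoint,observer,image_quality,artefact,right_iam_vis,right_iam_comp,right_cochlea_vis,right_cochlea_comp,right_vestibule_vis,right_vestibule_comp,left_iam_vis,left_iam_comp,left_cochlea_vis,left_cochlea_comp,left_vestibule_vis,left_vestibule_comp,reported_certainty,reported_side,eh_side
A,pre_registration,1,1,1,1,1,3,1,3,1,1,2,0,0,1,1,none,,left
A,pre_registration,2,1,1,1,2,3,2,3,2,1,2,0,0,0,0,definite,left,left
A,post_registration,1,1,1,1,1,3,2,3,2,1,2,0,0,1,1,definite,left,left
A,post_registration,2,1,1,1,2,3,2,3,2,1,2,0,0,0,0,definite,left,left
B,pre_registration,1,2,2,2,2,2,1,2,1,2,3,1,1,1,1,none,,right
B,pre_registration,2,2,2,1,1,1,1,1,1,2,2,1,1,1,1,none,,right
B,post_registration,1,2,2,1,2,2,1,2,1,2,2,1,1,1,1,none,,right
B,post_registration,2,2,2,1,1,1,1,0,0,2,3,1,2,1,2,none,,right
C,pre_registration,1,2,2,1,3,1,3,1,3,1,3,1,1,0,0,possible,left,left
C,pre_registration,2,2,2,1,3,1,2,1,2,1,3,0,0,1,1,possible,left,left
C,post_registration,1,2,2,1,3,1,3,1,3,1,3,0,0,0,0,possible,left,left
C,post_registration,2,2,2,1,3,1,2,1,2,1,3,0,0,0,0,possible,left,left
D,pre_registration,1,1,0,1,1,1,1,1,1,1,1,0,0,0,0,none,,left
D,pre_registration,2,1,0,1,1,2,1,2,1,1,1,1,1,1,1,none,,left
D,post_registration,1,1,0,1,2,2,2,1,1,1,1,0,0,0,0,definite,left,left
D,post_registration,2,1,0,1,1,2,1,2,2,1,1,0,0,1,1,possible,left,left
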