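id,plan_lobes,engel,operated,n_ied,note
P1,R F,3,1,36,
P2,L P,1,1,30,
P3,L T,1,1,61,
P4,L T,4,1,92,
P5,L T,1,1,18,
P6,R F,1,1,41,
P7,L T,2/3,1,8,Engel class recorded between II and III; poor outcome either way
P8,R T;R P,1,1,14,
P9,,,0,100,not operated
P10,,,0,45,not operated
P11,L F,1,1,75,
P12,R F,1,1,35,
P13,L T;L O,1,1,47,
P14,L P,2,1,17,
P15,R C;R P,1,1,39,
P16,R T,1,1,62,thermocoagulation only; treated lobe taken from the SEEG target
P17,R T,1,1,52,
P18,R T;R O,1,1,12,
P19,R F;R T,4,1,52,
P20,L T,2,1,72,
P21,R T;R P;R O,1,1,64,
P22,L T,3,1,82,
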