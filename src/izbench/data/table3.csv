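id,method,region,percent
P1,ecd,R F,39
P1,ecd,R C,31
P1,ecd,R P,25
P1,sesame,R F,36
P1,sesame,R C,23
P1,sesame,R P,21
P1,sesame,R T,11
P1,rap_music,R F,53
P1,rap_music,R C,19
P1,rap_music,R P,14
P1,wmne,R F,18
P1,wmne,R T,18
P1,wmne,R P,14
P1,wmne,L T,12
P2,ecd,L C,53
P2,ecd,L P,43
P2,sesame,L P,41
P2,sesame,L C,29
P2,sesame,L F,13
P2,rap_music,L P,47
P2,rap_music,L C,30
P2,wmne,L P,17
P2,wmne,L T,14
P2,wmne,R P,13
P2,wmne,L F,11
P3,ecd,L T,72
P3,ecd,L C,15
P3,ecd,L P,11
P3,sesame,L T,56
P3,sesame,L C,19
P3,sesame,L P,13
P3,rap_music,L T,61
P3,rap_music,L C,20
P3,wmne,L T,20
P3,wmne,L P,12
P3,wmne,L F,12
P3,wmne,R T,11
P4,ecd,R T,75
P4,sesame,R T,61
P4,sesame,R F,23
P4,rap_music,R T,49
P4,rap_music,R F,18
P4,rap_music,R O,12
P4,wmne,R T,19
P4,wmne,R F,16
P4,wmne,L T,14
P4,wmne,R P,11
P5,ecd,R P,50
P5,ecd,R T,33
P5,ecd,R C,17
P5,sesame,R P,34
P5,sesame,R T,34
P5,rap_music,R P,39
P5,rap_music,R T,39
P5,rap_music,R O,11
P5,wmne,R T,21
P5,wmne,R P,16
P5,wmne,L T,12
P5,wmne,R F,12
P6,ecd,R C,56
P6,ecd,R P,20
P6,ecd,R F,15
P6,sesame,R C,45
P6,sesame,R F,16
P6,sesame,R P,15
P6,rap_music,R C,46
P6,rap_music,R F,17
P6,rap_music,R P,15
P6,wmne,R F,14
P6,wmne,R P,13
P6,wmne,R T,13
P6,wmne,L T,13
P6,wmne,L F,13
P6,wmne,L P,11
P7,ecd,L T,50
P7,ecd,L P,50
P7,sesame,L P,38
P7,sesame,L T,29
P7,sesame,L F,15
P7,rap_music,L P,50
P7,rap_music,L T,38
P7,rap_music,R P,12
P7,wmne,L T,19
P7,wmne,L P,14
P7,wmne,L F,13
P7,wmne,R T,11
P7,wmne,R F,11
P8,ecd,L T,57
P8,ecd,L P,21
P8,sesame,L T,26
P8,sesame,L P,16
P8,sesame,L C,14
P8,sesame,R P,14
P8,sesame,R C,11
P8,rap_music,L P,29
P8,rap_music,R P,21
P8,rap_music,L T,14
P8,rap_music,L F,14
P8,wmne,L T,16
P8,wmne,R T,15
P8,wmne,L F,13
P8,wmne,R F,12
P9,ecd,R P,75
P9,ecd,R C,23
P9,sesame,R P,71
P9,sesame,R C,21
P9,rap_music,R P,71
P9,rap_music,R C,23
P9,wmne,R P,22
P9,wmne,R T,14
P9,wmne,R F,11
P10,ecd,R C,47
P10,ecd,R P,44
P10,sesame,R C,49
P10,sesame,R P,41
P10,rap_music,R C,49
P10,rap_music,R P,47
P10,wmne,R P,18
P10,wmne,R T,15
P10,wmne,L T,12
P10,wmne,R F,11
P11,ecd,L F,35
P11,ecd,R F,16
P11,ecd,L T,13
P11,ecd,L P,12
P11,sesame,L F,29
P11,sesame,L T,15
P11,sesame,R F,14
P11,sesame,L P,12
P11,rap_music,L T,25
P11,rap_music,R F,23
P11,rap_music,L F,17
P11,wmne,L P,14
P11,wmne,L F,13
P11,wmne,R P,13
P11,wmne,L T,13
P11,wmne,R T,12
P11,wmne,R F,12
P12,ecd,R T,60
P12,ecd,R F,17
P12,ecd,R C,14
P12,sesame,R T,59
P12,sesame,R F,18
P12,sesame,R C,11
P12,rap_music,R T,60
P12,rap_music,R F,17
P12,rap_music,R P,11
P12,wmne,R T,19
P12,wmne,R P,14
P12,wmne,R F,14
P12,wmne,L T,11
P13,ecd,L T,85
P13,ecd,L O,11
P13,sesame,L T,75
P13,sesame,L P,11
P13,rap_music,L T,79
P13,rap_music,L O,11
P13,wmne,L T,20
P13,wmne,L P,16
P13,wmne,R T,12
P14,ecd,L T,88
P14,ecd,L P,12
P14,sesame,L T,47
P14,sesame,L P,24
P14,sesame,R P,15
P14,rap_music,L T,47
P14,rap_music,L P,29
P14,rap_music,R P,18
P14,wmne,L T,19
P14,wmne,L P,16
P14,wmne,R P,12
P14,wmne,R T,11
P15,ecd,R P,72
P15,ecd,R C,21
P15,sesame,R P,72
P15,sesame,R C,19
P15,rap_music,R P,82
P15,rap_music,R C,13
P15,wmne,R P,22
P15,wmne,R T,14
P15,wmne,L P,11
P15,wmne,R C,11
P15,wmne,R F,11
P16,ecd,R T,98
P16,sesame,R T,84
P16,rap_music,R T,89
P16,wmne,R T,24
P16,wmne,R P,15
P16,wmne,R F,12
P17,ecd,R F,54
P17,ecd,R T,27
P17,ecd,R C,17
P17,sesame,R T,47
P17,sesame,R F,37
P17,rap_music,R T,50
P17,rap_music,R F,35
P17,wmne,R T,20
P17,wmne,R P,15
P17,wmne,R F,14
P18,ecd,R P,67
P18,ecd,R T,25
P18,sesame,R P,64
P18,sesame,R C,16
P18,sesame,R T,16
P18,rap_music,R P,75
P18,rap_music,R T,17
P18,wmne,R P,25
P18,wmne,R T,15
P19,ecd,R T,65
P19,ecd,R P,25
P19,sesame,R T,61
P19,sesame,R P,25
P19,rap_music,R T,60
P19,rap_music,R P,25
P19,rap_music,R O,12
P19,wmne,R T,19
P19,wmne,R P,18
P19,wmne,L P,12
P20,ecd,L T,42
P20,ecd,L P,25
P20,ecd,R P,12
P20,sesame,L T,40
P20,sesame,L P,20
P20,sesame,R P,13
P20,sesame,L C,12
P20,rap_music,L T,40
P20,rap_music,L P,19
P20,rap_music,R P,17
P20,rap_music,L C,12
P20,wmne,L T,17
P20,wmne,L P,17
P20,wmne,L F,12
P21,ecd,R T,97
P21,sesame,R T,92
P21,rap_music,R T,95
P21,wmne,R T,22
P21,wmne,R P,18
P21,wmne,R F,11
P22,ecd,L T,83
P22,sesame,L T,77
P22,sesame,L P,11
P22,rap_music,L T,78
P22,wmne,L T,22
P22,wmne,L P,13
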