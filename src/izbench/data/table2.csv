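id,method,metric,mean,std
P1,sesame,dld,16.17,13.56
P1,rap_music,dld,18.45,16.83
P1,wmne,dld,24.24,7.88
P1,sesame,mld,24.19,15.58
P1,wmne,mld,52.97,4.52
P1,sesame,sd,21.73,14.87
P1,wmne,sd,43.26,3.77
P1,sesame,auc,0.95,
P1,wmne,auc,0.82,
P2,sesame,dld,13.01,16.27
P2,rap_music,dld,18.41,17.14
P2,wmne,dld,21.02,11.94
P2,sesame,mld,21.42,15.21
P2,wmne,mld,52.23,5.18
P2,sesame,sd,20.72,12.94
P2,wmne,sd,45.38,3.87
P2,sesame,auc,0.98,
P2,wmne,auc,0.89,
P3,sesame,dld,17.77,22.44
P3,rap_music,dld,20.8,19.82
P3,wmne,dld,29.37,15.46
P3,sesame,mld,25.56,21.3
P3,wmne,mld,64.74,8.22
P3,sesame,sd,21.61,19.28
P3,wmne,sd,52.72,7.22
P3,sesame,auc,0.98,
P3,wmne,auc,0.88,
P4,sesame,dld,22.36,17.59
P4,rap_music,dld,27.83,19.32
P4,wmne,dld,30.71,23.82
P4,sesame,mld,26.77,15.98
P4,wmne,mld,60.33,7.66
P4,sesame,sd,20.83,13.11
P4,wmne,sd,55.63,5.29
P4,sesame,auc,0.97,
P4,wmne,auc,0.97,
P5,sesame,dld,20.27,18.83
P5,rap_music,dld,25.66,21.56
P5,wmne,dld,20.63,11.61
P5,sesame,mld,29.35,19.97
P5,wmne,mld,57.9,4.1
P5,sesame,sd,25.1,13.76
P5,wmne,sd,50.62,4.88
P5,sesame,auc,0.97,
P5,wmne,auc,0.93,
P6,sesame,dld,16.13,18.58
P6,rap_music,dld,20.64,22.89
P6,wmne,dld,19.18,7.57
P6,sesame,mld,22.19,18.75
P6,wmne,mld,55.6,7.55
P6,sesame,sd,18.18,13.07
P6,wmne,sd,49.15,4.02
P6,sesame,auc,0.95,
P6,wmne,auc,0.96,
P7,sesame,dld,18.87,17.12
P7,rap_music,dld,20.1,10.89
P7,wmne,dld,24.83,12.32
P7,sesame,mld,32.7,13.33
P7,wmne,mld,56.04,6.68
P7,sesame,sd,32.65,11
P7,wmne,sd,53.28,6.27
P7,sesame,auc,0.81,
P7,wmne,auc,0.86,
P8,sesame,dld,32.88,30.91
P8,rap_music,dld,34.16,27.13
P8,wmne,dld,38.28,26.75
P8,sesame,mld,41.15,27.24
P8,wmne,mld,65.7,5.45
P8,sesame,sd,31.33,18.46
P8,wmne,sd,54.74,4.02
P8,sesame,auc,0.78,
P8,wmne,auc,0.82,
P9,sesame,dld,8.66,7.81
P9,rap_music,dld,9.87,8.02
P9,wmne,dld,19.06,4.74
P9,sesame,mld,12.68,10.95
P9,wmne,mld,48.17,5.43
P9,sesame,sd,10.87,10.36
P9,wmne,sd,39.32,4.63
P9,sesame,auc,0.98,
P9,wmne,auc,0.9,
P10,sesame,dld,7.92,4.69
P10,rap_music,dld,7.05,4.21
P10,wmne,dld,14.91,14.9
P10,sesame,mld,11.5,6.81
P10,wmne,mld,51.99,6.86
P10,sesame,sd,11.06,7.97
P10,wmne,sd,49.26,5.53
P10,sesame,auc,0.96,
P10,wmne,auc,0.97,
P11,sesame,dld,21.58,19.94
P11,rap_music,dld,27.46,21.3
P11,wmne,dld,36.94,21.96
P11,sesame,mld,27.9,17.58
P11,wmne,mld,61.78,8.88
P11,sesame,sd,21.91,15.21
P11,wmne,sd,53.41,5.49
P11,sesame,auc,0.86,
P11,wmne,auc,0.77,
P12,sesame,dld,9.37,8.31
P12,rap_music,dld,11.77,10.39
P12,wmne,dld,15.27,10.67
P12,sesame,mld,12.88,9.08
P12,wmne,mld,53.11,4.36
P12,sesame,sd,9.86,7.6
P12,wmne,sd,50.66,5.22
P12,sesame,auc,0.98,
P12,wmne,auc,0.92,
P13,sesame,dld,15.26,19.13
P13,rap_music,dld,12.83,12.91
P13,wmne,dld,27.46,17.25
P13,sesame,mld,17.33,17.76
P13,wmne,mld,56.59,5.29
P13,sesame,sd,12.25,11.97
P13,wmne,sd,53.45,5.14
P13,sesame,auc,0.95,
P13,wmne,auc,0.94,
P14,sesame,dld,31.5,28.4
P14,rap_music,dld,31.42,28.12
P14,wmne,dld,30.25,22.75
P14,sesame,mld,36.46,27.99
P14,wmne,mld,55.18,7.69
P14,sesame,sd,14.55,14.75
P14,wmne,sd,47.41,5.78
P14,sesame,auc,0.9,
P14,wmne,auc,0.96,
P15,sesame,dld,11.01,14.99
P15,rap_music,dld,10.35,14.67
P15,wmne,dld,15.43,9.98
P15,sesame,mld,12.17,14.42
P15,wmne,mld,50.11,5.85
P15,sesame,sd,7.49,4.27
P15,wmne,sd,44.46,4.3
P15,sesame,auc,0.99,
P15,wmne,auc,0.97,
P16,sesame,dld,13.78,17.77
P16,rap_music,dld,14.54,18.13
P16,wmne,dld,17.65,12.12
P16,sesame,mld,15.02,15.01
P16,wmne,mld,54.57,7.43
P16,sesame,sd,9.71,8.53
P16,wmne,sd,48.01,6.05
P16,sesame,auc,0.99,
P16,wmne,auc,0.97,
P17,sesame,dld,33.33,22.14
P17,rap_music,dld,33.45,21.54
P17,wmne,dld,29.82,20.42
P17,sesame,mld,34.08,20.7
P17,wmne,mld,58.98,8.9
P17,sesame,sd,14.6,9.51
P17,wmne,sd,53.59,6.83
P17,sesame,auc,0.9,
P17,wmne,auc,0.92,
P18,sesame,dld,12.15,12.9
P18,rap_music,dld,7.42,5.11
P18,wmne,dld,14.76,6.22
P18,sesame,mld,13.04,11.41
P18,wmne,mld,44.27,5.05
P18,sesame,sd,11.41,11.65
P18,wmne,sd,41.97,7.42
P18,sesame,auc,0.98,
P18,wmne,auc,0.95,
P19,sesame,dld,9.56,6.28
P19,rap_music,dld,11.69,8.32
P19,wmne,dld,18.96,11.47
P19,sesame,mld,12.9,7.02
P19,wmne,mld,52.49,5.18
P19,sesame,sd,10.66,7.54
P19,wmne,sd,48.43,5.71
P19,sesame,auc,0.96,
P19,wmne,auc,0.92,
P20,sesame,dld,11.6,10.86
P20,rap_music,dld,12.52,11.23
P20,wmne,dld,25.14,15.71
P20,sesame,mld,14.02,10.36
P20,wmne,mld,53.32,6.07
P20,sesame,sd,11.2,8.3
P20,wmne,sd,49.11,8.28
P20,sesame,auc,0.91,
P20,wmne,auc,0.87,
P21,sesame,dld,7.67,6.37
P21,rap_music,dld,9.22,8.65
P21,wmne,dld,18.75,8.33
P21,sesame,mld,10.04,5.76
P21,wmne,mld,55.59,6.33
P21,sesame,sd,8.11,5.14
P21,wmne,sd,49.28,5.44
P21,sesame,auc,0.99,
P21,wmne,auc,0.97,
P22,sesame,dld,8.45,5.62
P22,rap_music,dld,11.08,9.43
P22,wmne,dld,21.6,17.19
P22,sesame,mld,12.07,6.74
P22,wmne,mld,57.75,6.06
P22,sesame,sd,10.77,7.7
P22,wmne,sd,52.65,6.28
P22,sesame,auc,0.96,
P22,wmne,auc,0.93,
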