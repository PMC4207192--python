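compound,n_experiments,concentrations_uM,clinical_code,assay_positive_max,assay_positive_therapeutic,outcome_max,outcome_therapeutic
B,8,0.3;3;30,NE,True,True,FP,FP
C,6,0.003;0.03;0.3,C,True,True,TP,TP
D,6,0.3;3;30,NE,True,False,FP,TN
E,6,0.3;3;30,NE,True,True,FP,FP
F,6,0.3;3;30,D,True,True,TP,TP
G,7,0.3;3;30,D,False,False,FN,FN
H,7,0.3;3;30,D,True,True,TP,TP
I,7,0.3;3;30,D,False,False,FN,FN
J,6,0.03;0.3;3,NE,True,True,FP,FP
M,6,0.3;3;30,D,True,False,TP,FN
N,6,0.3;3;30,NE,True,False,FP,TN
R,6,0.3;3;30,NE,False,False,TN,TN
S,4,0.3;3;30,NE,True,False,FP,TN
T,6,0.3;3;30,D,True,True,TP,TP
Z,6,0.3;3;30,D,True,True,TP,TP
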