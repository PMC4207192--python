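compound,n_animals,conc_min_uM,conc_max_uM,charcoal_effect,effect_within_window,clinical_code,outcome
B,10,0.08,22,Decrease,True,NE,FP
C,8,0.06,0.58,NC,True,C,FN
D,8,0.196,0.196,NC,True,NE,TN
E,8,0.28,5.38,Decrease,True,NE,FP
F,8,0.072,0.183,Decrease,True,D,TP
G,8,1.67,468,Decrease,True,D,TP
H,8,0,0.0014,Decrease,True,D,TP
I,8,11.3,189,Decrease,True,D,TP
J,8,0.012,0.034,Decrease,True,NE,FP
M,8,69,69,Decrease,False,D,FN
N,8,0.44,0.44,NC,True,NE,TN
R,8,0.06,10,NC,True,NE,TN
S,8,0,0.0000273,Increase,True,NE,FP
T,10,15,344,NC,True,D,FN
Z,10,0,23,NC,True,D,FN
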