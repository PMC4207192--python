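compound,clinical_finding,finding_verbatim,pct_subjects_affected,min_free_exposure_uM,max_free_exposure_uM,exposure_is_total
B,none,None,0,0.0024,0.6597,False
C,constipation,Constipation,17,0.0010,0.0029,False
D,none,None,0,0.0050,0.0352,False
E,none,None,0,0.0060,2.6331,False
F,diarrhea,Diarrhea,67,0.00007,0.6051,False
G,diarrhea,Diarrhea,53,6,12,True
H,diarrhea,Diarrhea,17,0.0006,0.0710,False
I,loose_stools,Loose stools,25,0.7,18.9,True
J,none,None,0,0.000008,0.0008,False
M,diarrhea,Diarrhea,17,0.0017,0.0506,False
N,none,None,0,0.00014,0.0373,True
R,none,None,0,0.000009,0.0837,False
S,nausea,Nausea,13,0.000125,0.001,False
T,diarrhea,Diarrhea,67,0.00935,0.1837,False
Z,loose_stools,Loose watery stools,100,0.00027,2,False
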