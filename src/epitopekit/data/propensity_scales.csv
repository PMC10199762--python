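scale,residue,value
parker_hydrophilicity,A,2.1
parker_hydrophilicity,C,1.4
parker_hydrophilicity,D,10.0
parker_hydrophilicity,E,7.8
parker_hydrophilicity,F,-9.2
parker_hydrophilicity,G,5.7
parker_hydrophilicity,H,2.1
parker_hydrophilicity,I,-8.0
parker_hydrophilicity,K,5.7
parker_hydrophilicity,L,-9.2
parker_hydrophilicity,M,-4.2
parker_hydrophilicity,N,7.0
parker_hydrophilicity,P,2.1
parker_hydrophilicity,Q,6.0
parker_hydrophilicity,R,4.2
parker_hydrophilicity,S,6.5
parker_hydrophilicity,T,5.2
parker_hydrophilicity,V,-3.7
parker_hydrophilicity,W,-10.0
parker_hydrophilicity,Y,-1.9
choufasman_beta_turn,A,0.66
choufasman_beta_turn,C,1.19
choufasman_beta_turn,D,1.46
choufasman_beta_turn,E,0.74
choufasman_beta_turn,F,0.60
choufasman_beta_turn,G,1.56
choufasman_beta_turn,H,0.95
choufasman_beta_turn,I,0.47
choufasman_beta_turn,K,1.01
choufasman_beta_turn,L,0.59
choufasman_beta_turn,M,0.60
choufasman_beta_turn,N,1.56
choufasman_beta_turn,P,1.52
choufasman_beta_turn,Q,0.98
choufasman_beta_turn,R,0.95
choufasman_beta_turn,S,1.43
choufasman_beta_turn,T,0.96
choufasman_beta_turn,V,0.50
choufasman_beta_turn,W,0.96
choufasman_beta_turn,Y,1.14
emini_accessibility,A,0.49
emini_accessibility,C,0.26
emini_accessibility,D,0.78
emini_accessibility,E,0.84
emini_accessibility,F,0.42
emini_accessibility,G,0.48
emini_accessibility,H,0.66
emini_accessibility,I,0.34
emini_accessibility,K,0.97
emini_accessibility,L,0.40
emini_accessibility,M,0.48
emini_accessibility,N,0.81
emini_accessibility,P,0.75
emini_accessibility,Q,0.84
emini_accessibility,R,0.95
emini_accessibility,S,0.65
emini_accessibility,T,0.70
emini_accessibility,V,0.36
emini_accessibility,W,0.51
emini_accessibility,Y,0.76
kolaskar_antigenicity,A,1.064
kolaskar_antigenicity,C,1.412
kolaskar_antigenicity,D,0.866
kolaskar_antigenicity,E,0.851
kolaskar_antigenicity,F,1.091
kolaskar_antigenicity,G,0.874
kolaskar_antigenicity,H,1.105
kolaskar_antigenicity,I,1.152
kolaskar_antigenicity,K,0.930
kolaskar_antigenicity,L,1.250
kolaskar_antigenicity,M,0.826
kolaskar_antigenicity,N,0.776
kolaskar_antigenicity,P,1.064
kolaskar_antigenicity,Q,1.015
kolaskar_antigenicity,R,0.873
kolaskar_antigenicity,S,1.012
kolaskar_antigenicity,T,0.909
kolaskar_antigenicity,V,1.383
kolaskar_antigenicity,W,0.893
kolaskar_antigenicity,Y,1.161
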