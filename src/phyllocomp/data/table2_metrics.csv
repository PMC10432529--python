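strain,dissimilarity,mro_m5c,score_in_vitro,mro_l8c,mro_l10c,mro_l13c,mro_l18c,mro_l26c,score_in_planta
PkP19E3,4.17,0.74,2.64,0.64,0.64,0.64,0.64,0.69,-0.75
PssB728a,3.81,0.69,3.03,0.59,0.67,0.59,0.59,0.77,1.31
MethL85,5.45,0.67,0.92,0.69,0.69,0.62,0.69,0.69,0.81
SmFR1,4.69,0.69,1.05,0.64,0.64,0.62,0.62,0.88,-1.03
ArthL145,3.28,0.77,2.41,0.69,0.81,0.85,0.81,0.81,0.51
RhodL225,6.53,0.62,0.69,0.69,0.62,0.69,0.69,0.77,-0.86
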