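strain,phylogroup,phylogenetic_distance
PkP19E3,Gammaproteobacteria,0.41
PssB728a,Gammaproteobacteria,0.41
MethL85,Alphaproteobacteria,0.68
SmFR1,Alphaproteobacteria,0.68
ArthL145,Actinobacteria,0.76
RhodL225,Actinobacteria,0.76
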