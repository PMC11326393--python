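patient_id,timepoint,gene,nt_change,aa_change,vaf_percent
P01,baseline,SETD2,CTAAG>C,Y501fs,0.067
P03,W6D1,TP53,TGAG>C,L252del,2.35
P03,W6D1,TP53,C>T,M237I,0.47
P04,W6D1,NRAS,C>T,G12D,0.07
P04,PostTx,NRAS,C>T,G12D,0.18
P05,baseline,VHL,TC>T,R167fs,0.58
P10,W6D1,VHL,GTC>G,P81fs,0.3
P12,W6D1,VHL,ACCCAAATGTG>A,P192fs,0.09
P22,W6D1,TERT,T>G,c.-57A>C,0.13
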