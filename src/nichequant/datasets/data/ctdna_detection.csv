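patient_id,timepoint,detected
P01,baseline,true
P02,baseline,true
P03,baseline,true
P04,baseline,true
P05,baseline,false
P06,baseline,false
P07,baseline,false
P08,baseline,false
P09,baseline,false
P10,baseline,false
P11,baseline,false
P12,baseline,false
P13,baseline,false
P01,W6D1,true
P02,W6D1,true
P03,W6D1,true
P04,W6D1,true
P05,W6D1,true
P06,W6D1,true
P07,W6D1,false
P08,W6D1,false
P09,W6D1,false
P10,W6D1,false
P11,W6D1,false
P12,W6D1,false
P13,W6D1,false
P14,W6D1,false
P01,PostTx,true
P02,PostTx,true
P03,PostTx,true
P04,PostTx,true
P05,PostTx,true
P06,PostTx,false
P07,PostTx,false
P08,PostTx,false
P09,PostTx,false
P10,PostTx,false
P11,PostTx,false
P12,PostTx,false
P13,PostTx,false
P14,PostTx,false
P15,PostTx,false
P16,PostTx,false
P01,PostSx,true
P02,PostSx,false
P03,PostSx,false
P04,PostSx,false
P05,PostSx,false
P06,PostSx,false
P07,PostSx,false
P08,PostSx,false
P09,PostSx,false
P10,PostSx,false
P11,PostSx,false
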