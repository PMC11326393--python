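patient_id,clinical_stage,best_response,resected_tumor_size_cm
P01,T3,PR,8.7
P02,T3,PR,4.9
P03,T3,SD,
P04,T3,SD,6.1
P05,T3,PR,11
P06,T4,PR,10
P07,T3,SD,2
P08,T3,SD,7.7
P09,T3,SD,5.7
P10,T4,SD,12.5
P11,T3,SD,9.5
P12,T3,SD,14.5
P13,T3,PR,3
P14,T3,PR,5.2
P15,T3,SD,9.8
P16,T3,SD,8.7
P17,T3,SD,10.5
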