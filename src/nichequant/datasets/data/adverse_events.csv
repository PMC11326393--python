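patient_id,term,grade
P01,Diarrhea,2
P02,Diarrhea,2
P03,Diarrhea,2
P04,Diarrhea,2
P05,Diarrhea,2
P06,Diarrhea,2
P07,Diarrhea,2
P08,Diarrhea,2
P09,Diarrhea,2
P10,Diarrhea,2
P11,Diarrhea,2
P12,Diarrhea,2
P01,Anorexia,2
P02,Anorexia,2
P03,Anorexia,2
P04,Anorexia,2
P05,Anorexia,2
P06,Anorexia,2
P07,Anorexia,2
P08,Anorexia,2
P09,Anorexia,2
P10,Anorexia,3
P01,Fatigue,2
P02,Fatigue,2
P03,Fatigue,2
P04,Fatigue,2
P05,Fatigue,2
P06,Fatigue,2
P07,Fatigue,2
P08,Fatigue,2
P09,Fatigue,3
P10,Fatigue,3
P01,Hypertension,2
P02,Hypertension,2
P03,Hypertension,2
P04,Hypertension,2
P05,Hypertension,2
P06,Hypertension,2
P07,Hypertension,3
P08,Hypertension,3
P09,Hypertension,3
P10,Hypertension,3
P01,Nausea,2
P02,Nausea,2
P03,Nausea,2
P04,Nausea,2
P05,Nausea,2
P06,Nausea,2
P07,Nausea,2
P08,Nausea,2
P09,Nausea,2
P01,Palmar-plantar erythrodysesthesia syndrome,2
P02,Palmar-plantar erythrodysesthesia syndrome,2
P03,Palmar-plantar erythrodysesthesia syndrome,2
P04,Palmar-plantar erythrodysesthesia syndrome,2
P05,Palmar-plantar erythrodysesthesia syndrome,3
P06,Palmar-plantar erythrodysesthesia syndrome,3
P07,Palmar-plantar erythrodysesthesia syndrome,3
P08,Palmar-plantar erythrodysesthesia syndrome,3
P09,Palmar-plantar erythrodysesthesia syndrome,3
P01,Mouth sores,2
P02,Mouth sores,2
P03,Mouth sores,2
P04,Mouth sores,2
P05,Mouth sores,2
P06,Mouth sores,2
P07,Mouth sores,3
P08,Mouth sores,3
P01,Alanine aminotransferase increased,2
P02,Alanine aminotransferase increased,2
P03,Alanine aminotransferase increased,2
P04,Alanine aminotransferase increased,2
P05,Alanine aminotransferase increased,2
P06,Alanine aminotransferase increased,2
P01,Hypomagnesemia,2
P02,Hypomagnesemia,2
P03,Hypomagnesemia,2
P04,Hypomagnesemia,2
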