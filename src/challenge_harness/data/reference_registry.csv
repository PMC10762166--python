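participant_id,final,language,fss_approach,mortality_approach
P01,1,R,Random Forest,Random Forest
P03,1,R,Gradient Boost,Gradient Boost
P07,1,R,Linear model,Logistic Regression
P11,1,python,Random Forest,Support Vector Machine
P12,1,R,Linear model,Logistic Regression
P14,1,R,Random Forest,Random Forest
P15,1,python,Ridge Regression,Random Forest
P20,1,R,Linear model,Logistic Regression
P22,1,R,Stacked Models,Stacked Models
P24,1,python,Random Forest,Random Forest
P26,1,R,Random Forest,Random Forest
R01,0,,,
R02,0,,,
R03,0,,,
R04,0,,,
R05,0,,,
R06,0,,,
R07,0,,,
R08,0,,,
R09,0,,,
R10,0,,,
R11,0,,,
R12,0,,,
R13,0,,,
R14,0,,,
R15,0,,,
R16,0,,,
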