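kind,code,code_system,tier,easy_to_diagnose,clinical_presentation_group,organ_system,anomaly_flag,mca_specific_flag,id_flag,dd_flag,e_flag,age_min_days,age_max_days,category,unit
diagnosis,Q210,ICD10,possible,false,congenital anomalies,cardiovascular,true,false,false,false,false,0,,,
diagnosis,Q039,ICD10,possible,false,congenital anomalies,nervous,true,false,false,false,false,0,,,
diagnosis,Q059,ICD10,probable,false,congenital anomalies,nervous,true,false,false,false,false,0,,,
diagnosis,Q6190,ICD10,possible,false,congenital anomalies,genitourinary,true,false,false,false,false,0,,,
diagnosis,Q790,ICD10,probable,false,congenital anomalies,digestive,true,false,false,false,false,0,,,
diagnosis,Q897,ICD10,probable,false,congenital anomalies,multiple,true,true,false,false,false,0,,,
diagnosis,Q909,ICD10,definite,false,congenital anomalies,chromosomal,true,false,false,false,false,0,,,
diagnosis,F71,ICD10,probable,false,mental/behavioral/neurodevelopmental,nervous,false,false,true,false,false,0,,,
diagnosis,F72,ICD10,probable,false,mental/behavioral/neurodevelopmental,nervous,false,false,true,false,false,0,,,
diagnosis,R6250,ICD10,possible,false,symptoms/signs,nervous,false,false,false,true,false,0,,,
diagnosis,G40909,ICD10,possible,false,nervous system,nervous,false,false,false,false,true,0,,,
diagnosis,G40401,ICD10,probable,false,nervous system,nervous,false,false,false,false,true,0,,,
diagnosis,E7521,ICD10,definite,false,endocrine/nutritional/metabolic,endocrine,false,false,false,false,false,0,,,
diagnosis,E700,ICD10,definite,false,endocrine/nutritional/metabolic,endocrine,false,false,false,false,false,0,,,
diagnosis,E840,ICD10,definite,true,endocrine/nutritional/metabolic,endocrine,false,false,false,false,false,0,,,
diagnosis,D570,ICD10,definite,true,blood disorders,blood,false,false,false,false,false,0,,,
diagnosis,M419,ICD10,possible,false,musculoskeletal system,musculoskeletal,false,false,false,false,false,0,28,,
diagnosis,R279,ICD10,possible,false,nervous system,nervous,false,false,false,false,false,0,1095,,
diagnosis,E889,ICD10,possible,false,endocrine/nutritional/metabolic,endocrine,false,false,false,false,false,0,,,
diagnosis,G710,ICD10,probable,false,musculoskeletal system,musculoskeletal,false,false,false,false,false,0,,,
diagnosis,7454,ICD9,possible,false,congenital anomalies,cardiovascular,true,false,false,false,false,0,,,
diagnosis,74230,ICD9,possible,false,congenital anomalies,nervous,true,false,false,false,false,0,,,
diagnosis,75989,ICD9,probable,false,congenital anomalies,multiple,true,true,false,false,false,0,,,
diagnosis,34590,ICD9,possible,false,nervous system,nervous,false,false,false,false,true,0,,,
diagnosis,3180,ICD9,probable,false,mental/behavioral/neurodevelopmental,nervous,false,false,true,false,false,0,,,
diagnosis,78342,ICD9,possible,false,symptoms/signs,nervous,false,false,false,true,false,0,,,
diagnosis,27701,ICD9,definite,true,endocrine/nutritional/metabolic,endocrine,false,false,false,false,false,0,,,
diagnosis,7580,ICD9,definite,false,congenital anomalies,chromosomal,true,false,false,false,false,0,,,
procedure,81220,CPT,,,,,,,,,,,,genetic_test,
procedure,81415,CPT,,,,,,,,,,,,genetic_test,
procedure,81228,CPT,,,,,,,,,,,,genetic_test,
procedure,81229,CPT,,,,,,,,,,,,genetic_test,
procedure,S3870,HCPCS,,,,,,,,,,,,genetic_test,
procedure,70551,CPT,,,,,,,,,,,,other_workup,
procedure,95816,CPT,,,,,,,,,,,,other_workup,
procedure,93306,CPT,,,,,,,,,,,,other_workup,
procedure,88305,CPT,,,,,,,,,,,,other_workup,
revenue,0173,,,,,,,,,,,,,,NICU
revenue,0174,,,,,,,,,,,,,,NICU
revenue,0203,,,,,,,,,,,,,,PICU
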