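product_name,dosage_form,atc,components
Acetylsalicylic Acid Inhouse 100 mg,tablet,B01AC06,acetylsalicylic acid:100 mg
Amlodipine Inhouse 5 mg,tablet,C08CA01,amlodipine:5 mg
Apixaban Inhouse 5 mg,tablet,B01AF02,apixaban:5 mg
Bisoprolol Inhouse 5 mg,tablet,C07AB07,bisoprolol:5 mg
Candesartan Inhouse 8 mg,tablet,C09CA06,candesartan:8 mg
Candesartan/HCT Inhouse 16/12.5 mg,tablet,C09DA06,candesartan:16 mg;hydrochlorothiazide:12.5 mg
Colecalciferol Inhouse 20000 iu,tablet,A11CC05,colecalciferol:20000 iu
Dipyrone Inhouse 500 mg,tablet,N02BB02,dipyrone:500 mg
Empagliflozin Inhouse 10 mg,tablet,A10BK03,empagliflozin:10 mg
Hydrochlorothiazide Inhouse 25 mg,tablet,C03AA03,hydrochlorothiazide:25 mg
Insulin Glargine Inhouse 100 iu/ml,injection,A10AE04,insulin glargine:100 iu/ml
L-Thyroxine Inhouse 100 mcg,tablet,H03AA01,l-thyroxine:100 mcg
Metformin Inhouse 1000 mg,tablet,A10BA02,metformin:1000 mg
Metoprolol (Succinate) Inhouse 95 mg,tablet,C07AB02,metoprolol|succinate:95 mg
Pantoprazole Inhouse 40 mg,tablet,A02BC02,pantoprazole:40 mg
Ramipril Inhouse 5 mg,tablet,C09AA05,ramipril:5 mg
Rivaroxaban Inhouse 20 mg,tablet,B01AF01,rivaroxaban:20 mg
Rosuvastatin Inhouse 10 mg,tablet,C10AA07,rosuvastatin:10 mg
Salbutamol Inhouse 0.1 mg,inhalation,R03AC02,salbutamol:0.1 mg
Simvastatin Inhouse 40 mg,tablet,C10AA01,simvastatin:40 mg
Tamsulosin Inhouse 0.4 mg,capsule,G04CA02,tamsulosin:0.4 mg
Torasemide Inhouse 10 mg,tablet,C03CA04,torasemide:10 mg
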