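table_id,source_ingredient,source_strength,target_ingredient,target_strength,match_level
ppi,omeprazole,20 mg,pantoprazole,40 mg,4
ppi,lansoprazole,30 mg,pantoprazole,40 mg,4
statin,simvastatin,20 mg,rosuvastatin,10 mg,4
insulin,insulin glulisine,100 iu/ml,insulin aspart,100 iu/ml,4
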