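ingredient_a,ingredient_b,severity
acetylsalicylic acid,ibuprofen,moderate
acetylsalicylic acid,dipyrone,moderate
amlodipine,simvastatin,moderate
clopidogrel,omeprazole,major
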