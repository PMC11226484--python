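ingredient,catalog,category
oxybutynin,priscus,listed
amitriptyline,priscus,listed
zopiclone,priscus,listed
solifenacin,forta,C
desfesoterodine,forta,C
pioglitazone,forta,D
digoxin,forta,C
amiodarone,forta,C
doxazosin,forta,C
moxonidine,forta,C
oxazepam,forta,C
zolpidem,forta,D
diclofenac,forta,C
etoricoxib,forta,C
quetiapine,forta,C
ramipril,forta,A
metformin,forta,A
apixaban,forta,B
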