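trait	p
BMI (GIANT East Asian dataset)	2.0e-7
BMI (BBJ dataset)	1.4e-3
HDL cholesterol	1.2e-2
Hematocrit	7.4e-3
Hemoglobin	3.2e-2
LDL cholesterol	2.0e-1
Mean corpuscular hemoglobin	1.7e-3
Platelet count	6.7e-4
Red blood cell count	1.8e-5
Serum creatinine levels	4.3e-1
Type 2 diabetes	2.6e-3
White blood cell count	3.9e-3
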