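icd_low,icd_high,intermediate,broad
A15,A19,tuberculosis,communicable
B90,B90,tuberculosis,communicable
B20,B24,hiv_aids,communicable
J09,J22,respiratory_infections,communicable
G00,G03,meningitis,communicable
A00,B99,other_infectious,communicable
C00,D48,neoplasms,noncommunicable
D50,D89,blood_immune_disorders,noncommunicable
E10,E14,diabetes,noncommunicable
E00,E99,other_endocrine,noncommunicable
F00,F99,mental_behavioral_disorders,noncommunicable
G04,H95,neurological_sensory_disorders,noncommunicable
I00,I99,cardiovascular_diseases,noncommunicable
J30,J99,chronic_respiratory_diseases,noncommunicable
J23,J29,chronic_respiratory_diseases,noncommunicable
K00,K93,digestive_diseases,noncommunicable
L00,N99,skin_urogenital_musculoskeletal,noncommunicable
O00,O99,maternal_causes,noncommunicable
P00,Q99,perinatal_congenital,noncommunicable
R00,R98,ill_defined,other
R99,R99,unknown,other
V01,V99,transport_injuries,transport
W00,X39,other_unintentional_injuries,other
X40,X45,drug_overdose,other
X46,X59,other_unintentional_injuries,other
X60,X84,suicide,suicide
X85,Y09,interpersonal_violence,violence
Y10,Y19,undetermined_intent,other
Y20,Y20,hanging_undetermined_intent,other
Y21,Y33,undetermined_intent,other
Y34,Y34,unknown,other
Y35,Y36,legal_intervention,violence
Y40,Y89,medical_complications,other
Y90,Z99,unclassified,other
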