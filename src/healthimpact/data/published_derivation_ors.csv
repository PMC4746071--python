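condition_id,count,unadjusted,base,mental,full_contextual,source_model
angina,1097,8.89,4.94,4.71,2.77,main
myocardial_infarction,758,5.67,2.85,3.03,2.09,main
cerebrovascular_stroke,414,5.77,3.89,3.37,2.12,main
asthma,1876,2.24,1.67,1.66,1.63,main
chronic_bronchitis,1460,3.10,1.65,1.48,1.38,main
epilepsy,284,1.70,1.10,1.03,1.12,main
migraine,3280,1.83,1.42,1.33,1.38,main
parkinsons_disease,20,8.59,15.66,12.18,12.56,over70
thyroid,788,3.12,2.01,1.92,1.65,main
diabetes,482,4.68,3.07,3.10,2.30,main
kidney_stone,1113,2.35,1.52,1.59,1.16,main
liver_disease,393,2.80,1.34,1.17,1.11,main
ventricular_ulcer,1026,3.83,2.12,2.08,1.72,main
duodenal_ulcer,953,3.09,1.71,1.70,1.52,main
cancer_survivor,790,2.80,1.69,1.61,1.19,main
psoriasis,1636,1.58,1.25,1.21,1.22,main
atopic_eczema,2325,1.08,0.88,0.84,0.99,main
hand_eczema,3450,1.26,1.06,1.06,1.09,main
pollen_allergies,2851,0.97,0.72,0.71,0.81,main
osteoporosis,350,9.29,4.70,4.63,2.56,main
arthritis,730,3.05,2.17,1.99,1.99,over70
rheumatoid_arthritis,162,4.63,3.09,2.94,2.99,over70
food_allergies,1769,1.41,1.14,1.13,1.29,main
hypersensitivity,3184,1.75,1.25,1.13,1.20,main
fibromyalgia,1872,8.19,6.78,6.07,5.93,main
urinary_incontinence,409,2.88,1.71,1.41,1.40,over70
glaucoma,141,1.75,0.82,0.99,0.96,over70
cataract,421,1.77,1.19,1.05,1.01,over70
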