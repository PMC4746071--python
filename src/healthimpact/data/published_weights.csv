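condition_id,weight,source_or,source_model,override
hypersensitivity,1,1.20,main,true
psoriasis,1,1.22,main,false
food_allergies,1,1.29,main,false
chronic_bronchitis,1,1.38,main,false
migraine,1,1.38,main,false
urinary_incontinence,1,1.40,over70,false
duodenal_ulcer,2,1.52,main,false
asthma,2,1.63,main,false
thyroid,2,1.65,main,false
ventricular_ulcer,2,1.72,main,false
arthritis,2,1.99,over70,false
myocardial_infarction,2,2.09,main,false
cerebrovascular_stroke,2,2.12,main,false
diabetes,2,2.30,main,false
osteoporosis,3,2.56,main,false
angina,3,2.77,main,false
rheumatoid_arthritis,3,2.99,over70,false
fibromyalgia,6,5.93,main,false
parkinsons_disease,13,12.56,over70,false
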