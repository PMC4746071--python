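# Default condition catalog: the self-reported conditions of a Tromso-style
# general-population health survey. Six conditions were asked only of
# participants older than 70 years (age_restricted: true); for younger
# subjects their status is missing, not absent.
#
# charlson_category groups conditions that fall under a single Charlson
# comorbidity category (used for category-level deduplication when computing
# the Charlson comparator); null means the condition has no Charlson analogue
# in this survey.
conditions:
  - id: angina
    label: Angina pectoris
    age_restricted: false
    charlson_category: null
  - id: myocardial_infarction
    label: Myocardial infarction
    age_restricted: false
    charlson_category: myocardial_infarction
  - id: cerebrovascular_stroke
    label: Cerebrovascular stroke
    age_restricted: false
    charlson_category: cerebrovascular_disease
  - id: asthma
    label: Asthma
    age_restricted: false
    charlson_category: chronic_pulmonary
  - id: chronic_bronchitis
    label: Chronic bronchitis
    age_restricted: false
    charlson_category: chronic_pulmonary
  - id: epilepsy
    label: Epilepsy
    age_restricted: false
    charlson_category: null
  - id: migraine
    label: Migraine
    age_restricted: false
    charlson_category: null
  - id: parkinsons_disease
    label: Parkinson's disease
    age_restricted: true
    charlson_category: null
  - id: thyroid
    label: Thyroid disease
    age_restricted: false
    charlson_category: null
  - id: diabetes
    label: Diabetes
    age_restricted: false
    charlson_category: diabetes
  - id: kidney_stone
    label: Kidney stone
    age_restricted: false
    charlson_category: null
  - id: liver_disease
    label: Liver disease
    age_restricted: false
    charlson_category: mild_liver_disease
  - id: ventricular_ulcer
    label: Ventricular (gastric) ulcer
    age_restricted: false
    charlson_category: ulcer_disease
  - id: duodenal_ulcer
    label: Duodenal ulcer
    age_restricted: false
    charlson_category: ulcer_disease
  - id: cancer_survivor
    label: Cancer (any diagnosis, incl. survivors)
    age_restricted: false
    charlson_category: malignancy
  - id: psoriasis
    label: Psoriasis
    age_restricted: false
    charlson_category: null
  - id: atopic_eczema
    label: Atopic eczema
    age_restricted: false
    charlson_category: null
  - id: hand_eczema
    label: Hand eczema
    age_restricted: false
    charlson_category: null
  - id: pollen_allergies
    label: Pollen allergies
    age_restricted: false
    charlson_category: null
  - id: osteoporosis
    label: Osteoporosis
    age_restricted: false
    charlson_category: null
  - id: arthritis
    label: Arthritis (osteoarthritis)
    age_restricted: true
    charlson_category: null
  - id: rheumatoid_arthritis
    label: Rheumatoid arthritis
    age_restricted: true
    charlson_category: connective_tissue
  - id: food_allergies
    label: Food allergies
    age_restricted: false
    charlson_category: null
  - id: hypersensitivity
    label: Hypersensitivity (other allergy)
    age_restricted: false
    charlson_category: null
  - id: fibromyalgia
    label: Fibromyalgia
    age_restricted: false
    charlson_category: null
  - id: urinary_incontinence
    label: Urinary incontinence
    age_restricted: true
    charlson_category: null
  - id: glaucoma
    label: Glaucoma
    age_restricted: true
    charlson_category: null
  - id: cataract
    label: Cataract
    age_restricted: true
    charlson_category: null
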