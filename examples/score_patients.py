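"""Score patients with the published Health Impact Index weight table.

Builds two small patient records, computes their HII score, comorbidity
group and Charlson comparator score, and prints what the numbers mean.
"""

import healthimpact as hi

weights = hi.published_weights()

patients = {
    "angina + diabetes": {"angina": 1, "diabetes": 1},
    "parkinson's + fibromyalgia + migraine": {
        "parkinsons_disease": 1, "fibromyalgia": 1, "migraine": 1
    },
    "no conditions": {},
}

for label, record in patients.items():
    score = hi.compute_hii(weights, record)
    group = hi.assign_group(hi.DEFAULT_GROUPS, score)
    cci = hi.compute_cci(hi.DEFAULT_CHARLSON_MAP, record)
    print(f"{label:40s} HII={score:<3d} group={group:15s} CCI={cci}")

print()
print("The HII is the sum of the published condition weights; e.g. angina")
print("weighs 3 and diabetes 2, so that patient scores 5 ('Moderately ill',")
print("scores 3-5). The Charlson comparator weighs mortality risk instead,")
print("so the same patients rank differently under it.")
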