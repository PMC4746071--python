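"""Predict self-reported health from the published prediction model.

For a grid of index scores the script prints the four SRH category
probabilities and the expected SRH of a fixed reference subject, showing
how predicted health declines as comorbidity accumulates.
"""

import healthimpact as hi

model = hi.published_model()
reference = {"mhi": 1.5, "age": 50, "sex": 0}  # 50-year-old woman, mild distress

print("hii   P(poor)  P(not so good)  P(good)  P(very good)  E[SRH]")
for score in (0, 2, 5, 10, 15, 20):
    probs = hi.predict_category_probs(model, {**reference, "hii": score})
    expected = hi.expected_ordinal(model, {**reference, "hii": score})
    print(
        f"{score:3d}   {probs[0]:7.4f}  {probs[1]:14.4f}  {probs[2]:7.4f}"
        f"  {probs[3]:12.4f}  {expected:6.3f}"
    )

print()
print("Each row is the predicted SRH distribution (1=poor ... 4=very good)")
print("for the same subject at increasing comorbidity burden: the")
print("probability of poor health rises monotonically with the index and")
print("the expected SRH falls.")
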