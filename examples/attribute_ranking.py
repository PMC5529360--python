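"""Attribute ranking on a synthetic cohort with a planted effect.

Generates 5000 patients in the standard cohort schema where bone
metastasis multiplies the odds of the outcome by 8 and every other
attribute is null, then ranks all 24 attributes with each evaluator.
Every measure should place the planted attribute first.
"""

import resiflex as rf

df = rf.generate_cohort(rf.CohortRecipe(n_patients=5000, seed=42,
                                        effects={"bone_met": 8.0}))
print(f"synthetic cohort: n={len(df)}, outcome rate "
      f"{df['t790m'].mean():.3f}\n")

for evaluator in ("chi2", "info_gain", "symmetrical_uncertainty",
                  "correlation", "relieff"):
    ranking = rf.rank_attributes(df, evaluator, seed=0)
    top3 = ", ".join(f"{a} ({s:.3g})" for a, s in ranking.ranking[:3])
    print(f"{evaluator:>24s}: {top3}")

print("\neach line shows the three highest-scoring attributes; the planted "
      "bone_met effect tops every evaluator, and the remaining scores sit "
      "near the null level.")
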