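"""Apply the two-fold significance rule to published effect estimates.

Loads the packaged worked examples (odds/hazard/relative ratios with CI or
p-value) and shows which pass the rule, then adjudicates the gastric-cancer
study set for CHEK2.
"""

from genespectrum import VerificationStatus, adjudicate, load_fixture, meets_risk_rule

studies = load_fixture("adjudication_examples")

print(f"{'study':<30} {'effect':>8} {'estimate':>9}  passes two-fold rule")
for s in studies:
    ci = f"({s.ci_low}-{s.ci_high})" if s.ci_low else f"p={s.p_value:g}"
    print(f"{s.study_id:<30} {s.effect_type.value:>8} {s.point_estimate:>9} "
          f" {str(meets_risk_rule(s)):<5} {ci}")

gastric = [
    s for s in studies
    if s.gene == "CHEK2" and s.disease == "gastric cancer"
    and "young" not in s.ascertainment_note
]
verdict = adjudicate(gastric)
print(f"\nCHEK2-gastric cancer study set ({len(gastric)} studies): {verdict.value}")
print(f"empty study set: {adjudicate([]).value}")

# A single high-quality study with at least a two-fold, significant risk
# verifies the association: here the cohort hazard ratio of 5.76 carries the
# pair even though the case-control odds ratio of 1.6 falls below two-fold.
assert verdict is VerificationStatus.VERIFIED
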