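"""Impute exact economics onto the survey by synthetic matching.

Each survey record receives income, welfare and tax from a donor agreeing on
ten categorical matching variables; when the full ten-variable cell is empty,
variables are relaxed one at a time from the end of the priority list (labour
force status, listed first, is never dropped).
"""

from exitcost import default_spec, generate_donors, generate_survey, impute_economics

spec = default_spec(seed=1)
survey = generate_survey(spec, seed=1)
donors = generate_donors(spec, 20_000, seed=2)

matched, report = impute_economics(survey, donors, seed=3)

print(f"exact ten-variable match rate: {report.exact_match_rate:.1%}")
print("relaxations needed (variables dropped -> records):")
for k in sorted(report.relaxation_histogram):
    print(f"  {k}: {report.relaxation_histogram[k]}")
print("\nmedian imputed income by labour force status:")
print(matched.groupby("lf_status")["income"].median().round().to_string())
# Most records match exactly; full-time medians sit near AU$55,000 and
# not-in-labour-force medians an order of magnitude lower.
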