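"""Generate the synthetic survey base population and donor pool.

The survey emulates a pooled national disability survey for ages 45-64:
seven labour-force/diabetes groups with fixed record counts and design
weights. Donors emulate a microsimulation snapshot: the same ten matching
variables plus exact annual income, welfare and tax.
"""

from exitcost import default_spec, generate_donors, generate_survey

spec = default_spec(seed=1)
survey = generate_survey(spec, seed=1)
donors = generate_donors(spec, 20_000, seed=2)

print("survey records by group (should match the surveyed counts):")
print(survey.groupby("group").size().to_string())
print("\nweighted persons by group (design weights, pre-calibration):")
print(survey.groupby("group")["design_weight"].sum().round().to_string())
print(f"\ndonor pool: {len(donors)} records, "
      f"median full-time income AU${donors.loc[donors.lf_status == 'ft', 'income'].median():,.0f}")
# The group out of the labour force due to diabetes has 46 records weighting
# up to ~11,310 persons; full-time median income sits near AU$55,000.
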