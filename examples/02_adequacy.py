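"""Classify a synthetic cohort's intakes against the three built-in
dietary reference frameworks and print the adequacy percentages.
"""

import vitecal as v

instrument = v.builtin_instrument()
db = v.fixture_db_for_instrument(seed=1, instrument=instrument)

cfg = v.SynthConfig(n_respondents=447, seed=1)
responses, _ = v.gen_cohort(cfg, instrument, db)
intakes = v.intake_table(v.cohort_intake(responses, instrument, db))

results = v.assess_cohort(intakes)  # NIPH-NIH-NRI (α-TE), NIH + EFSA (α-T)
summary = v.group_summary(results)
print(summary.round(0).to_string(index=False))

# pct_adequate: the share of respondents at or above the sex-specific AI/RDA
# of each framework; pct_ul_exceeded: above the tolerable upper level.
# The three frameworks disagree because they use different metrics
# (α-T vs α-TE) and thresholds (8-15 mg/day).
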