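"""Simulate a dammed-river dolphin survey with known truth.

Places dolphin groups by habitat x stratum density, runs double-platform
detection along mixed line/strip effort, and prints the effort bookkeeping.
"""

import riversurvey as rs

scenario = rs.demo_scenario(seed=42)
transects, sightings, truth = rs.simulate_survey(scenario)

print(f"placed groups: {len(truth)}  (true N = {scenario.true_abundance():.0f} individuals)")
print(f"detected sighting records: {len(sightings)} "
      f"({len(rs.unique_groups(sightings))} unique groups, "
      f"{sum(1 for s in sightings if s.duplicate_of)} bow/stern duplicates)")
print()
print(rs.summarize_effort(transects, sightings).to_string(index=False))
# Each row is one stratum x protocol: L (km of effort), transect count and
# unique detected groups; the TOTAL row is the whole survey.
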