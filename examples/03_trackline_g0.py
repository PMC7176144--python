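"""Estimate the trackline detection probability g(0) from platform duplicates.

Stern observers search blind to bow detections, so the fraction of
near-trackline stern sightings the bow missed estimates the single-platform
miss probability q, and g(0) = 1 - q^2.
"""

import riversurvey as rs

scenario = rs.demo_scenario(seed=3, effort_scale=2.0)
transects, sightings, _ = rs.simulate_survey(scenario)
line_ids = {t.transect_id for t in transects if t.kind == "line"}

est = rs.estimate_g0(
    [s for s in sightings if s.transect_id in line_ids], trackline_band_m=50.0, seed=3
)
print(f"stern sightings within 50 m of the trackline: n1 = {est.n1}")
print(f"of those, missed by the bow:                  n01 = {est.n01}")
print(f"q = n01/n1 = {est.q_hat:.3f}")
print(f"g(0) = 1 - q^2 = {est.g0:.3f}  (CV = {est.cv:.3f})")
print(f"=> roughly {100 * (1 - est.g0):.0f}% of groups on the line are missed by both platforms")
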