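"""Sensitivity analyses: correspondence-window variation and first births only.

The correspondence window (default +/-60 days) bounds how far an inferred
birth date may sit from a delivery date. Widening it recovers more links on
ambiguity-free data; narrowing it trades sensitivity for confidence. The
first-births restriction keeps only each mother's earliest qualifying
episode, mirroring designs that study first pregnancies.
"""

from momlink import (
    LinkageConfig,
    SimulationConfig,
    link_mother_infants,
    score_links,
    simulate,
)

dataset, truth = simulate(
    SimulationConfig(n_families=500, seed=42, p_multi_mother_household=0.0)
)

print("window (days)  final links  sensitivity(all)")
for window in (30, 60, 90):
    result = link_mother_infants(dataset, LinkageConfig(window_days=window))
    m = score_links(result.links, truth)
    print(f"{window:13d}  {result.attrition.final_links:11d}  "
          f"{m.sensitivity_all:16.3f}")

first = link_mother_infants(dataset, LinkageConfig(first_births_only=True))
full = link_mother_infants(dataset)
print(f"\nfirst-births restriction: {first.attrition.final_links} links "
      f"(vs {full.attrition.final_links} unrestricted); the drop happens in "
      "Step 3, where the restriction applies")
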