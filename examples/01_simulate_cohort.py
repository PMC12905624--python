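"""Simulate a small CGM + EMA cohort and inspect its ground truth.

The generator encodes a known mediation structure (glucose → metabolic
state → mood with a null direct path), so every downstream estimator can be
checked against the truth it should recover.
"""

import warnings

import glycomood as g

warnings.simplefilter("ignore")

params = g.CohortParams(n_participants=6, n_days=10, seed=1)
bundle, truth = g.simulate_cohort(params)

print(f"CGM samples:        {len(bundle['cgm'])}")
print(f"EMA records:        {len(bundle['ema'])} "
      f"(~{len(bundle['ema']) / params.n_participants:.0f} per participant)")
print(f"participants:       {len(bundle['participants'])}")
print()
print("per-person glucose→hunger couplings a_i (negative = hungrier when low):")
print(truth.a.round(3).to_string())
print()
print(f"implied true ACME = mean(a_i)·b = {truth.acme:.3f}")
print(f"implied true ADE  = c'          = {truth.ade:.3f}")
# The ACME is positive: lower glucose raises hunger (a_i < 0) and hunger
# lowers mood (b < 0), so higher glucose indirectly lifts mood.
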