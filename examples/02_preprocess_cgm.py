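"""Condition one participant's CGM record and check it against the truth.

Shows the chain: gap segmentation → short-gap interpolation → per-segment
drift correction → stable overnight re-referencing → Gaussian smoothing →
5-min gridding, and how well the output tracks the drift-free signal.
"""

import warnings

import numpy as np

import glycomood as g

warnings.simplefilter("ignore")

params = g.CohortParams(n_participants=1, n_days=10, seed=5,
                        sensor_offset_sd=0.0, noise_sd=1.5)
rng = np.random.default_rng(np.random.SeedSequence(5))
trace = g.simulate_glucose_trace({"basal": 85.0}, params, rng)

grid, report = g.preprocess_participant(trace.observed)

print(f"raw samples:          {report['n_raw_samples']}")
print(f"segments:             {report['n_segments']} "
      "(split at >20-min gaps and sensor changes)")
print(f"interpolated points:  {report['n_interpolated']}")
print(f"stable baseline:      {report['baseline_value']:.1f} mg/dL "
      f"(generative basal: 85.0, night {report['baseline_night']})")

merged = grid.merge(trace.truth, on="timestamp", suffixes=("_proc", "_true"))
r = np.corrcoef(merged["glucose_mg_dl_proc"], merged["glucose_mg_dl_true"])[0, 1]
print(f"corr(processed, drift-free truth): {r:.3f}")
# The baseline lands within ~2 mg/dL of the generative overnight level and
# the processed trace tracks the drift-free physiology despite the injected
# sensor drift, noise and data gaps.
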