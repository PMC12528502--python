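"""Decompose the anatomically informed loss on one prepared sample.

The composite loss is alpha*MAE + beta*PL + gamma*PL_DRR +
omega*PL_structures with flagship weights (1, 0.05, 0.01, 0.04); the four
ablation configurations are nothing but weight settings of the same
function.
"""

from orthosyn import (ABLATION_WEIGHTS, FeatureExtractorSpec, LossWeights,
                      PhantomSpec, PrepSettings, alf_total, make_cohort,
                      prepare_fraction)

spec = PhantomSpec(grid_shape=(32, 32, 16), spacing_mm=(8.0, 8.0, 8.0), n_fractions=1)
cohort = make_cohort(spec, 3, (0.34, 0.33, 0.33), seed=2)
sample = prepare_fraction(cohort.cases[0], 0, PrepSettings())

feat = FeatureExtractorSpec()  # seeded random VGG19-topology backbone
# score the planning CT as if it were the prediction for the daily CBCT
total, parts = alf_total(sample.pct01.data, sample.target01.data,
                         sample.drrs, sample.umask, LossWeights.preset("ALF"), feat)
print("prediction = planning CT (no daily anatomy):")
for name, value in parts.items():
    print(f"  {name:>14s} = {value:.5f}")
print(f"  {'ALF total':>14s} = {total.item():.5f}")

for name, weights in ABLATION_WEIGHTS.items():
    t, _ = alf_total(sample.pct01.data, sample.target01.data, sample.drrs,
                     sample.umask, LossWeights(*weights), feat)
    print(f"{name:>8s} {weights} -> {t.item():.5f}")

# The nonzero components quantify how far yesterday's anatomy is from
# today's: exactly the gap the reconstruction network is trained to close.
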