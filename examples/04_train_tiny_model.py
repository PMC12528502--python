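"""Overfit the flagship model on a single case (a fast convergence check).

Fifty optimisation steps of fusion_skip_res under the anatomically
informed loss on one fraction; the loss should fall by well over half.
"""

from orthosyn import (FeatureExtractorSpec, LossWeights, ModelConfig,
                      PhantomSpec, PrepSettings, build_model, init_weights,
                      make_cohort, prepare_fraction, train_step)
from orthosyn import nn

spec = PhantomSpec(grid_shape=(32, 32, 16), spacing_mm=(8.0, 8.0, 8.0), n_fractions=1)
cohort = make_cohort(spec, 3, (0.34, 0.33, 0.33), seed=11)
sample = prepare_fraction(cohort.cases[0], 0, PrepSettings())

cfg = ModelConfig(variant="fusion_skip_res", in_shape_3d=(32, 32, 16),
                  in_raster_2d=(32, 32), base_channels=8)
model = build_model(cfg)
init_weights(model, seed=0)
opt = nn.AdamW(model.parameters())
weights = LossWeights.preset("ALF")
feat = FeatureExtractorSpec()

for step in range(50):
    loss, parts = train_step(model, opt, sample, weights, feat)
    if step % 10 == 0 or step == 49:
        print(f"step {step:3d}  loss {loss:.4f}  (mae {parts['mae']:.4f})")

# A steadily falling single-case loss confirms gradients flow through the
# encoder-decoder, the differentiable projector and the masked perceptual
# terms alike.
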