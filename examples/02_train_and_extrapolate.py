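"""Train a model with and without virtual-node attention, then compare their
extrapolation to separations beyond the message-passing cutoff.

This runs one seed of the desk-scale study from docs/methods.md (500 frames,
140 epochs, default architecture) and takes a few minutes on one CPU. The
attention-extended model tracks the −k_e/r Coulomb tail on separations it
never saw during training; the local baseline goes flat beyond its cutoff
and its error is an order of magnitude larger.
"""

import numpy as np

from rangeff import (
    COULOMB_CONSTANT, EnergyModel, ModelConfig, TrainingConfig,
    evaluate, gen_dimer_dataset, predict_batch, train,
)

frames, tr, te = gen_dimer_dataset(500, seed=11)
train_f = [frames[i].config for i in tr]
test_f = [frames[i].config for i in te]
seps = np.array([frames[i].separation for i in te])
print(f"training on {len(train_f)} frames (≤ 9 Å), testing on {len(test_f)} (> 9 Å)")

tc = TrainingConfig(epochs=140, batch_size=32, seed=1)

for name, enabled in (("virtual-node attention", True), ("local baseline", False)):
    model = EnergyModel(ModelConfig(range_enabled=enabled), seed=1)
    train(model, train_f, tc)
    mae_e, mae_f = evaluate(model, test_f)
    pred, _ = predict_batch(model, test_f)
    r = np.corrcoef(pred, -COULOMB_CONSTANT / seps)[0, 1]
    print(f"{name:>24}: test MAE {mae_e:6.2f} kcal/mol "
          f"({mae_f:.3f} kcal/mol/Å on forces), "
          f"correlation with Coulomb tail r = {r:+.3f}")

print("the baseline's test error reflects its flat prediction beyond the cutoff;")
print("the attention model infers the separation from its positional encoding")
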