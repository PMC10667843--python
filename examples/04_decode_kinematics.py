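"""Decode hindlimb joint coordinates from multichannel spike counts.

Builds the 26-bin lookback tensor (300 ms of history per video frame, 50 ms
windows stepped by 10 ms), then trains the two-layer LSTM decoder with a
short Bayesian hyperparameter search and compares it with a ridge baseline.
Runs a few minutes on one CPU.
"""

import numpy as np

from spindec import MinMaxNormalizer, SimConfig
from spindec.decode import (
    SMALL_SEARCH_SPACE,
    DecoderConfig,
    evaluate_r2,
    optimize_decoder,
    split_session,
    train_decoder,
)
from spindec.pipeline import run_pipeline

cfg = SimConfig(seed=4, duration_s=17.5, moving_fraction=1.0)
res = run_pipeline(cfg, with_trajectory=False)
valid = res.features.valid
X = res.features.data.astype(float)[valid][:1000]
Y = MinMaxNormalizer().fit_transform(res.kinematics.coordinate_matrix())[valid][:1000]
print(f"session: {len(X)} frames, tensor {X.shape[1]} bins x {X.shape[2]} channels")

results = optimize_decoder(
    X, Y, rounds=8, repeats=2, seed=0,
    space=SMALL_SEARCH_SPACE, base_config=DecoderConfig(epochs=30, patience=5),
)
joints = [f"{j}_{ax}" for j in ("toe", "ankle", "knee", "hip", "iliac") for ax in "xy"]
r2 = np.mean([r.r2_test for r in results], axis=0)
for name, v in zip(joints, r2):
    print(f"  {name:>8}  R^2 = {v:.3f}")

tr, va, te = split_session(len(X))
ridge = train_decoder(X, Y, DecoderConfig(architecture="ridge"), tr, va)
print(f"ridge baseline toe_x R^2 = {evaluate_r2(ridge.predict(X[te]), Y[te])[0]:.3f}")
# Test-set R^2 near 1 means the decoder reconstructs the joint trajectory
# almost perfectly from neural history alone; the recurrent model should
# match or beat the linear baseline.
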