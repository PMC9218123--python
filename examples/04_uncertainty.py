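"""Quantify counting uncertainty with a bootstrap ensemble and MC dropout.

Trains a small bootstrap ensemble (B=3) and runs MC dropout (r=10) on a
single model (around three minutes on one CPU), then reports count +/- 1
sigma per dish.  Both frameworks use the same aggregation: member mean as
the prediction, population variance as the squared 1-sigma uncertainty.
"""

import numpy as np

from sndm import (BootstrapConfig, DropoutInferenceConfig, ModelConfig,
                  SceneParams, TrainConfig, build_model, generate_scene_set,
                  mc_dropout_predict, train)
from sndm.synth import TruncatedExponentialCounts
from sndm.training import predict_counts
from sndm.uncertainty import bootstrap_train

params = SceneParams(
    image_size=96, seed=8,
    count_distribution=TruncatedExponentialCounts(max_count=60, mean=15))
ds = generate_scene_set(120, params, output_stride=2)
train_set, val_set, test_set = (ds.subset(range(96)),
                                ds.subset(range(96, 108)),
                                ds.subset(range(108, 114)))

mcfg = ModelConfig(mode="sndm", input_size=96, output_stride=2,
                   dropout_rate=0.1, seed=1)
tcfg = TrainConfig(max_epochs=15, patience=15, learning_rate=2e-3, seed=0)

model = build_model(mcfg)
train(model, train_set, val_set, tcfg)

print("MC dropout (r=10), one stochastic model:")
for i in range(len(test_set)):
    ens = mc_dropout_predict(model, test_set.images[i],
                             DropoutInferenceConfig(r=10, seed=50 + i))
    print(f"  true {test_set.counts[i]:3d}: "
          f"{ens.mean_count:6.2f} +/- {ens.sigma_count:.2f}")

members = bootstrap_train(train_set, val_set, mcfg, tcfg,
                          BootstrapConfig(B=3, subset_fraction=0.63, seed=4))
per_member = np.stack([predict_counts(m, test_set) for m in members])
mean = per_member.mean(axis=0)
sigma = np.sqrt(((per_member - mean) ** 2).mean(axis=0))
print("\nbootstrap ensemble (B=3, subsets of 0.63N with replacement):")
for i in range(len(test_set)):
    print(f"  true {test_set.counts[i]:3d}: {mean[i]:6.2f} +/- {sigma[i]:.2f}")
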