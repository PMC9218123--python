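"""Bootstrap-ensemble and MC-dropout prediction with 1-sigma uncertainties.

Both frameworks aggregate member predictions identically: the mean is the
prediction and the population variance (divisor B, respectively r — not
B-1) gives the squared 1-sigma uncertainty.  Count statistics are computed
on per-member scalar counts (each the pixel sum of that member's fused map),
never by summing per-pixel variances, because pixels are correlated.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np

from .data import SceneSet
from .model import DensityMapNet, DensityOutputs, ModelConfig, build_model
from .nn.autograd import Tensor
from .training import TrainConfig, train

__all__ = ["BootstrapConfig", "DropoutInferenceConfig", "EnsemblePrediction",
           "bootstrap_subsets", "bootstrap_train", "ensemble_predict",
           "mc_dropout_predict"]

log = logging.getLogger(__name__)


@dataclass
class BootstrapConfig:
    B: int = 20                    # ensemble size
    subset_fraction: float = 0.63  # b / N, drawn with replacement
    seed: int = 0

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.subset_fraction <= 1.0:
            raise ValueError("subset_fraction must be in (0, 1]")


@dataclass
class DropoutInferenceConfig:
    r: int = 20                    # stochastic forward passes
    dropout_active: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if not self.dropout_active:
            raise ValueError("MC dropout requires dropout_active=True")


@dataclass
class EnsemblePrediction:
    mean_count: float
    sigma_count: float
    mean_map: np.ndarray
    sigma_map: np.ndarray
    member_counts: list[float]
    method: str                    # "bootstrap" | "mc_dropout"


# ---------------------------------------------------------------- sampling

def bootstrap_subsets(dataset_ids: list, config: BootstrapConfig) -> list[list]:
    """B multisets of b = round(fraction*N) ids drawn with replacement."""
    N = len(dataset_ids)
    if N < 1:
        raise ValueError("dataset must contain at least one id")
    b = int(round(config.subset_fraction * N))
    if b == 0:
        raise ValueError("subset size b rounded to zero; increase subset_fraction")
    rng = np.random.default_rng(config.seed)
    return [[dataset_ids[j] for j in rng.integers(0, N, size=b)]
            for _ in range(config.B)]


def bootstrap_train(train_set: SceneSet, val_set: SceneSet,
                    model_config: ModelConfig, train_config: TrainConfig,
                    config: BootstrapConfig) -> list[DensityMapNet]:
    """Train B fresh models on with-replacement subsets; shared validation."""
    indices = bootstrap_subsets(list(range(len(train_set))), config)
    seeds = np.random.SeedSequence(config.seed).spawn(config.B)
    members = []
    for i, idx in enumerate(indices):
        s = int(seeds[i].generate_state(1)[0] % (2 ** 31))
        mcfg = copy.deepcopy(model_config)
        mcfg.seed = s
        tcfg = copy.deepcopy(train_config)
        tcfg.seed = s
        model = build_model(mcfg)
        log.info("bootstrap member %d/%d: b=%d", i + 1, config.B, len(idx))
        train(model, train_set.subset(idx), val_set, tcfg)
        members.append(model)
    return members


# ------------------------------------------------------------- aggregation

def ensemble_predict(members: list[DensityOutputs],
                     method: str = "bootstrap") -> EnsemblePrediction:
    """Mean and population-variance 1-sigma over member outputs for one image."""
    if len(members) == 0:
        raise ValueError("ensemble must contain at least one member")
    counts = np.array([m.predicted_count for m in members], dtype=np.float64)
    maps = np.stack([m.P0 for m in members]).astype(np.float64)
    B = len(members)
    if np.all(counts == counts[0]):        # exact-agreement short circuit:
        mean_count, sigma_count = counts[0], 0.0   # sigma is 0, not rounding noise
    else:
        mean_count = counts.mean()
        sigma_count = float(np.sqrt(((mean_count - counts) ** 2).sum() / B))
    mean_map = maps.mean(axis=0)
    if np.all(maps == maps[0]):
        mean_map, sigma_map = maps[0], np.zeros_like(maps[0])
    else:
        sigma_map = np.sqrt(((mean_map[None] - maps) ** 2).sum(axis=0) / B)
    return EnsemblePrediction(mean_count=float(mean_count),
                              sigma_count=sigma_count, mean_map=mean_map,
                              sigma_map=sigma_map,
                              member_counts=counts.tolist(), method=method)


def mc_dropout_predict(model: DensityMapNet, image: np.ndarray,
                       config: DropoutInferenceConfig) -> EnsemblePrediction:
    """r stochastic passes with dropout kept active; same aggregation rules."""
    if model.config.dropout_rate == 0.0 and config.r > 1:
        log.warning("mc_dropout_predict on a model with dropout_rate=0: "
                    "all passes are identical and sigma will be 0")
    from .model import _as_batch  # shared input validation
    x = _as_batch(image, model.config.input_size)
    rng = np.random.default_rng(config.seed)
    members = []
    for _ in range(config.r):
        S, beta = model._forward_graph(Tensor(x), training=True,
                                       dropout_rng=rng)
        P0 = model.probability_maps(S[:1], beta)[0]
        members.append(_LightOutput(P0.data[0, :, :, 0].astype(np.float64)))
    return ensemble_predict(members, method="mc_dropout")


class _LightOutput:
    """Duck-typed stand-in for DensityOutputs carrying only the fused map."""

    def __init__(self, P0: np.ndarray):
        self.P0 = P0
        self.predicted_count = float(P0.sum())
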