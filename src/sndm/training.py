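"""Deep-supervised BCE loss with the beta penalty, and the optimisation loop.

The loss is the pixel-sum binary cross entropy of every probability map
(fused map plus all side maps) against the clipped density target, summed
over maps and images, plus a per-image penalty (1-beta)^2/2 that anchors the
self-normalization parameter near 1.  Optimisation is Adam with L2 weight
decay; the returned checkpoint is the epoch with the best validation metric.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SceneSet
from .model import DensityMapNet, DensityOutputs
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.optim import Adam
from .targets import DensityTarget, loss_view

__all__ = ["LossBreakdown", "TrainConfig", "TrainResult", "bce_map_loss",
           "total_loss", "train"]

log = logging.getLogger(__name__)


@dataclass
class LossBreakdown:
    per_map_bce: list[float]     # one BCE term per map, fused first
    penalty: float               # sum over images of (1-beta)^2 / 2
    total: float

    def __post_init__(self):
        if not np.isclose(self.total, sum(self.per_map_bce) + self.penalty,
                          rtol=1e-9, atol=1e-9):
            raise ValueError("total must equal sum(per_map_bce) + penalty")


@dataclass
class TrainConfig:
    learning_rate: float = 0.0001
    weight_decay: float = 0.0005
    batch_size: int = 2
    max_epochs: int = 100
    early_stopping_metric: str = "val_count_mae"   # or "val_loss"
    patience: int = 10
    penalty_weight: float = 1.0
    clip_eps: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "weight_decay", "batch_size",
                     "max_epochs", "patience", "penalty_weight", "clip_eps"):
            if getattr(self, name) <= 0 and name != "weight_decay":
                raise ValueError(f"{name} must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.early_stopping_metric not in ("val_count_mae", "val_loss"):
            raise ValueError("early_stopping_metric must be val_count_mae or val_loss")


@dataclass
class TrainResult:
    model: DensityMapNet
    history: pd.DataFrame
    best_epoch: int
    best_metric: float


# -------------------------------------------------------------------- losses

def bce_map_loss(P: np.ndarray, P_G: np.ndarray) -> float:
    """Pixel-sum binary cross entropy  -sum[ P_G ln P + (1-P_G) ln(1-P) ]."""
    P = np.asarray(P, dtype=np.float64)
    P_G = np.asarray(P_G, dtype=np.float64)
    if P.shape != P_G.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {P_G.shape}")
    if np.any(P <= 0) or np.any(P >= 1):
        raise ValueError("P must lie strictly inside (0, 1)")
    return float(-(P_G * np.log(P) + (1.0 - P_G) * np.log(1.0 - P)).sum())


def _one_loss(outputs: DensityOutputs, view: np.ndarray) -> list[float]:
    return [bce_map_loss(P, view) for P in outputs.maps]


def total_loss(outputs: DensityOutputs | list[DensityOutputs],
               target_loss_view: np.ndarray | list[np.ndarray],
               beta: float | list[float]) -> LossBreakdown:
    """Deep-supervision loss: one BCE term per map plus the beta penalty.

    Accepts a single image's outputs or a batch (lists); per-map terms are
    summed over the batch, as is the penalty.
    """
    if isinstance(outputs, DensityOutputs):
        outputs, target_loss_view, beta = [outputs], [target_loss_view], [beta]
    per_map = None
    for out, view in zip(outputs, target_loss_view):
        terms = _one_loss(out, view)
        per_map = terms if per_map is None else [a + b for a, b in zip(per_map, terms)]
    penalty = float(sum(0.5 * (1.0 - b) ** 2 for b in beta))
    return LossBreakdown(per_map_bce=per_map, penalty=penalty,
                         total=sum(per_map) + penalty)


# ---------------------------------------------------------------- internals

def _clipped_targets(ds: SceneSet, eps: float) -> list[np.ndarray]:
    return [loss_view(DensityTarget(map=t, count=float(t.sum())), eps=eps)
            for t in ds.targets]


def _batch_tensor(images: np.ndarray) -> Tensor:
    return Tensor(np.ascontiguousarray(images))


def _np_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _eval_split(model: DensityMapNet, ds: SceneSet, views: list[np.ndarray],
                penalty_weight: float, batch: int = 8):
    """Deterministic pass over a split: counts, loss, mean beta."""
    n = len(ds)
    counts = np.empty(n)
    betas = np.empty(n)
    loss = 0.0
    for lo in range(0, n, batch):
        hi = min(lo + batch, n)
        x = _batch_tensor(ds.images[lo:hi])
        S, beta = model._forward_graph(x, training=False)
        b = beta.data.reshape(-1).astype(np.float64)
        T = np.stack(views[lo:hi])[..., None]
        for s in S:
            z = b[:, None, None, None] * s.data.astype(np.float64)
            loss += float((np.maximum(z, 0) - z * T
                           + np.log1p(np.exp(-np.abs(z)))).sum())
        z0 = b[:, None, None, None] * S[0].data.astype(np.float64)
        counts[lo:hi] = _np_sigmoid(z0).sum(axis=(1, 2, 3))
        betas[lo:hi] = b
        loss += penalty_weight * float((0.5 * (1.0 - b) ** 2).sum())
    return counts, loss, float(betas.mean())


def predict_counts(model: DensityMapNet, ds: SceneSet, batch: int = 8,
                   return_beta: bool = False):
    """Dropout-free predicted counts (pixel sums of P_0) for a SceneSet."""
    n = len(ds)
    counts = np.empty(n)
    betas = np.empty(n)
    for lo in range(0, n, batch):
        hi = min(lo + batch, n)
        x = _batch_tensor(ds.images[lo:hi])
        S, beta = model._forward_graph(x, training=False)
        P0 = model.probability_maps(S[:1], beta)[0].data.astype(np.float64)
        counts[lo:hi] = P0.sum(axis=(1, 2, 3))
        betas[lo:hi] = beta.data.reshape(-1).astype(np.float64)
    return (counts, betas) if return_beta else counts


# -------------------------------------------------------------------- train

def train(model: DensityMapNet, train_set: SceneSet, val_set: SceneSet,
          config: TrainConfig) -> TrainResult:
    """Adam-optimised deep-supervision training with validation selection."""
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    dropout_rng = np.random.default_rng(rng.integers(2 ** 31))
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    train_views = _clipped_targets(train_set, config.clip_eps)
    val_views = _clipped_targets(val_set, config.clip_eps)

    rows = []
    best_metric, best_state, best_epoch = np.inf, None, -1
    bad_epochs = 0
    n = len(train_set)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        train_loss = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            x = _batch_tensor(train_set.images[idx])
            T = np.stack([train_views[i] for i in idx])[..., None]
            S, beta = model._forward_graph(x, training=True,
                                           dropout_rng=dropout_rng)
            b4 = ag.reshape(beta, (len(idx), 1, 1, 1))
            loss = None
            for s in S:
                term = ag.bce_with_logits_sum(ag.mul(b4, s), T)
                loss = term if loss is None else ag.add(loss, term)
            ones = Tensor(np.ones_like(beta.data))
            pen = ag.sum_all(ag.pow_const(ag.sub(ones, beta), 2.0))
            pen = ag.mul(Tensor(np.asarray(0.5 * config.penalty_weight,
                                           dtype=beta.data.dtype)), pen)
            loss = ag.add(loss, pen)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_loss += loss.item()

        val_counts, val_loss, mean_beta = _eval_split(
            model, val_set, val_views, config.penalty_weight)
        val_mae = float(np.abs(val_counts - val_set.counts).mean())
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss, "val_count_mae": val_mae,
                     "mean_beta": mean_beta})
        log.info("epoch %d train_loss=%.3f val_loss=%.3f val_mae=%.3f beta=%.4f",
                 epoch, train_loss, val_loss, val_mae, mean_beta)

        metric = val_mae if config.early_stopping_metric == "val_count_mae" else val_loss
        if metric < best_metric:
            best_metric, best_epoch = metric, epoch
            best_state = copy.deepcopy(model.state_dict())
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainResult(model=model, history=pd.DataFrame(rows),
                       best_epoch=best_epoch, best_metric=best_metric)
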