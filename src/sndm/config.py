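"""Run configuration (YAML, schema-validated) and the end-to-end smoke workflow.

Defaults follow the published training protocol: Adam with learning rate
0.0001, weight decay 0.0005, minibatch 2; bootstrap B=20 with subset
fraction 0.63; MC dropout r=20; beta activation bound lambda=1.5.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import synth, targets as tg
from .data import SceneSet, generate_scene_set, load_dataset_dir
from .evaluation import evaluate
from .model import ModelConfig, build_model
from .training import TrainConfig, train
from .uncertainty import BootstrapConfig, DropoutInferenceConfig, bootstrap_train

__all__ = ["RunConfig", "load_config", "smoke_pipeline"]

log = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", protected_namespaces=(),
                              populate_by_name=True)


class SceneSection(_Strict):
    image_size: int = 96
    p_low: float = 0.85           # P(count < threshold)
    count_threshold: int = 50
    max_count: int = 100
    low_mean: float = 18.0
    radius_median_px: float = 2.5
    radius_sigma_log: float = 0.35
    illumination_mode: str = "random"
    overlap_allowed: bool = True
    noise_sigma: float = 0.01

    def to_params(self, seed: int) -> synth.SceneParams:
        return synth.SceneParams(
            image_size=self.image_size,
            count_distribution=synth.LowCountMixture(
                p_low=self.p_low, threshold=self.count_threshold,
                max_count=self.max_count, low_mean=self.low_mean),
            radius_distribution=synth.LogNormalRadius(
                median_px=self.radius_median_px, sigma_log=self.radius_sigma_log),
            illumination_mode=self.illumination_mode,
            overlap_allowed=self.overlap_allowed,
            noise_sigma=self.noise_sigma, seed=seed)


class KernelSection(_Strict):
    sigma: float | str = "adaptive"
    truncation_radius: float | None = None

    def to_spec(self) -> tg.KernelSpec:
        if self.sigma == "adaptive":
            return tg.KernelSpec(adaptive=True,
                                 truncation_radius=self.truncation_radius)
        return tg.KernelSpec(sigma_blur=float(self.sigma), adaptive=False,
                             truncation_radius=self.truncation_radius)


class ModelSection(_Strict):
    mode: str = "sndm"
    input_size: int = 96
    n_stages: int = 3
    base_channels: int = 8
    rsu_depths: list[int] | None = None
    dropout_rate: float = 0.1
    beta_activation: str = "scaled_sigmoid"
    lambda_: float = Field(default=1.5, alias="lambda")
    output_stride: int = 1

    def to_config(self, mode: str | None = None, seed: int = 0) -> ModelConfig:
        return ModelConfig(mode=mode or self.mode, input_size=self.input_size,
                           n_stages=self.n_stages,
                           base_channels=self.base_channels,
                           rsu_depths=(list(self.rsu_depths)
                                       if self.rsu_depths else None),
                           dropout_rate=self.dropout_rate,
                           beta_activation=self.beta_activation,
                           lambda_=self.lambda_,
                           output_stride=self.output_stride, seed=seed)


class TrainSection(_Strict):
    learning_rate: float = 0.0001
    weight_decay: float = 0.0005
    batch_size: int = 2
    max_epochs: int = 100
    early_stopping_metric: str = "val_count_mae"
    patience: int = 10
    penalty_weight: float = 1.0

    def to_config(self, seed: int = 0, **overrides) -> TrainConfig:
        kw = dict(learning_rate=self.learning_rate,
                  weight_decay=self.weight_decay, batch_size=self.batch_size,
                  max_epochs=self.max_epochs,
                  early_stopping_metric=self.early_stopping_metric,
                  patience=self.patience, penalty_weight=self.penalty_weight,
                  seed=seed)
        kw.update(overrides)
        return TrainConfig(**kw)


class BootstrapSection(_Strict):
    B: int = 20
    subset_fraction: float = 0.63

    def to_config(self, seed: int = 0) -> BootstrapConfig:
        return BootstrapConfig(B=self.B, subset_fraction=self.subset_fraction,
                               seed=seed)


class DropoutSection(_Strict):
    r: int = 20

    def to_config(self, seed: int = 0) -> DropoutInferenceConfig:
        return DropoutInferenceConfig(r=self.r, seed=seed)


class EvaluationSection(_Strict):
    stratum_threshold: int = 50


class SmokeSection(_Strict):
    """Problem sizes of the end-to-end smoke workflow (kept desk-tiny)."""

    n_images: int = 24
    image_size: int = 48
    max_epochs: int = 2
    B: int = 2
    r: int = 4


class RunConfig(_Strict):
    seed: int = 0
    scene: SceneSection = Field(default_factory=SceneSection)
    kernel: KernelSection = Field(default_factory=KernelSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    bootstrap: BootstrapSection = Field(default_factory=BootstrapSection)
    dropout: DropoutSection = Field(default_factory=DropoutSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)
    smoke: SmokeSection = Field(default_factory=SmokeSection)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed split from the global seed."""
        h = np.random.SeedSequence([self.seed, abs(hash(stage)) % (2 ** 31)])
        return int(h.generate_state(1)[0] % (2 ** 31))


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run config; empty/missing file yields full defaults."""
    payload = {}
    if path is not None:
        text = Path(path).read_text()
        payload = yaml.safe_load(text) or {}
    cfg = RunConfig(**payload)
    log.info("resolved config: %s", cfg.model_dump(by_alias=True))
    return cfg


# --------------------------------------------------------------- smoke run

def smoke_pipeline(config: RunConfig, workdir: str | Path) -> dict:
    """Generate, train (dm and sndm), predict with all three methods, evaluate.

    A miniature end-to-end pass through every stage of the toolchain; writes
    a summary JSON plus per-model history CSVs under `workdir`.
    """
    workdir = Path(workdir)
    sm = config.smoke

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise RuntimeError(f"smoke pipeline failed at stage '{name}': {e}") from e

    def _generate():
        workdir.mkdir(parents=True, exist_ok=True)
        probe = workdir / ".write-probe"
        probe.write_text("ok")
        probe.unlink()
        scene = config.scene.model_copy(update={"image_size": sm.image_size})
        params = scene.to_params(seed=config.stage_seed("generate"))
        ds = generate_scene_set(sm.n_images, params, config.kernel.to_spec())
        n_val = max(len(ds) // 6, 1)
        return (ds.subset(range(len(ds) - 2 * n_val)),
                ds.subset(range(len(ds) - 2 * n_val, len(ds) - n_val)),
                ds.subset(range(len(ds) - n_val, len(ds))))

    train_set, val_set, test_set = stage("generate", _generate)

    summary: dict = {"seed": config.seed, "models": {}}
    models = {}
    for mode in ("dm", "sndm"):
        def _train(mode=mode):
            mcfg = config.model.to_config(
                mode=mode, seed=config.stage_seed(f"train-{mode}"))
            mcfg.input_size = sm.image_size
            net = build_model(mcfg)
            tcfg = config.train.to_config(seed=config.stage_seed(f"opt-{mode}"),
                                          max_epochs=sm.max_epochs,
                                          patience=sm.max_epochs)
            result = train(net, train_set, val_set, tcfg)
            result.history.to_csv(workdir / f"history-{mode}.csv", index=False)
            return net, result

        models[mode], result = stage(f"train-{mode}", _train)
        summary["models"][mode] = {
            "best_epoch": result.best_epoch,
            "mean_beta_trajectory": result.history["mean_beta"].tolist(),
        }

    for mode in ("dm", "sndm"):
        def _evaluate(mode=mode):
            net = models[mode]
            out = {}
            rep, frame = evaluate(net, test_set, method="single",
                                  stratum_threshold=config.evaluation.stratum_threshold)
            out["single"] = rep
            frame.to_csv(workdir / f"records-{mode}-single.csv", index=False)
            bcfg = BootstrapConfig(B=sm.B, subset_fraction=config.bootstrap.subset_fraction,
                                   seed=config.stage_seed(f"boot-{mode}"))
            mcfg = config.model.to_config(mode=mode, seed=0)
            mcfg.input_size = sm.image_size
            tcfg = config.train.to_config(seed=0, max_epochs=sm.max_epochs,
                                          patience=sm.max_epochs)
            members = bootstrap_train(train_set, val_set, mcfg, tcfg, bcfg)
            rep_b, _ = evaluate(members, test_set, method="bootstrap")
            out["bootstrap"] = rep_b
            dcfg = DropoutInferenceConfig(r=sm.r,
                                          seed=config.stage_seed(f"mc-{mode}"))
            rep_d, _ = evaluate(net, test_set, method="mc_dropout",
                                dropout_config=dcfg)
            out["mc_dropout"] = rep_d
            return out

        reports = stage(f"evaluate-{mode}", _evaluate)
        for method, rep in reports.items():
            summary["models"][mode][method] = {
                "mae": rep.mae, "smape": rep.smape,
                "within_1sigma": rep.within_1sigma,
                "mean_sigma": rep.mean_sigma,
                "stratified": rep.stratified.to_dict(orient="records"),
            }

    def _write():
        (workdir / "summary.json").write_text(json.dumps(summary, indent=1))
        return summary

    return stage("write-summary", _write)
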