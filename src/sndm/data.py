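"""In-memory datasets pairing rendered scenes with density-map targets."""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import synth, targets as tg

__all__ = ["SceneSet", "generate_scene_set", "load_dataset_dir"]


@dataclass
class SceneSet:
    """Aligned arrays of images, density targets and per-image covariates."""

    images: np.ndarray                       # (N, H, W, 3) float32
    targets: list[np.ndarray]                # N maps (Ht, Wt) float64
    counts: np.ndarray                       # (N,) int
    coverages: np.ndarray                    # (N,) float
    mean_sizes: np.ndarray                   # (N,) float (NaN when empty)
    ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, indices) -> "SceneSet":
        idx = list(indices)
        return SceneSet(images=self.images[idx],
                        targets=[self.targets[i] for i in idx],
                        counts=self.counts[idx],
                        coverages=self.coverages[idx],
                        mean_sizes=self.mean_sizes[idx],
                        ids=[self.ids[i] for i in idx])


def _target_for(annotation: synth.ColonyAnnotation, shape: tuple[int, int],
                kernel: tg.KernelSpec) -> np.ndarray:
    scale = shape[0] / annotation.geometry.image_height
    sigma = kernel.resolve_sigma(annotation, scale=scale)
    centers = tg.centers_from_bboxes(annotation, shape)
    return tg.render_density_target(centers, shape, kernel, sigma=sigma,
                                    scale_factor=scale).map


def generate_scene_set(n: int, params: synth.SceneParams,
                       kernel: tg.KernelSpec | None = None,
                       output_stride: int = 1) -> SceneSet:
    """Render `n` scenes (seeds spawned from params.seed) with their targets."""
    kernel = kernel or tg.KernelSpec()
    size = params.image_size
    shape = (size // output_stride, size // output_stride)
    children = np.random.SeedSequence(params.seed).spawn(n)
    images, targets_, counts, covs, sizes, ids = [], [], [], [], [], []
    for i, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        scene = synth.generate_scene(dataclasses.replace(params, seed=seed))
        images.append(scene.image)
        targets_.append(_target_for(scene.annotation, shape, kernel))
        counts.append(scene.annotation.count)
        covs.append(scene.coverage)
        sizes.append(scene.mean_colony_size)
        ids.append(f"img-{i:05d}")
    return SceneSet(images=np.stack(images), targets=targets_,
                    counts=np.asarray(counts), coverages=np.asarray(covs),
                    mean_sizes=np.asarray(sizes), ids=ids)


def load_dataset_dir(path: str | Path, kernel: tg.KernelSpec | None = None,
                     output_stride: int = 1) -> dict[str, SceneSet]:
    """Read a generated dataset directory into train/val/test SceneSets."""
    kernel = kernel or tg.KernelSpec()
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    records = {r["id"]: r for r in synth.read_annotations(path / "annotations.json")}
    out = {}
    for split in ("train", "val", "test"):
        images, targets_, counts, covs, sizes, ids = [], [], [], [], [], []
        for image_id in manifest[split]:
            rec = records[image_id]
            ann = rec["annotation"]
            img = np.asarray(Image.open(path / rec["file"]), dtype=np.float32) / 255.0
            shape = (img.shape[0] // output_stride, img.shape[1] // output_stride)
            images.append(img)
            targets_.append(_target_for(ann, shape, kernel))
            counts.append(ann.count)
            covs.append(rec.get("coverage", math.nan))
            ms = rec.get("mean_colony_size")
            sizes.append(math.nan if ms is None else ms)
            ids.append(image_id)
        out[split] = SceneSet(images=np.stack(images) if images else
                              np.zeros((0, 0, 0, 3), np.float32),
                              targets=targets_, counts=np.asarray(counts),
                              coverages=np.asarray(covs),
                              mean_sizes=np.asarray(sizes), ids=ids)
    return out
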