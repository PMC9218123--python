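"""Synthetic annotated Petri-dish scenes.

Emulates the statistical structure of higher-resolution colony-counting
benchmarks: a circular dish on a dark table, 0-100 colonies per image with
most images below 50, colony radii drawn from a log-normal (so dishes mix
large and tiny colonies), overlapping and near-edge colonies, and several
background illumination variants.  Colonies are rendered as soft-edged disks;
each is annotated with a half-open, 0-based integer bounding box whose center
lies inside the dish circle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "DishGeometry", "ColonyAnnotation", "SceneParams", "SyntheticScene",
    "LowCountMixture", "TruncatedExponentialCounts", "LogNormalRadius",
    "ILLUMINATION_MODES", "generate_scene", "generate_dataset",
    "coverage_factor", "mean_colony_size", "write_annotations",
    "read_annotations",
]

ILLUMINATION_MODES = ("uniform", "gradient", "vignette")

_MAX_COUNT = 100


# ------------------------------------------------------------------ geometry

@dataclass(frozen=True)
class DishGeometry:
    """Circular dish footprint inside the image, in pixel units."""

    image_width: int
    image_height: int
    dish_center_x: float
    dish_center_y: float
    dish_radius: float

    def __post_init__(self):
        if self.dish_radius <= 0:
            raise ValueError("dish_radius must be positive")
        if (self.dish_center_x - self.dish_radius < 0
                or self.dish_center_y - self.dish_radius < 0
                or self.dish_center_x + self.dish_radius > self.image_width
                or self.dish_center_y + self.dish_radius > self.image_height):
            raise ValueError("dish circle must lie fully inside image bounds")

    def contains(self, x: float, y: float) -> bool:
        dx = x - self.dish_center_x
        dy = y - self.dish_center_y
        return dx * dx + dy * dy <= self.dish_radius ** 2


@dataclass
class ColonyAnnotation:
    """Per-image colony labels: half-open integer boxes [x_min,x_max)x[y_min,y_max)."""

    image_id: str
    geometry: DishGeometry
    boxes: list[tuple[int, int, int, int]]
    species_labels: list[str | None] | None = None

    def __post_init__(self):
        for (x0, y0, x1, y1) in self.boxes:
            if not (x0 < x1 and y0 < y1):
                raise ValueError(f"degenerate box {(x0, y0, x1, y1)}")
            cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
            if not self.geometry.contains(cx, cy):
                raise ValueError(f"box center ({cx}, {cy}) outside dish circle")
        if self.species_labels is not None and len(self.species_labels) != len(self.boxes):
            raise ValueError("species_labels length must match boxes")

    @property
    def count(self) -> int:
        return len(self.boxes)


# ------------------------------------------------------------- distributions

class LowCountMixture:
    """Counts on 0..max_count: P(count < threshold) = p_low exactly.

    Below the threshold, counts follow a discretised exponential (crowded
    dishes are rarer than sparse ones); at or above it, counts are uniform.
    Defaults put 85% of the mass below 50 colonies.
    """

    def __init__(self, p_low: float = 0.85, threshold: int = 50,
                 max_count: int = _MAX_COUNT, low_mean: float = 18.0):
        if not 0.0 < p_low < 1.0:
            raise ValueError("p_low must be in (0,1)")
        if not 0 < threshold <= max_count <= _MAX_COUNT:
            raise ValueError("need 0 < threshold <= max_count <= 100")
        self.p_low = p_low
        self.threshold = threshold
        self.max_count = max_count
        self.low_mean = low_mean
        k = np.arange(threshold)
        w = np.exp(-k / low_mean)
        self._low_pmf = w / w.sum()

    def sample(self, rng: np.random.Generator) -> int:
        if rng.random() < self.p_low:
            return int(rng.choice(self.threshold, p=self._low_pmf))
        return int(rng.integers(self.threshold, self.max_count + 1))


class TruncatedExponentialCounts:
    """Heavy-tailed-toward-zero counts on 0..max_count (discretised exponential)."""

    def __init__(self, max_count: int = 60, mean: float = 15.0):
        if not 0 < max_count <= _MAX_COUNT:
            raise ValueError("max_count must be in 1..100")
        self.max_count = max_count
        self.mean = mean
        k = np.arange(max_count + 1)
        w = np.exp(-k / mean)
        self._pmf = w / w.sum()

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.max_count + 1, p=self._pmf))


class LogNormalRadius:
    """Colony radius in pixels: log-normal, clamped to [min_px, max_px]."""

    def __init__(self, median_px: float = 2.5, sigma_log: float = 0.35,
                 min_px: float = 1.2, max_px: float | None = None):
        if median_px <= 0 or min_px <= 0:
            raise ValueError("radii must be positive")
        self.median_px = median_px
        self.sigma_log = sigma_log
        self.min_px = min_px
        self.max_px = max_px

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        r = np.exp(rng.normal(math.log(self.median_px), self.sigma_log, n))
        hi = self.max_px if self.max_px is not None else np.inf
        return np.clip(r, self.min_px, hi)


@dataclass
class SceneParams:
    """Knobs of the scene generator; `seed` makes a scene bit-reproducible."""

    image_size: int = 96
    count_distribution: LowCountMixture | TruncatedExponentialCounts = field(
        default_factory=LowCountMixture)
    radius_distribution: LogNormalRadius = field(default_factory=LogNormalRadius)
    illumination_mode: str = "random"   # one of ILLUMINATION_MODES or "random"
    overlap_allowed: bool = True
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.illumination_mode not in ILLUMINATION_MODES + ("random",):
            raise ValueError(f"unknown illumination_mode {self.illumination_mode!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SyntheticScene:
    image: np.ndarray                 # (H, W, 3) float32 in [0,1]
    annotation: ColonyAnnotation
    coverage: float                   # colony area fraction of the dish
    mean_colony_size: float           # mean equivalent diameter; NaN when empty


# ------------------------------------------------------------------- helpers

_MEDIUM_RGB = np.array([0.56, 0.52, 0.44])   # agar growth medium
_TABLE_RGB = np.array([0.13, 0.13, 0.16])
_COLONY_RGB = np.array([0.88, 0.84, 0.70])


def _illumination_field(mode: str, H: int, W: int, geom: DishGeometry,
                        rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    if mode == "uniform":
        return np.full((H, W), 1.0)
    if mode == "gradient":
        theta = rng.uniform(0, 2 * math.pi)
        t = (np.cos(theta) * xx + np.sin(theta) * yy)
        t = (t - t.min()) / max(t.max() - t.min(), 1e-9)
        return 0.78 + 0.34 * t
    # vignette: bright above the dish center, darker toward the rim
    d = np.hypot(xx - geom.dish_center_x, yy - geom.dish_center_y)
    return 1.08 - 0.30 * np.clip(d / geom.dish_radius, 0, 1.4)


def _place_centers(rng: np.random.Generator, geom: DishGeometry,
                   radii: np.ndarray, overlap_allowed: bool) -> np.ndarray:
    """Uniform-in-disc colony centers; near-edge placements permitted."""
    centers = np.empty((len(radii), 2))
    R = geom.dish_radius
    for i, r in enumerate(radii):
        max_d = max(R - 1.5 - 0.5 * r, 1.0)
        best, best_sep = None, -np.inf
        attempts = 1 if overlap_allowed else 200
        for _ in range(attempts):
            u, theta = rng.random(), rng.uniform(0, 2 * math.pi)
            d = max_d * math.sqrt(u)
            x = geom.dish_center_x + d * math.cos(theta)
            y = geom.dish_center_y + d * math.sin(theta)
            if i == 0 or overlap_allowed:
                best = (x, y)
                break
            sep = np.min(np.hypot(centers[:i, 0] - x, centers[:i, 1] - y)
                         - (radii[:i] + r))
            if sep > best_sep:
                best, best_sep = (x, y), sep
            if sep >= 0:
                break
        centers[i] = best
    return centers


# ---------------------------------------------------------------- operations

def generate_scene(params: SceneParams,
                   count_override: int | None = None) -> SyntheticScene:
    """Render one annotated dish scene; identical params give identical scenes."""
    if count_override is not None and not (0 <= count_override <= _MAX_COUNT):
        raise ValueError("count out of modeled range (0..100)")
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    H = W = size

    cx = W / 2.0 + rng.uniform(-0.02, 0.02) * size
    cy = H / 2.0 + rng.uniform(-0.02, 0.02) * size
    R = 0.46 * size * (1.0 + rng.uniform(-0.02, 0.02))
    R = min(R, cx - 0.5, cy - 0.5, W - 0.5 - cx, H - 0.5 - cy)
    geom = DishGeometry(W, H, cx, cy, R)

    mode = params.illumination_mode
    if mode == "random":
        mode = ILLUMINATION_MODES[rng.integers(len(ILLUMINATION_MODES))]

    count = params.count_distribution.sample(rng)
    if count_override is not None:
        count = count_override
    radii = params.radius_distribution.sample(rng, count)
    centers = _place_centers(rng, geom, radii, params.overlap_allowed)

    # --- background
    field_ = _illumination_field(mode, H, W, geom, rng)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    d = np.hypot(xx - cx, yy - cy)
    dish = d <= R
    img = np.where(dish[..., None], _MEDIUM_RGB, _TABLE_RGB) * field_[..., None]
    rim = np.clip(1.0 - np.abs(d - R) / 1.5, 0, 1)
    img *= (1.0 - 0.45 * rim)[..., None]

    # --- colonies (windowed soft disks) + hard mask for coverage
    mask = np.zeros((H, W), dtype=bool)
    boxes: list[tuple[int, int, int, int]] = []
    edge = 1.0
    for (x, y), r in zip(centers, radii):
        tint = _COLONY_RGB * rng.uniform(0.9, 1.1)
        x0 = max(int(math.floor(x - r - edge - 1)), 0)
        x1 = min(int(math.ceil(x + r + edge + 1)) + 1, W)
        y0 = max(int(math.floor(y - r - edge - 1)), 0)
        y1 = min(int(math.ceil(y + r + edge + 1)) + 1, H)
        wy, wx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
        dist = np.hypot(wx - x, wy - y)
        w = np.clip((r + edge / 2 - dist) / edge, 0.0, 1.0)
        img[y0:y1, x0:x1] = (img[y0:y1, x0:x1] * (1 - w[..., None])
                             + tint * field_[y0:y1, x0:x1, None] * w[..., None])
        mask[y0:y1, x0:x1] |= dist <= r

        bx0, bx1 = int(math.floor(x - r)), int(math.ceil(x + r))
        by0, by1 = int(math.floor(y - r)), int(math.ceil(y + r))
        bx0, by0 = max(bx0, 0), max(by0, 0)
        bx1, by1 = min(max(bx1, bx0 + 1), W), min(max(by1, by0 + 1), H)
        boxes.append((bx0, by0, bx1, by1))

    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    ann = ColonyAnnotation(image_id=f"scene-{params.seed}", geometry=geom,
                           boxes=boxes)
    cov = coverage_factor(ann, mask)
    return SyntheticScene(image=img, annotation=ann, coverage=cov,
                          mean_colony_size=mean_colony_size(ann))


def coverage_factor(annotation: ColonyAnnotation, colony_mask: np.ndarray) -> float:
    """Fraction of dish-interior pixels covered by colonies."""
    geom = annotation.geometry
    if colony_mask.shape != (geom.image_height, geom.image_width):
        raise ValueError("mask shape must match the annotated image")
    yy, xx = np.mgrid[0:geom.image_height, 0:geom.image_width]
    inside = (np.hypot(xx - geom.dish_center_x, yy - geom.dish_center_y)
              <= geom.dish_radius)
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise ValueError("dish interior contains no pixels; coverage undefined")
    return float((colony_mask & inside).sum() / n_inside)


def mean_colony_size(annotation: ColonyAnnotation) -> float:
    """Mean equivalent diameter sqrt(w*h) over boxes; NaN when the dish is empty."""
    if annotation.count == 0:
        return float("nan")
    sizes = [math.sqrt((x1 - x0) * (y1 - y0))
             for (x0, y0, x1, y1) in annotation.boxes]
    return float(np.mean(sizes))


# ----------------------------------------------------------------------- I/O

def _annotation_record(ann: ColonyAnnotation, file: str,
                       extras: dict | None = None) -> dict:
    g = ann.geometry
    rec = {
        "id": ann.image_id,
        "file": file,
        "width": g.image_width,
        "height": g.image_height,
        "dish": {"cx": g.dish_center_x, "cy": g.dish_center_y, "r": g.dish_radius},
        "colonies": [
            {"x_min": x0, "y_min": y0, "x_max": x1, "y_max": y1,
             "label": (ann.species_labels[i] if ann.species_labels else None)}
            for i, (x0, y0, x1, y1) in enumerate(ann.boxes)
        ],
    }
    if extras:
        rec.update(extras)
    return rec


def write_annotations(path: str | Path, records: list[dict]) -> None:
    Path(path).write_text(json.dumps({"images": records}, indent=1))


def read_annotations(path: str | Path) -> list[dict]:
    """Parse the annotation JSON; each record gains an `annotation` object."""
    payload = json.loads(Path(path).read_text())
    out = []
    for rec in payload["images"]:
        geom = DishGeometry(rec["width"], rec["height"], rec["dish"]["cx"],
                            rec["dish"]["cy"], rec["dish"]["r"])
        boxes = [(c["x_min"], c["y_min"], c["x_max"], c["y_max"])
                 for c in rec["colonies"]]
        labels = [c.get("label") for c in rec["colonies"]] or None
        rec = dict(rec)
        rec["annotation"] = ColonyAnnotation(rec["id"], geom, boxes, labels)
        out.append(rec)
    return out


def generate_dataset(n_images: int, params: SceneParams, out_dir: str | Path,
                     split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     ) -> dict:
    """Write n_images PNG scenes + annotations.json + a train/val/test manifest."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(params.seed).spawn(n_images)
    records = []
    for i, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        scene = generate_scene(dataclasses.replace(params, seed=seed))
        image_id = f"img-{i:05d}"
        scene.annotation.image_id = image_id
        fname = f"{image_id}.png"
        arr = np.clip(np.rint(scene.image * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out / fname)
        records.append(_annotation_record(
            scene.annotation, fname,
            extras={"coverage": scene.coverage,
                    "mean_colony_size": (None if math.isnan(scene.mean_colony_size)
                                         else scene.mean_colony_size),
                    "seed": seed}))
    write_annotations(out / "annotations.json", records)

    n_val = int(round(split_fractions[1] * n_images))
    n_test = int(round(split_fractions[2] * n_images))
    ids = [r["id"] for r in records]
    manifest = {
        "n_images": n_images,
        "fractions": list(split_fractions),
        "train": ids[: n_images - n_val - n_test],
        "val": ids[n_images - n_val - n_test: n_images - n_test],
        "test": ids[n_images - n_test:],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
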