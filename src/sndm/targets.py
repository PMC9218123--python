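"""Bounding-box annotations -> count-conserving density-map targets.

Each colony contributes one Gaussian kernel centred at its bounding-box
center.  The kernel is truncated to a finite window, clipped at map edges,
and renormalised per colony to unit mass, so the pixel sum of the target
equals the colony count exactly (up to float rounding) and superposition
holds.  Counting any density map back is just the pixel sum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .synth import ColonyAnnotation

__all__ = ["KernelSpec", "DensityTarget", "centers_from_bboxes",
           "render_density_target", "count_from_map", "loss_view"]

log = logging.getLogger(__name__)

#: floor on the Gaussian sigma: keeps an isolated kernel's peak 1/(2*pi*s^2) <= 1
MIN_SIGMA = 0.4


@dataclass
class KernelSpec:
    """Gaussian blur applied to each colony's center impulse.

    `sigma_blur` is the standard deviation in target pixels.  In adaptive
    mode sigma is 0.25x the mean bounding-box side (at target resolution),
    floored at MIN_SIGMA; `sigma_blur` then acts as an explicit override if
    set.  The kernel window is truncated at `truncation_radius` (default
    4 sigma, never below 3 sigma).
    """

    sigma_blur: float | None = None
    truncation_radius: float | None = None
    adaptive: bool = True

    def __post_init__(self):
        if self.sigma_blur is not None and self.sigma_blur < MIN_SIGMA:
            raise ValueError(f"sigma_blur must be >= {MIN_SIGMA}")
        if (self.sigma_blur is None) and not self.adaptive:
            raise ValueError("fixed-sigma mode requires sigma_blur")

    def resolve_sigma(self, annotation: ColonyAnnotation | None = None,
                      scale: float = 1.0) -> float:
        if self.sigma_blur is not None:
            return float(self.sigma_blur)
        if annotation is None or annotation.count == 0:
            return MIN_SIGMA
        side = np.mean([((x1 - x0) + (y1 - y0)) / 2.0
                        for (x0, y0, x1, y1) in annotation.boxes])
        return max(0.25 * side * scale, MIN_SIGMA)

    def resolve_truncation(self, sigma: float) -> float:
        if self.truncation_radius is not None:
            if self.truncation_radius < 3.0 * sigma:
                raise ValueError("truncation_radius must be >= 3*sigma")
            return float(self.truncation_radius)
        return 4.0 * sigma


@dataclass
class DensityTarget:
    """Ground-truth density map: non-negative, pixel sum == colony count."""

    map: np.ndarray       # (H_t, W_t) float64
    count: float
    scale_factor: float = 1.0

    def __post_init__(self):
        if np.any(self.map < 0):
            raise ValueError("density map entries must be non-negative")
        if not math.isclose(float(self.map.sum()), self.count,
                            rel_tol=1e-6, abs_tol=1e-6):
            raise ValueError("pixel sum of the map must equal the count")


def centers_from_bboxes(annotation: ColonyAnnotation,
                        target_shape: tuple[int, int]) -> list[tuple[float, float]]:
    """Box centers as (row, col), rescaled from image to target resolution."""
    Ht, Wt = target_shape
    if Ht <= 0 or Wt <= 0:
        raise ValueError("target_shape must be positive")
    g = annotation.geometry
    sy, sx = Ht / g.image_height, Wt / g.image_width
    centers = []
    for (x0, y0, x1, y1) in annotation.boxes:
        if x0 < 0 or y0 < 0 or x1 > g.image_width or y1 > g.image_height:
            raise ValueError(f"box {(x0, y0, x1, y1)} outside image bounds")
        centers.append(((y0 + y1) / 2.0 * sy, (x0 + x1) / 2.0 * sx))
    return centers


def render_density_target(centers: list[tuple[float, float]],
                          target_shape: tuple[int, int],
                          kernel: KernelSpec,
                          sigma: float | None = None,
                          scale_factor: float = 1.0) -> DensityTarget:
    """Superpose one unit-mass truncated Gaussian per center.

    `sigma` overrides the kernel's own resolution logic (used by callers that
    already resolved an adaptive sigma from the annotation).
    """
    Ht, Wt = target_shape
    s = float(sigma) if sigma is not None else kernel.resolve_sigma()
    if s < MIN_SIGMA:
        raise ValueError(f"sigma must be >= {MIN_SIGMA}")
    trunc = kernel.resolve_truncation(s)
    R = int(math.ceil(trunc))
    dm = np.zeros((Ht, Wt), dtype=np.float64)
    for (row, col) in centers:
        if not (0 <= row < Ht and 0 <= col < Wt):
            raise ValueError(f"center {(row, col)} outside the target map")
        r0, r1 = max(int(math.floor(row)) - R, 0), min(int(math.ceil(row)) + R + 1, Ht)
        c0, c1 = max(int(math.floor(col)) - R, 0), min(int(math.ceil(col)) + R + 1, Wt)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        d2 = (rr - row) ** 2 + (cc - col) ** 2
        k = np.exp(-d2 / (2.0 * s * s))
        k[d2 > trunc * trunc] = 0.0
        k /= k.sum()                       # per-colony renormalisation
        dm[r0:r1, c0:c1] += k
    return DensityTarget(map=dm, count=float(len(centers)),
                         scale_factor=scale_factor)


def count_from_map(map_: np.ndarray) -> float:
    """Object count read off a density map: the scalar pixel sum."""
    arr = np.asarray(map_, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("density map entries must be non-negative")
    return float(arr.sum())


def loss_view(target: DensityTarget, eps: float = 1e-6) -> np.ndarray:
    """Target map clipped to [eps, 1-eps] for use inside a BCE loss.

    Counting always uses the unclipped map; this view only keeps the cross
    entropy finite.  Overlapping colonies can push target pixels above 1-eps
    (superposed kernel amplitudes add up); such pixels are clipped and a
    warning is logged.
    """
    if not 0.0 < eps < 0.5:
        raise ValueError("eps must be in (0, 0.5)")
    m = target.map
    n_over = int(np.count_nonzero(m > 1.0 - eps))
    if n_over:
        log.warning("loss_view: %d target pixel(s) exceeded 1-eps and were "
                    "clipped (overlapping colonies enlarge map amplitude)", n_over)
    return np.clip(m, eps, 1.0 - eps)
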