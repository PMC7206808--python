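"""Turn a nerve probability map into a final 1-px-wide binary tracing.

The sequence is hysteresis thresholding, topology-preserving thinning, then
removal of small skeleton fragments. Hysteresis suits confocal nerve imaging,
where fibers drift in and out of focus along their length: faint mid-sections
survive as long as they connect to at least one confidently detected stretch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _thin

from .core import BinaryMask, ProbabilityMap, SkeletonMap

__all__ = [
    "PostprocessConfig",
    "hysteresis_threshold",
    "skeletonize",
    "remove_small_components",
    "postprocess",
]

# 8-connectivity structure shared by the hysteresis flood and component labeling
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PostprocessConfig:
    """Thresholds and minimum component size of the post-processing chain.

    Defaults are the operating point used for all images: hysteresis at
    0.125/0.275 and removal of skeleton components under 35 pixels.
    """

    t_low: float = 0.125
    t_high: float = 0.275
    min_component_px: int = 35
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_low < self.t_high <= 1.0):
            raise ValueError(
                f"require 0 <= t_low < t_high <= 1, got ({self.t_low}, {self.t_high})"
            )
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")
        if self.connectivity != 8:
            raise ValueError("only 8-connectivity is supported")


def hysteresis_threshold(
    prob: ProbabilityMap, cfg: PostprocessConfig | None = None
) -> BinaryMask:
    """Two-threshold binarization.

    A pixel is foreground iff its probability is >= ``t_low`` and it is
    8-connected, through pixels >= ``t_low``, to some pixel >= ``t_high``.
    """
    cfg = cfg or PostprocessConfig()
    low = prob.pixels >= cfg.t_low
    high = prob.pixels >= cfg.t_high
    labels, _ = ndimage.label(low, structure=_STRUCT8)
    seeded = np.unique(labels[high])
    seeded = seeded[seeded != 0]
    mask = np.isin(labels, seeded)
    return BinaryMask(mask.astype(np.uint8), prob.calibration)


def skeletonize(mask: BinaryMask) -> SkeletonMap:
    """Topology-preserving thinning to 1-px-wide centerlines (Zhang-Suen class)."""
    skel = _thin(mask.pixels.astype(bool))
    return SkeletonMap(skel.astype(np.uint8), mask.calibration)


def remove_small_components(
    skel: SkeletonMap, cfg: PostprocessConfig | None = None
) -> SkeletonMap:
    """Delete 8-connected components with strictly fewer pixels than the minimum."""
    cfg = cfg or PostprocessConfig()
    labels, n = ndimage.label(skel.pixels, structure=_STRUCT8)
    if n == 0:
        return SkeletonMap(skel.pixels.copy(), skel.calibration)
    counts = np.bincount(labels.ravel())
    keep = counts >= cfg.min_component_px
    keep[0] = False
    return SkeletonMap(keep[labels].astype(np.uint8), skel.calibration)


def postprocess(prob: ProbabilityMap, cfg: PostprocessConfig | None = None) -> SkeletonMap:
    """Full chain: hysteresis threshold, skeletonize, drop small fragments."""
    cfg = cfg or PostprocessConfig()
    return remove_small_components(skeletonize(hysteresis_threshold(prob, cfg)), cfg)
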