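"""Domain types for corneal nerve image analysis.

Conventions used throughout the package:

* rasters are 2-D numpy arrays indexed ``[row, col]`` (row-major, 0-based),
  with pixel centers at integer coordinates;
* polyline vertices are ``(x, y)`` pairs where ``x`` is the column and ``y``
  the row;
* binary rasters use ``uint8`` values in ``{0, 1}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Field of view of the Heidelberg HRTIII Rostock corneal module images this
#: package was designed around: 400 x 400 um sampled over 384 x 384 pixels.
DEFAULT_FOV_UM = 400.0
DEFAULT_SIZE_PX = 384


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration of a square confocal image.

    Parameters
    ----------
    fov_um : float
        Field-of-view edge length in micrometres.
    size_px : int
        Image edge length in pixels.
    """

    fov_um: float = DEFAULT_FOV_UM
    size_px: int = DEFAULT_SIZE_PX

    def __post_init__(self) -> None:
        if not self.fov_um > 0:
            raise ValueError(f"fov_um must be positive, got {self.fov_um}")
        if not self.size_px > 0:
            raise ValueError(f"size_px must be positive, got {self.size_px}")

    @property
    def pixel_size_um(self) -> float:
        """Edge length of one pixel in micrometres (``fov_um / size_px``)."""
        return self.fov_um / self.size_px

    @property
    def area_mm2(self) -> float:
        """Image area in mm^2, the denominator of nerve fiber length density."""
        return (self.fov_um / 1000.0) ** 2


def default_calibration() -> Calibration:
    """The 400 um / 384 px calibration applied when metadata is absent."""
    return Calibration(DEFAULT_FOV_UM, DEFAULT_SIZE_PX)


def _check_raster(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {pixels.shape}")
    if pixels.size == 0:
        raise ValueError("raster is empty")
    return pixels


def _check_binary(pixels: np.ndarray) -> np.ndarray:
    pixels = _check_raster(pixels)
    u = np.unique(pixels)
    if not np.all(np.isin(u, (0, 1))):
        raise ValueError("binary raster must contain only values in {0, 1}")
    return pixels.astype(np.uint8)


@dataclass
class IVCMImage:
    """A grayscale in vivo confocal microscopy image with identity metadata.

    ``subject_id`` is required because cross-validation folds are assigned
    subject-wise: images of one animal must never straddle a train/test split.
    """

    pixels: np.ndarray
    calibration: Calibration
    subject_id: str = "unknown"
    image_id: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = _check_raster(self.pixels).astype(np.float64)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("image intensities must be non-negative")
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class TracingMap:
    """A 1-px-wide binary nerve centerline raster traced by a reader."""

    pixels: np.ndarray
    calibration: Calibration
    reader_id: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = _check_binary(self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ProbabilityMap:
    """Per-pixel nerve probability in [0, 1] output by the segmentation net."""

    pixels: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.pixels = _check_raster(self.pixels).astype(np.float64)
        if np.any(self.pixels < 0) or np.any(self.pixels > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A binary segmentation raster (pre-skeletonization)."""

    pixels: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.pixels = _check_binary(self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SkeletonMap:
    """A 1-px-wide binary nerve centerline raster (thinning-stable)."""

    pixels: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.pixels = _check_binary(self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class NerveAnalysis:
    """Per-image nerve quantification record.

    ``fractal_dimension`` is ``nan`` (undefined) for an empty skeleton rather
    than 0, so that empty images do not drag down population statistics.
    """

    image_id: str
    subject_id: str
    cnfl_mm_per_mm2: float
    fractal_dimension: float
    n_components: int
    total_length_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.cnfl_mm_per_mm2 < 0:
            raise ValueError("CNFL must be non-negative")
        if self.n_components < 0:
            raise ValueError("component count must be non-negative")
        fd = self.fractal_dimension
        if not np.isnan(fd) and not (0.0 <= fd <= 2.0):
            raise ValueError(f"fractal dimension out of [0, 2]: {fd}")
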