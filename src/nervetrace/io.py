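"""Readers and writers for images, nerve tracings and result tables.

Supported tracing interchange formats:

``mask``
    A PNG/TIFF raster; any pixel > 0 is foreground. This is the canonical
    format: ground truth is defined at the pixel level.
``csv_polyline``
    A CSV with columns ``nerve_id, x, y`` listing polyline vertices per nerve
    (``x`` = column, ``y`` = row). Vertices are rasterized to 8-connected
    1-px Bresenham paths.
``neuronj``
    Best-effort parsing of NeuronJ-style ``.ndf`` text exports: blocks of
    alternating x/y coordinate lines separated by non-numeric header lines,
    each block one tracing.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import line as _bresenham_line

from .core import Calibration, IVCMImage, NerveAnalysis, TracingMap

__all__ = [
    "load_image",
    "save_image",
    "load_tracing",
    "save_mask",
    "rasterize_polylines",
    "write_quantification",
    "read_quantification",
]

QUANT_COLUMNS = [
    "image_id",
    "subject_id",
    "cnfl_mm_per_mm2",
    "fractal_dimension",
    "n_components",
    "total_length_mm",
]


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise OSError(f"could not decode image file {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        arr = rgb.mean(axis=-1)
        # equal-channel RGB collapses to the exact grayscale values
        if np.allclose(arr, rgb[..., 0]):
            arr = rgb[..., 0]
    if arr.ndim != 2:
        raise ValueError(
            f"{path} decodes to shape {arr.shape}; multi-frame stacks are not "
            "supported - extract the sub-basal frame first"
        )
    return arr


def load_image(
    path: str | Path,
    calibration: Calibration | None = None,
    subject_id: str = "unknown",
    image_id: str | None = None,
) -> IVCMImage:
    """Load a grayscale confocal image, preserving 8/16-bit values exactly."""
    arr = _read_raster(path)
    if calibration is None:
        calibration = Calibration(size_px=arr.shape[0])
    if image_id is None:
        image_id = Path(path).stem
    return IVCMImage(arr, calibration, subject_id=subject_id, image_id=image_id)


def save_image(path: str | Path, pixels: np.ndarray, bit_depth: int = 16) -> None:
    """Write an intensity raster as 8- or 16-bit PNG/TIFF without rescaling."""
    if bit_depth == 8:
        out = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        out = np.clip(np.rint(pixels), 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), out)


def save_mask(path: str | Path, pixels: np.ndarray) -> None:
    """Write a {0,1} raster as an 8-bit {0,255} PNG/TIFF."""
    iio.imwrite(Path(path), (np.asarray(pixels) > 0).astype(np.uint8) * 255)


def rasterize_polylines(
    polylines: Iterable[Sequence[tuple[float, float]]],
    shape: tuple[int, int],
) -> np.ndarray:
    """Rasterize ``(x, y)`` polylines to an 8-connected 1-px binary raster.

    Each consecutive vertex pair is drawn as a Bresenham line. Vertices
    falling outside ``shape`` raise ``ValueError`` naming the offending index.
    """
    out = np.zeros(shape, dtype=np.uint8)
    h, w = shape
    for nerve_idx, verts in enumerate(polylines):
        verts = list(verts)
        if not verts:
            continue
        pts = []
        for vert_idx, (x, y) in enumerate(verts):
            c, r = int(round(x)), int(round(y))
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(
                    f"polyline {nerve_idx} vertex {vert_idx} ({x}, {y}) lies "
                    f"outside the {h}x{w} image"
                )
            pts.append((r, c))
        if len(pts) == 1:
            out[pts[0]] = 1
            continue
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = _bresenham_line(r0, c0, r1, c1)
            out[rr, cc] = 1
    return out


def _parse_csv_polylines(path: Path) -> list[list[tuple[float, float]]]:
    df = pd.read_csv(path)
    required = {"nerve_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path} must have columns {sorted(required)}")
    return [
        list(zip(grp["x"].astype(float), grp["y"].astype(float)))
        for _, grp in df.groupby("nerve_id", sort=True)
    ]


def _parse_neuronj(path: Path) -> list[list[tuple[float, float]]]:
    """Best-effort NeuronJ text parsing: numeric lines alternate x, y."""
    polylines: list[list[tuple[float, float]]] = []
    coords: list[float] = []

    def flush() -> None:
        if len(coords) >= 2:
            xs, ys = coords[0::2], coords[1::2]
            polylines.append(list(zip(xs, ys)))
        coords.clear()

    for raw in Path(path).read_text().splitlines():
        token = raw.strip()
        try:
            coords.append(float(token))
        except ValueError:
            flush()
    flush()
    return polylines


def load_tracing(
    path: str | Path,
    format: str = "mask",
    calibration: Calibration | None = None,
    reader_id: str = "unknown",
    shape: tuple[int, int] | None = None,
) -> TracingMap:
    """Load a nerve tracing as a binary centerline raster.

    ``shape`` is required for vertex-list formats (``csv_polyline``,
    ``neuronj``) and ignored for ``mask``.
    """
    path = Path(path)
    if format == "mask":
        arr = _read_raster(path)
        pixels = (arr > 0).astype(np.uint8)
    elif format in ("csv_polyline", "neuronj"):
        if shape is None:
            if calibration is not None:
                shape = (calibration.size_px, calibration.size_px)
            else:
                raise ValueError(f"shape is required for format {format!r}")
        parse = _parse_csv_polylines if format == "csv_polyline" else _parse_neuronj
        pixels = rasterize_polylines(parse(path), shape)
    else:
        raise ValueError(f"unknown tracing format {format!r}")
    if calibration is None:
        calibration = Calibration(size_px=pixels.shape[0])
    return TracingMap(pixels, calibration, reader_id=reader_id)


def write_quantification(records: Sequence[NerveAnalysis], path: str | Path) -> None:
    """Write per-image quantification records to CSV (6 decimal places)."""
    if not records:
        raise ValueError("no records to write")
    ids = [r.image_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate image_id(s): {dupes}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(QUANT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.image_id,
                    r.subject_id,
                    f"{r.cnfl_mm_per_mm2:.6f}",
                    f"{r.fractal_dimension:.6f}",
                    r.n_components,
                    f"{r.total_length_mm:.6f}",
                ]
            )


def read_quantification(path: str | Path) -> list[NerveAnalysis]:
    """Read a quantification CSV written by :func:`write_quantification`."""
    df = pd.read_csv(path, dtype={"image_id": str, "subject_id": str})
    return [
        NerveAnalysis(
            image_id=row.image_id,
            subject_id=row.subject_id,
            cnfl_mm_per_mm2=float(row.cnfl_mm_per_mm2),
            fractal_dimension=float(row.fractal_dimension),
            n_components=int(row.n_components),
            total_length_mm=float(row.total_length_mm),
        )
        for row in df.itertuples()
    ]
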