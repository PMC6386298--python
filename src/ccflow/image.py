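"""En-face image containers and grayscale raster I/O.

An en-face image is a frontal 2-D projection from a 3-D OCT/OCTA volume at a
chosen depth slab (here: a choriocapillaris slab, carried as provenance only).
Pixels are normalized to [0, 1] on load; physical geometry travels with the
array so every downstream measurement can be expressed in mm/µm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "ScanGeometry",
    "EnFaceImage",
    "BinaryFlowMap",
    "load_enface",
    "save_enface",
    "load_mask_png",
    "save_mask_png",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of a square en-face scan.

    Parameters
    ----------
    grid_px : int
        Side length in pixels (e.g. 1024).
    field_mm : float
        Physical side length in mm (e.g. 6.0 for a 6 x 6 mm scan).
    fovea_px : tuple of float
        Fovea location as (x, y) in 0-based pixel coordinates. Physical
        coordinates are taken at pixel centers throughout.
    """

    grid_px: int
    field_mm: float
    fovea_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.grid_px <= 0:
            raise ValueError(f"grid_px must be positive, got {self.grid_px}")
        if self.field_mm <= 0:
            raise ValueError(f"field_mm must be positive, got {self.field_mm}")
        if self.fovea_px is not None:
            x, y = self.fovea_px
            if not (0 <= x < self.grid_px and 0 <= y < self.grid_px):
                raise ValueError(f"fovea {self.fovea_px} outside {self.grid_px} px grid")

    @property
    def um_per_px(self) -> float:
        return self.field_mm * 1000.0 / self.grid_px

    @property
    def mm_per_px(self) -> float:
        return self.field_mm / self.grid_px

    @property
    def px_area_mm2(self) -> float:
        return self.mm_per_px**2

    def fovea_mm(self) -> tuple[float, float]:
        """Fovea position in mm, measured at pixel centers."""
        if self.fovea_px is None:
            raise ValueError("fovea position not set on this geometry")
        x, y = self.fovea_px
        return ((x + 0.5) * self.mm_per_px, (y + 0.5) * self.mm_per_px)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "grid_px": self.grid_px,
            "field_mm": self.field_mm,
            "um_per_px": self.um_per_px,
        }
        if self.fovea_px is not None:
            payload["fovea_x_px"], payload["fovea_y_px"] = self.fovea_px
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanGeometry":
        d = json.loads(Path(path).read_text())
        fovea = None
        if "fovea_x_px" in d:
            fovea = (d["fovea_x_px"], d["fovea_y_px"])
        return cls(grid_px=int(d["grid_px"]), field_mm=float(d["field_mm"]), fovea_px=fovea)


@dataclass
class EnFaceImage:
    """One grayscale en-face raster (structure or flow) with its geometry."""

    pixels: np.ndarray
    geometry: ScanGeometry
    modality: str = "flow"  # "structure" or "flow"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"expected a square 2-D array, got shape {px.shape}")
        if px.shape[0] != self.geometry.grid_px:
            raise ValueError(
                f"array side {px.shape[0]} does not match geometry grid_px {self.geometry.grid_px}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("image values must lie in [0, 1]; normalize on load")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryFlowMap:
    """Binarized angiogram: True marks a flow void (signal below local threshold)."""

    voids: np.ndarray
    geometry: ScanGeometry
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.voids, dtype=bool)
        if v.ndim != 2 or v.shape[0] != self.geometry.grid_px:
            raise ValueError("void map shape does not match geometry")
        self.voids = v

    def void_fraction(self, region: np.ndarray | None = None) -> float:
        if region is None:
            return float(self.voids.mean())
        region = np.asarray(region, dtype=bool)
        n = int(region.sum())
        if n == 0:
            raise ValueError("empty region")
        return float(self.voids[region].sum() / n)


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Normalize integer rasters by their nominal bit-depth maximum."""
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    arr = arr.astype(float)
    if arr.size and arr.max() > 1.0:  # unnormalized float export
        arr = arr / arr.max()
    return np.clip(arr, 0.0, 1.0)


def load_enface(path: str | Path, geometry: ScanGeometry, modality: str = "flow") -> EnFaceImage:
    """Read a grayscale TIFF/PNG and normalize to [0, 1] by nominal bit depth."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:  # collapse any accidental RGB export
        arr = arr[..., 0]
    return EnFaceImage(pixels=_normalize(arr), geometry=geometry, modality=modality)


def save_enface(image: EnFaceImage, path: str | Path) -> None:
    """Write as 16-bit grayscale (TIFF) or 8-bit (PNG) by extension."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, np.round(image.pixels * 65535).astype(np.uint16))
    else:
        iio.imwrite(path, np.round(image.pixels * 255).astype(np.uint8))


def load_mask_png(path: str | Path) -> np.ndarray:
    """Binary lesion mask from PNG: any nonzero pixel is lesion."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def save_void_map_png(fmap: BinaryFlowMap, path: str | Path) -> None:
    """Void map as PNG: voids black (0), signal white (255)."""
    iio.imwrite(Path(path), np.where(fmap.voids, 0, 255).astype(np.uint8))
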