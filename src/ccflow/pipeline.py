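"""Shadow compensation and local-threshold binarization of CC angiograms.

The choriocapillaris sits beneath the RPE, so drusen and other RPE/BM changes
attenuate both the structural OCT signal and the OCTA decorrelation signal in
the same columns. Compensation multiplies the flow image by the smoothed,
inverted structural image: columns that are dark structurally (shadowed) get
boosted, normally-lit columns are left (up to a global gain) unchanged. The
compensated angiogram is then binarized with the Phansalkar local threshold,
an adaptive method designed for low-contrast images; pixels below the local
threshold are flow voids.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .image import BinaryFlowMap, EnFaceImage

__all__ = [
    "CompensationParams",
    "BinarizationParams",
    "compensate",
    "phansalkar_binarize",
    "phansalkar_threshold",
]


@dataclass(frozen=True)
class CompensationParams:
    """Parameters of the inverse-structure compensation.

    smooth_kernel_px : odd side length of the truncated Gaussian used to
        suppress speckle in the inverted structural image (default 3).
    sigma_px : Gaussian sigma before truncation; 0.85 px gives the common
        3x3 Gaussian approximation once renormalized.
    rescale : min-max rescale the product back to [0, 1] (default True),
        which makes the subsequent binarization invariant to the global
        gain the multiplication introduces.
    """

    smooth_kernel_px: int = 3
    sigma_px: float = 0.85
    rescale: bool = True

    def __post_init__(self) -> None:
        if self.smooth_kernel_px < 1 or self.smooth_kernel_px % 2 == 0:
            raise ValueError("smooth_kernel_px must be odd and >= 1")
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")


@dataclass(frozen=True)
class BinarizationParams:
    """Phansalkar threshold t = m * (1 + p*exp(-q*m) + k*(s/r_norm - 1)).

    m and s are the mean and standard deviation over a circular window of
    radius `radius_px` centered on each pixel. Defaults are the original
    Phansalkar constants (also the ImageJ Auto Local Threshold defaults);
    only the radius is image-protocol specific (15 px on a 1024 px / 6 mm
    grid, i.e. a ~88 µm neighborhood).
    """

    radius_px: int = 15
    k: float = 0.25
    r_norm: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        for name in ("k", "r_norm", "p", "q"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Truncated, renormalized 2-D Gaussian kernel of odd side `size`."""
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def compensate(
    flow: EnFaceImage,
    structure: EnFaceImage,
    params: CompensationParams | None = None,
) -> EnFaceImage:
    """Multiply the flow image by the smoothed, inverted structural image.

    Returns ``flow * G(1 - structure)`` where G is the configured truncated
    Gaussian blur, optionally min-max rescaled to [0, 1]. For two pixels with
    equal flow value, the one under lower smoothed structural signal maps to
    a higher compensated value, which is the point: shadowed columns are
    boosted relative to well-lit ones.
    """
    params = params or CompensationParams()
    if flow.shape != structure.shape:
        raise ValueError(f"flow shape {flow.shape} != structure shape {structure.shape}")
    if flow.geometry.grid_px != structure.geometry.grid_px or not np.isclose(
        flow.geometry.field_mm, structure.geometry.field_mm
    ):
        raise ValueError("flow and structure geometries disagree")

    kernel = _gaussian_kernel(params.smooth_kernel_px, params.sigma_px)
    inverted = 1.0 - structure.pixels
    smoothed = ndimage.correlate(inverted, kernel, mode="reflect")
    comp = flow.pixels * smoothed

    if params.rescale:
        lo, hi = comp.min(), comp.max()
        if hi - lo <= 0:
            # Degenerate: constant product (e.g. constant structure AND
            # constant flow). Min-max is undefined; pass the flow through.
            return EnFaceImage(flow.pixels.copy(), flow.geometry, modality="flow")
        comp = (comp - lo) / (hi - lo)
    else:
        comp = np.clip(comp, 0.0, 1.0)
    return EnFaceImage(comp, flow.geometry, modality="flow")


def circular_footprint(radius: int) -> np.ndarray:
    """Boolean disc of pixel offsets with dx^2 + dy^2 <= radius^2."""
    ax = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(ax, ax, indexing="ij")
    return (dx**2 + dy**2) <= radius**2


def phansalkar_threshold(image: np.ndarray, params: BinarizationParams) -> np.ndarray:
    """Per-pixel Phansalkar threshold over a circular window, reflective padding."""
    img = np.asarray(image, dtype=float)
    fp = circular_footprint(params.radius_px).astype(float)
    n = fp.sum()
    # Windowed mean and population SD from running sums; 'reflect' in
    # scipy.ndimage repeats the edge sample (symmetric padding).
    s1 = ndimage.correlate(img, fp, mode="reflect")
    s2 = ndimage.correlate(img * img, fp, mode="reflect")
    m = s1 / n
    var = np.maximum(s2 / n - m * m, 0.0)
    s = np.sqrt(var)
    return m * (1.0 + params.p * np.exp(-params.q * m) + params.k * (s / params.r_norm - 1.0))


def phansalkar_binarize(
    image: EnFaceImage, params: BinarizationParams | None = None
) -> BinaryFlowMap:
    """Binarize an en-face angiogram; True = flow void (value below threshold)."""
    params = params or BinarizationParams()
    side = image.shape[0]
    if params.radius_px > side // 2:
        raise ValueError(f"radius {params.radius_px} px exceeds half the image side ({side} px)")
    t = phansalkar_threshold(image.pixels, params)
    voids = image.pixels < t
    return BinaryFlowMap(voids, image.geometry, provenance=asdict(params))
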