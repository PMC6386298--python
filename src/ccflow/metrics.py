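"""Per-eye flow-void metrics and the square-root-transformed growth rate.

Flow-void percentages (FV) are the fraction of binarized-void pixels inside
a region, in percent: FV_OUT over all non-lesion pixels, FV_500 in the
para-atrophy ring (0-500 µm from the lesion edge) and FV_1000 in the
peri-atrophy ring (500-1000 µm). Their difference dFV = FV_500 - FV_1000
is the local excess of flow impairment immediately at the lesion edge over
the adjacent background, which makes it robust to the eye-wide level and to
the physiologic eccentricity gradient of void density.

The yearly growth rate uses the square-root transform of lesion areas,
yGR = (sqrt(A2) - sqrt(A1)) / FU in mm/yr, which removes the dependence of
raw area growth on baseline lesion size (a circle growing at constant edge
speed v has yGR = sqrt(pi) * v regardless of its radius).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    LesionMask,
    RegionSet,
    build_regions,
    fovea_distance,
    lesion_area,
    touches_border,
)
from .image import BinaryFlowMap, EnFaceImage
from .pipeline import BinarizationParams, CompensationParams, compensate, phansalkar_binarize

__all__ = ["EyeRecord", "fv_percentage", "compute_ygr", "analyze_eye"]


@dataclass
class EyeRecord:
    """One eye's measurements; the row format of results.csv."""

    eye_id: str
    patient_id: str  # GEE cluster
    area_baseline_mm2: float
    area_followup_mm2: float
    fu_years: float
    ygr: float
    fv_out: float
    fv_500: float
    fv_1000: float
    dfv: float
    fv_out_beyond: float  # FV_OUT variant excluding both rings
    fovea_dist_mm: float
    age: float = math.nan
    excluded_border: bool = False
    negative_growth: bool = False
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "eye_id": self.eye_id,
            "patient_id": self.patient_id,
            "area_baseline_mm2": self.area_baseline_mm2,
            "area_followup_mm2": self.area_followup_mm2,
            "fu_years": self.fu_years,
            "ygr": self.ygr,
            "fv_out": self.fv_out,
            "fv_500": self.fv_500,
            "fv_1000": self.fv_1000,
            "dfv": self.dfv,
            "fv_out_beyond": self.fv_out_beyond,
            "fovea_dist_mm": self.fovea_dist_mm,
            "age": self.age,
            "excluded_border": self.excluded_border,
            "negative_growth": self.negative_growth,
        }
        d.update(self.extras)
        return d


def fv_percentage(voids: BinaryFlowMap, region: np.ndarray, name: str = "region") -> float:
    """Percentage of void pixels inside a region mask."""
    region = np.asarray(region, dtype=bool)
    if region.shape != voids.voids.shape:
        raise ValueError(f"{name} mask shape {region.shape} != void map {voids.voids.shape}")
    n = int(region.sum())
    if n == 0:
        raise ValueError(f"region '{name}' is empty")
    return 100.0 * float(voids.voids[region].sum()) / n


def compute_ygr(area_baseline_mm2: float, area_followup_mm2: float, fu_years: float) -> float:
    """Square-root-transformed yearly growth rate, mm/yr.

    Negative values (shrinking lesions) are returned as-is; truncation would
    bias cohort means and is left to the caller to flag.
    """
    if fu_years <= 0:
        raise ValueError(f"follow-up must be positive, got {fu_years}")
    if area_baseline_mm2 < 0 or area_followup_mm2 < 0:
        raise ValueError("areas must be non-negative")
    return (math.sqrt(area_followup_mm2) - math.sqrt(area_baseline_mm2)) / fu_years


def analyze_eye(
    flow: EnFaceImage,
    structure: EnFaceImage,
    mask_t0: LesionMask,
    mask_t1: LesionMask,
    *,
    eye_id: str,
    patient_id: str,
    fu_years: float,
    age: float = math.nan,
    comp_params: CompensationParams | None = None,
    bin_params: BinarizationParams | None = None,
    ring_widths_um: tuple[float, float] = (500.0, 500.0),
) -> EyeRecord:
    """Run the full per-eye pipeline on the baseline OCTA.

    compensate -> binarize -> distance-map rings on the baseline mask ->
    the three FV percentages and dFV; lesion areas and yGR from the two
    masks; border exclusion from either visit. FV metrics are baseline
    quantities (the OCTA is a first-visit acquisition).
    """
    try:
        comp = compensate(flow, structure, comp_params)
        voids = phansalkar_binarize(comp, bin_params)
        regions = build_regions(mask_t0, ring_widths_um)
        fv_out = fv_percentage(voids, regions.outside, "outside")
        fv_500 = fv_percentage(voids, regions.para, "para")
        fv_1000 = fv_percentage(voids, regions.peri, "peri")
        beyond = regions.beyond
        fv_beyond = fv_percentage(voids, beyond, "beyond") if beyond.any() else math.nan
        a0 = lesion_area(mask_t0)
        a1 = lesion_area(mask_t1)
        ygr = compute_ygr(a0, a1, fu_years)
        fd = fovea_distance(mask_t0)
    except Exception as exc:
        raise RuntimeError(f"eye {eye_id}: {exc}") from exc

    return EyeRecord(
        eye_id=eye_id,
        patient_id=patient_id,
        area_baseline_mm2=a0,
        area_followup_mm2=a1,
        fu_years=fu_years,
        ygr=ygr,
        fv_out=fv_out,
        fv_500=fv_500,
        fv_1000=fv_1000,
        dfv=fv_500 - fv_1000,
        fv_out_beyond=fv_beyond,
        fovea_dist_mm=fd,
        age=age,
        excluded_border=touches_border(mask_t0, mask_t1),
        negative_growth=ygr < 0,
    )
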