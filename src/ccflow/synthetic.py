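"""Synthetic en-face OCTA cohorts with known ground truth.

Each synthetic eye mimics the statistical structure the analysis assumes:

* a granular choriocapillaris flow texture (band-pass-filtered white noise)
  in which a spatial *void-probability field* suppresses signal — its base
  level is ~42% void, voids become slightly less frequent away from the
  fovea (the physiologic eccentricity gradient of ~0.8% per 500 µm), and a
  per-eye *ring excess* adds extra voids in the 0-500 µm band around the GA
  lesion, tapering linearly to zero at 1000 µm;
* a structural channel that is uniform except under randomly placed drusen,
  whose multiplicative shadow darkens both channels in the same columns
  (what the compensation step is there to undo);
* focal or multifocal elliptical GA lesions whose border advances
  isotropically at a per-eye edge speed coupled to the ring excess, so that
  the growth-rate / flow-void association the pipeline is meant to detect
  is injected by construction;
* a cohort table with 1-2 eyes per patient for cluster-aware statistics.

Everything is deterministic given the config seed: each eye draws from its
own RNG stream spawned from (seed, eye index).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .geometry import LesionMask, build_regions, dilate_mask, lesion_area, touches_border
from .image import EnFaceImage, ScanGeometry, save_enface, save_mask_png

__all__ = ["SyntheticConfig", "EyeBundle", "generate_cohort", "grow_mask", "simulate_eye_records"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    The defaults emulate a dry-AMD GA cohort on 6 x 6 mm scans: ~42% base
    void fraction, a -0.8%-per-500-µm eccentricity gradient, follow-up of
    1.31 ± 0.2 years (floored at the 12-month eligibility minimum), and a
    para-ring void excess drawn per eye from U[0, 0.10] whose coupling to
    the lesion edge speed carries the signal of interest.
    """

    n_patients: int = 20
    eyes_per_patient: int = 2  # 1 or 2
    grid_px: int = 1024
    field_mm: float = 6.0
    seed: int = 0
    base_void_frac: float = 0.42
    eccentricity_gradient: float = -0.008  # void-fraction change per 500 µm from fovea
    ring_excess_range: tuple[float, float] = (0.0, 0.10)
    growth_coupling: float = 4.0  # mm/yr of edge speed per unit ring excess
    base_edge_speed: float = 0.02  # mm/yr
    edge_speed_sd: float = 0.03  # mm/yr, eye-level noise on the edge speed
    drusen_density: float = 1.0  # discs per mm^2
    drusen_radius_um: float = 60.0
    drusen_radius_sd_um: float = 15.0
    drusen_shadow_depth: float = 0.30  # fractional darkening under a druse
    followup_years_mean: float = 1.31
    followup_years_sd: float = 0.2
    speckle_grain_um: float = 30.0  # CC lobule-scale texture grain
    void_level: float = 0.15  # flow intensity inside a void
    signal_level: float = 0.70  # flow intensity where CC flow is present
    texture_noise_sd: float = 0.04
    structure_base: float = 0.5  # structural level away from drusen
    lesion_void_frac: float = 0.90  # CC under the atrophy is largely flow-void
    area_log_mean: float = math.log(0.8)  # lognormal baseline GA area, mm^2
    area_log_sd: float = 1.0
    multifocal_probs: tuple[float, ...] = (0.7, 0.2, 0.1)  # P(1, 2, 3 foci)
    lesion_offset_mm_sd: float = 0.55  # lesion-center scatter around the fovea
    mean_age: float = 84.67
    sd_age: float = 6.42

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.eyes_per_patient not in (1, 2):
            raise ValueError("eyes_per_patient must be 1 or 2")
        if self.grid_px <= 0 or self.field_mm <= 0:
            raise ValueError("grid_px and field_mm must be positive")
        for name in ("base_void_frac", "drusen_shadow_depth", "void_level",
                     "signal_level", "structure_base", "lesion_void_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        lo, hi = self.ring_excess_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("ring_excess_range must be ordered and within [0, 1]")
        if self.followup_years_mean < 1.0:
            raise ValueError("mean follow-up must be >= 1 year (eligibility floor)")

    @property
    def n_eyes(self) -> int:
        return self.n_patients * self.eyes_per_patient

    @property
    def um_per_px(self) -> float:
        return self.field_mm * 1000.0 / self.grid_px


@dataclass
class EyeBundle:
    """One synthetic eye: image pair, masks at both visits, covariates, truth."""

    eye_id: str
    patient_id: str
    flow: EnFaceImage
    structure: EnFaceImage
    mask_t0: LesionMask
    mask_t1: LesionMask
    fu_years: float
    age: float
    truth: dict = field(default_factory=dict)


def grow_mask(mask: LesionMask, speed_mm_per_yr: float, years: float) -> LesionMask:
    """Advance the lesion border isotropically by speed x years (mm).

    Every background pixel within that distance of the lesion becomes
    lesion; a circular lesion of radius r maps to radius r + speed*years,
    so circles of any size share yGR = sqrt(pi) * speed.
    """
    if speed_mm_per_yr < 0:
        raise ValueError("edge speed must be non-negative")
    return dilate_mask(mask, speed_mm_per_yr * years)


def _rasterize_ellipse(shape, center_px, a_px, b_px, theta):
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    dy = rows - center_px[1]
    dx = cols - center_px[0]
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def _make_lesion(cfg: SyntheticConfig, geom: ScanGeometry, rng: np.random.Generator) -> np.ndarray:
    """Focal or multifocal elliptical baseline lesion near the fovea."""
    px_mm = geom.mm_per_px
    total_area = float(np.clip(rng.lognormal(cfg.area_log_mean, cfg.area_log_sd), 0.1, 8.0))
    n_foci = int(rng.choice(np.arange(1, len(cfg.multifocal_probs) + 1), p=cfg.multifocal_probs))
    weights = rng.dirichlet(np.full(n_foci, 2.0))
    fx, fy = geom.fovea_px
    mask = np.zeros((geom.grid_px, geom.grid_px), dtype=bool)
    margin_mm = 0.8  # leave room for follow-up growth before the scan edge
    prev = None
    for area, _ in zip(total_area * weights, range(n_foci)):
        q = rng.uniform(0.55, 1.0)  # axis ratio
        a_mm = math.sqrt(area / (math.pi * q))
        b_mm = q * a_mm
        theta = rng.uniform(0.0, math.pi)
        if prev is None:
            off = rng.normal(0.0, cfg.lesion_offset_mm_sd, size=2)
        else:
            off = prev + rng.normal(0.0, 0.7, size=2)
        cx = fx + off[0] / px_mm
        cy = fy + off[1] / px_mm
        lim = (max(a_mm, b_mm) + margin_mm) / px_mm
        cx = float(np.clip(cx, lim, geom.grid_px - 1 - lim))
        cy = float(np.clip(cy, lim, geom.grid_px - 1 - lim))
        prev = np.array([(cx - fx) * px_mm, (cy - fy) * px_mm])
        mask |= _rasterize_ellipse(mask.shape, (cx, cy), a_mm / px_mm, b_mm / px_mm, theta)
    if not mask.any():  # degenerate rasterization of a tiny focus
        mask[int(fy), int(fx)] = True
    return mask


def _texture_uniform(cfg: SyntheticConfig, geom: ScanGeometry, rng: np.random.Generator) -> np.ndarray:
    """Granular [0,1]-uniform field: DoG-filtered white noise through its CDF."""
    grain_px = cfg.speckle_grain_um / geom.um_per_px
    sigma = max(grain_px / 2.355, 0.45)
    white = rng.standard_normal((geom.grid_px, geom.grid_px))
    g = ndimage.gaussian_filter(white, sigma) - ndimage.gaussian_filter(white, 1.6 * sigma)
    g /= g.std()
    return special.ndtr(g)  # standard normal CDF -> approx U(0,1)


def _void_probability_field(
    cfg: SyntheticConfig,
    geom: ScanGeometry,
    mask_t0: np.ndarray,
    ring_excess: float,
) -> np.ndarray:
    """Spatial void probability: base + eccentricity gradient + ring excess.

    The excess is at full strength within 500 µm of the lesion edge and
    tapers linearly to zero between 500 and 1000 µm.
    """
    n = geom.grid_px
    mm = geom.mm_per_px
    fx_mm, fy_mm = geom.fovea_mm()
    xv = (np.arange(n) + 0.5) * mm
    dxx, dyy = np.meshgrid(xv - fx_mm, xv - fy_mm)
    d_fovea_um = np.hypot(dxx, dyy) * 1000.0

    d_lesion_um = ndimage.distance_transform_edt(~mask_t0, sampling=geom.um_per_px)
    taper = np.where(
        d_lesion_um <= 500.0, 1.0, np.clip((1000.0 - d_lesion_um) / 500.0, 0.0, 1.0)
    )
    p = (
        cfg.base_void_frac
        + cfg.eccentricity_gradient * (d_fovea_um / 500.0)
        + ring_excess * taper
    )
    p = np.where(mask_t0, cfg.lesion_void_frac, p)
    return np.clip(p, 0.01, 0.99)


def _drusen_shadow(cfg: SyntheticConfig, geom: ScanGeometry, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative shadow map: 1 away from drusen, 1-depth under them."""
    n = geom.grid_px
    n_drusen = rng.poisson(cfg.drusen_density * cfg.field_mm**2)
    disc = np.zeros((n, n), dtype=float)
    if n_drusen:
        centers = rng.uniform(0, n, size=(n_drusen, 2))
        radii_um = np.clip(
            rng.normal(cfg.drusen_radius_um, cfg.drusen_radius_sd_um, size=n_drusen), 25.0, 150.0
        )
        rows, cols = np.ogrid[:n, :n]
        for (cx, cy), r_um in zip(centers, radii_um):
            r_px = r_um / geom.um_per_px
            disc[(rows - cy) ** 2 + (cols - cx) ** 2 <= r_px**2] = 1.0
        feather_px = max(10.0 / geom.um_per_px, 0.8)
        disc = np.clip(ndimage.gaussian_filter(disc, feather_px), 0.0, 1.0)
    return 1.0 - cfg.drusen_shadow_depth * disc


def _generate_eye(
    cfg: SyntheticConfig, eye_id: str, patient_id: str, age: float, rng: np.random.Generator
) -> EyeBundle:
    n = cfg.grid_px
    jitter = rng.uniform(-0.05, 0.05, size=2) * n  # fovea near scan center
    geom = ScanGeometry(
        grid_px=n,
        field_mm=cfg.field_mm,
        fovea_px=(n / 2 - 0.5 + jitter[0], n / 2 - 0.5 + jitter[1]),
    )

    mask_t0 = _make_lesion(cfg, geom, rng)
    lo, hi = cfg.ring_excess_range
    ring_excess = float(rng.uniform(lo, hi))
    speed = max(
        0.0,
        cfg.base_edge_speed + cfg.growth_coupling * ring_excess + rng.normal(0.0, cfg.edge_speed_sd),
    )
    fu_years = max(1.0, rng.normal(cfg.followup_years_mean, cfg.followup_years_sd))

    lesion0 = LesionMask(mask_t0, geom)
    lesion1 = grow_mask(lesion0, speed, fu_years)

    p_field = _void_probability_field(cfg, geom, mask_t0, ring_excess)
    u = _texture_uniform(cfg, geom, rng)
    void = u < p_field
    flow_clean = np.where(void, cfg.void_level, cfg.signal_level) + rng.normal(
        0.0, cfg.texture_noise_sd, size=(n, n)
    )
    shadow = _drusen_shadow(cfg, geom, rng)
    flow_px = np.clip(flow_clean * shadow, 0.0, 1.0)
    struct_px = np.clip(
        cfg.structure_base * shadow + rng.normal(0.0, 0.01, size=(n, n)), 0.0, 1.0
    )

    regions = build_regions(lesion0)
    truth = {
        "eye_id": eye_id,
        "patient_id": patient_id,
        "true_void_frac_out": float(p_field[regions.outside].mean()),
        "true_void_frac_para": float(p_field[regions.para].mean()),
        "true_void_frac_peri": float(p_field[regions.peri].mean()),
        "true_ring_excess": ring_excess,
        "true_edge_speed": speed,
        "baseline_area": lesion_area(lesion0),
        "followup_area": lesion_area(lesion1),
        "fu_years": fu_years,
        "age": age,
        "focus_centroids": ";".join(
            f"{cx:.4f},{cy:.4f}" for cx, cy in (f["centroid_mm"] for f in lesion0.foci())
        ),
        "border_truncated": touches_border(lesion0, lesion1),
    }
    return EyeBundle(
        eye_id=eye_id,
        patient_id=patient_id,
        flow=EnFaceImage(flow_px, geom, "flow"),
        structure=EnFaceImage(struct_px, geom, "structure"),
        mask_t0=lesion0,
        mask_t1=lesion1,
        fu_years=fu_years,
        age=age,
        truth=truth,
    )


def generate_cohort(
    config: SyntheticConfig, outdir: str | Path | None = None
) -> tuple[list[EyeBundle], pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns (eye bundles, truth table, cohort table). If `outdir` is given,
    the per-eye images (16-bit TIFF), masks (PNG), `cohort.csv`,
    `truth.csv` and a geometry sidecar JSON are written there.
    """
    root = np.random.SeedSequence(config.seed)
    eye_seeds = root.spawn(config.n_eyes + 1)
    meta_rng = np.random.default_rng(eye_seeds[-1])
    ages = meta_rng.normal(config.mean_age, config.sd_age, size=config.n_patients)

    bundles: list[EyeBundle] = []
    eye_idx = 0
    for p in range(config.n_patients):
        patient_id = f"P{p:03d}"
        for e in range(config.eyes_per_patient):
            eye_id = f"{patient_id}_E{e}"
            rng = np.random.default_rng(eye_seeds[eye_idx])
            bundles.append(_generate_eye(config, eye_id, patient_id, float(ages[p]), rng))
            eye_idx += 1

    truth_df = pd.DataFrame([b.truth for b in bundles])
    cohort_df = pd.DataFrame(
        [
            {
                "eye_id": b.eye_id,
                "patient_id": b.patient_id,
                "fu_years": b.fu_years,
                "fovea_x_px": b.flow.geometry.fovea_px[0],
                "fovea_y_px": b.flow.geometry.fovea_px[1],
                "age": b.age,
            }
            for b in bundles
        ]
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for b in bundles:
            save_enface(b.structure, outdir / f"{b.eye_id}_struct.tif")
            save_enface(b.flow, outdir / f"{b.eye_id}_flow.tif")
            save_mask_png(b.mask_t0.pixels, outdir / f"{b.eye_id}_mask_t0.png")
            save_mask_png(b.mask_t1.pixels, outdir / f"{b.eye_id}_mask_t1.png")
            b.flow.geometry.to_json(outdir / f"{b.eye_id}_geometry.json")
        cohort_df.to_csv(outdir / "cohort.csv", index=False)
        truth_df.to_csv(outdir / "truth.csv", index=False)
        cfg_dict = asdict(config)
        pd.Series(cfg_dict).to_json(outdir / "config.json")
    return bundles, truth_df, cohort_df


def simulate_eye_records(
    config: SyntheticConfig,
    rng: np.random.Generator,
    *,
    dfv_noise_pp: float = 1.2,
    fv_noise_pp: float = 0.8,
    patient_speed_sd: float = 0.03,
) -> pd.DataFrame:
    """Record-level cohort draw (no images) with the pipeline's error structure.

    Emulates the sampling distribution of the measured per-eye quantities:
    the true para-ring excess contributes its full value to FV_500 and, via
    the linear taper, half its value to FV_1000, so the expected measured
    dFV is 50 * excess percentage points; measurement noise reflects the
    binarization sampling spread over ring-sized areas. Edge speeds carry a
    shared within-patient component so eyes cluster. Useful where many
    cohorts are needed (e.g. type-I-error studies of the GEE screen) and
    rendering images for each would be pointless.
    """
    lo, hi = config.ring_excess_range
    rows = []
    for p in range(config.n_patients):
        patient_id = f"P{p:03d}"
        age = rng.normal(config.mean_age, config.sd_age)
        pat_eff = rng.normal(0.0, patient_speed_sd)
        for e in range(config.eyes_per_patient):
            excess = rng.uniform(lo, hi)
            speed = max(
                0.0,
                config.base_edge_speed
                + config.growth_coupling * excess
                + pat_eff
                + rng.normal(0.0, config.edge_speed_sd),
            )
            fu = max(1.0, rng.normal(config.followup_years_mean, config.followup_years_sd))
            ygr = math.sqrt(math.pi) * speed + rng.normal(0.0, 0.01)
            base_pp = 100.0 * config.base_void_frac
            fv_out = base_pp + rng.normal(0.0, fv_noise_pp)
            fv_1000 = base_pp + 50.0 * excess + rng.normal(0.0, fv_noise_pp)
            dfv = 50.0 * excess + rng.normal(0.0, dfv_noise_pp)
            rows.append(
                {
                    "eye_id": f"{patient_id}_E{e}",
                    "patient_id": patient_id,
                    "age": age,
                    "fu_years": fu,
                    "ygr": ygr,
                    "fv_out": fv_out,
                    "fv_1000": fv_1000,
                    "fv_500": fv_1000 + dfv,
                    "dfv": dfv,
                    "area_baseline_mm2": float(
                        np.clip(rng.lognormal(config.area_log_mean, config.area_log_sd), 0.1, 8.0)
                    ),
                    "fovea_dist_mm": abs(rng.normal(0.86, 0.54)),
                }
            )
    return pd.DataFrame(rows)
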