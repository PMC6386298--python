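import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ccflow import LesionMask, ScanGeometry  # noqa: E402


def circle_mask(geometry: ScanGeometry, radius_mm: float, center_px=None) -> LesionMask:
    """Rasterized disc: pixel centers within radius of the given center."""
    n = geometry.grid_px
    if center_px is None:
        center_px = (n / 2 - 0.5, n / 2 - 0.5)
    cx, cy = center_px
    yy, xx = np.mgrid[:n, :n]
    r_px = radius_mm / geometry.mm_per_px
    return LesionMask((xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2, geometry)


@pytest.fixture
def geom1024():
    return ScanGeometry(1024, 6.0, fovea_px=(511.5, 511.5))


@pytest.fixture
def geom256():
    return ScanGeometry(256, 6.0, fovea_px=(127.5, 127.5))


@pytest.fixture(scope="session")
def effect_cohort():
    """40-eye synthetic cohort with the coupled growth signal, analyzed once.

    512 px grid with the Phansalkar radius scaled to keep the physical
    window near the 1024-px protocol's ~88 µm.
    """
    from ccflow import BinarizationParams, SyntheticConfig, generate_cohort
    from ccflow.run import analyze_bundles, run_stats

    cfg = SyntheticConfig(n_patients=20, eyes_per_patient=2, grid_px=512, seed=1)
    bundles, truth, cohort = generate_cohort(cfg)
    results = analyze_bundles(bundles, bin_params=BinarizationParams(radius_px=8))
    report = run_stats(results)
    return {"config": cfg, "bundles": bundles, "truth": truth, "results": results, "report": report}
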