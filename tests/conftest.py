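"""Shared fixtures: configs, calibration, and small rendered scenes.

All fixtures are generated programmatically; nothing is read from disk.
"""

import numpy as np
import pytest

from hevscape import AnalysisConfig, Calibration
from hevscape.synthcohort import LNLayout, VesselSpec


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def calib() -> Calibration:
    return Calibration(um_per_px=0.5)


def make_layout(field_px: int = 600, um_per_px: float = 0.5,
                **kw) -> LNLayout:
    """Small tissue disc layout for single-vessel scenes (no mesh by default)."""
    defaults = dict(
        field_px=field_px, um_per_px=um_per_px,
        tissue_radius_um=0.47 * field_px * um_per_px,
        mesh_spacing_um=10_000.0,  # effectively no mesh
    )
    defaults.update(kw)
    return LNLayout(**defaults)


def make_spec(a: float = 14.0, b: float = 8.0, t: float = 5.0,
              center=(150.0, 150.0), theta: float = 0.0,
              pnad: float = 1.0, ccl21: float = 1.0, asma: float = 1.0,
              hs: float = 1.0, **kw) -> VesselSpec:
    """One open-lumen vessel spec with explicit geometry (µm)."""
    from hevscape.periscore import categorize

    cfg_ = AnalysisConfig()
    cov = {"CCL21": ccl21, "ASMA": asma, "HS": hs}
    cats = {m: categorize(c, cfg_) for m, c in cov.items()}
    defaults = dict(
        lumen_axes=(a, b), wall_thickness=t, pnad_coverage=pnad,
        ring_coverage=cov, ring_category=cats,
        dilation_class="NON" if b == 0 else ("HIGH" if 2 * b >= 10 else "INT"),
        thin=t < 3.0, pnad_discontinuous=pnad < 0.9,
        center=center, theta=theta,
    )
    defaults.update(kw)
    return VesselSpec(**defaults)


@pytest.fixture
def single_vessel_scene(calib):
    """Noise-free image with one annular vessel, full marker coverage."""
    from hevscape.synthcohort import render_ln_image

    spec = make_spec()
    layout = make_layout()
    image, masks, truth = render_ln_image(
        [spec], layout, calib=calib, noise_sd=0.0,
        rng=np.random.default_rng(0))
    return spec, layout, image, masks, truth
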