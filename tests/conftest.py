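"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import zoom

import canalregen as cr


@pytest.fixture
def params() -> cr.ScoringParams:
    return cr.ScoringParams()


# ---------------------------------------------------------------------------
# independent angular-histogram oracle (voxel classification, no ray casting)


def angular_histogram_oracle(
    cs: cr.CrossSection,
    hu_thresh: float,
    p: cr.ScoringParams,
    bin_deg: float = 1.0,
    upsample: int = 4,
) -> float:
    """Enclosure angle by polar-binning supra-threshold pixels.

    Upsamples the section grid (linear), classifies every pixel centre inside
    the wall-search annulus whose value is in the bone range, bins the polar
    angles at ``bin_deg`` resolution and counts occupied bins. Completely
    independent of the ray-casting implementation.
    """
    g = zoom(cs.grid, upsample, order=1)
    pitch = cs.in_plane_spacing * (cs.grid.shape[0] - 1) / (g.shape[0] - 1)
    m = g.shape[0]
    offs = (np.arange(m) - (m - 1) / 2.0) * pitch
    X, Y = np.meshgrid(offs, offs, indexing="ij")
    r = np.hypot(X, Y)
    th = np.degrees(np.arctan2(Y, X))
    mask = (
        (r >= p.band_inner_mm)
        & (r <= p.band_outer_mm)
        & (g > hu_thresh)
        & (g < p.hu_bone_upper)
    )
    bins = np.unique(np.floor((th[mask] + 180.0) / bin_deg))
    return float(len(bins) * bin_deg)


# ---------------------------------------------------------------------------
# fine-resolution single-arc phantoms for enclosure-fidelity checks


ARC_PARAMS = cr.ScoringParams(band_inner_mm=2.4, band_outer_mm=6.0)


def arc_section(arc_deg: float) -> cr.CrossSection:
    """Mid-axis cross-section of a noiseless phantom with one analytic arc.

    Uses 0.15 mm voxels, a 3 mm lumen and a 1.5 mm wall at 1200 HU over a
    400 HU background so the 800 HU threshold crossing falls midway between
    wall and background (no systematic edge bias).
    """
    nz = 24
    spec = cr.PhantomSpec(
        shape=(128, 128, nz),
        spacing=(0.15, 0.15, 0.15),
        canal_radius=3.0,
        wall_thickness=1.5,
        background_hu=400.0,
        lumen_hu=40.0,
        stations=[cr.Station(0.0, (nz - 1) * 0.15, arc_deg, 1200.0)],
        noise_sd=0.0,
    )
    vol, truth = cr.build_phantom(spec)
    sections = cr.resample_sections(
        vol, truth.centerline, step_mm=0.3, patch_mm=12.6, in_plane_mm=0.15
    )
    return sections[len(sections) // 2]


def make_verdict(
    s: float,
    pass_mature: bool = False,
    pass_early: bool = False,
) -> cr.SectionVerdict:
    """A minimal hand-built verdict for run/quantify tests."""
    return cr.SectionVerdict(
        station_s=s,
        enclosure_deg_mature=300.0 if pass_mature else 100.0,
        enclosure_deg_early=300.0 if pass_early else 100.0,
        longest_arc_mature=300.0 if pass_mature else 100.0,
        longest_arc_early=300.0 if pass_early else 100.0,
        circularity=0.9,
        occluded_fraction=0.0,
        low_confidence=False,
        pass_mature=pass_mature,
        pass_early=pass_early,
    )
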