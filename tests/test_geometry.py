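"""Cross-section resampling and defect-interval geometry."""

import numpy as np
import pytest

import canalregen as cr
from canalregen.errors import GeometryError

L = 18.9


def _straight_centerline(z0=0.0, z1=10.0, n=21, x=5.0, y=5.0):
    z = np.linspace(z0, z1, n)
    return cr.Centerline(np.stack([np.full(n, x), np.full(n, y), z], axis=1))


def test_station_count_and_positions():
    v = cr.Volume(np.zeros((40, 40, 40)), spacing=(0.3, 0.3, 0.3), origin=(0, 0, 0))
    c = _straight_centerline(0.0, 10.0, x=5.85, y=5.85)
    secs = cr.resample_sections(v, c, step_mm=0.3, patch_mm=6.0, in_plane_mm=0.3)
    assert len(secs) == 34  # floor(10/0.3) + 1, stations 0 ... 9.9
    assert secs[0].station_s == 0.0
    assert secs[-1].station_s == pytest.approx(9.9)


@pytest.mark.parametrize("total,step,expected", [(10.0, 0.3, 34), (9.0, 0.3, 31), (10.0, 1.0, 11)])
def test_station_count_formula(total, step, expected):
    v = cr.Volume(np.zeros((60, 60, 60)), spacing=(0.3, 0.3, 0.3), origin=(0, 0, 0))
    c = _straight_centerline(1.0, 1.0 + total, x=8.85, y=8.85)
    secs = cr.resample_sections(v, c, step_mm=step, patch_mm=4.8, in_plane_mm=0.3)
    assert len(secs) == expected


def test_constant_volume_sections_are_constant():
    v = cr.Volume(np.full((40, 40, 40), 123.0), spacing=(0.3, 0.3, 0.3), origin=(0, 0, 0))
    c = _straight_centerline(2.0, 8.0, x=5.85, y=5.85)
    secs = cr.resample_sections(v, c, step_mm=1.0, patch_mm=4.8, in_plane_mm=0.3)
    for cs in secs:
        assert np.allclose(cs.grid, 123.0)
        assert cs.oob_fraction == 0.0


def test_section_normals_unit_and_tangential():
    from canalregen.phantom import _axis_samples_raw

    ax = cr.AxisSpec("sinusoidal", amplitude_mm=0.8, period_mm=12.0)
    Ltrue = float(_axis_samples_raw((48, 48, 64), (0.3, 0.3, 0.3), ax)[1][-1])
    spec = cr.PhantomSpec(stations=[cr.Station(0.0, Ltrue, 360, 1000)], axis=ax)
    vol, truth = cr.build_phantom(spec)
    secs = cr.resample_sections(vol, truth.centerline, step_mm=0.6)
    for cs in secs:
        assert abs(np.linalg.norm(cs.normal) - 1.0) < 1e-9
        assert abs(np.dot(cs.normal, cs.u)) < 1e-9
        assert abs(np.dot(cs.normal, cs.v)) < 1e-9


def test_annulus_radius_recovered_in_section():
    """Radial-profile oracle: mean wall radius = canal_radius + thickness/2."""
    spec = cr.PhantomSpec(stations=[cr.Station(0.0, L, 360, 1200)], noise_sd=0.0)
    vol, truth = cr.build_phantom(spec)
    secs = cr.resample_sections(vol, truth.centerline)
    cs = secs[len(secs) // 2]
    m = cs.grid.shape[0]
    offs = (np.arange(m) - (m - 1) / 2.0) * cs.in_plane_spacing
    X, Y = np.meshgrid(offs, offs, indexing="ij")
    r = np.hypot(X, Y)
    wall = cs.grid > 800.0
    mean_r = r[wall].mean()
    expected = spec.canal_radius + spec.wall_thickness / 2.0
    assert abs(mean_r - expected) <= cs.in_plane_spacing


def test_out_of_bounds_samples_flagged():
    v = cr.Volume(np.zeros((12, 12, 40)), spacing=(0.3, 0.3, 0.3), origin=(0, 0, 0))
    c = _straight_centerline(2.0, 8.0, x=1.65, y=1.65)  # near the volume corner
    secs = cr.resample_sections(v, c, step_mm=1.0, patch_mm=6.0, in_plane_mm=0.3)
    assert all(cs.oob_fraction > 0 for cs in secs)


def test_centerline_outside_volume_rejected():
    v = cr.Volume(np.zeros((10, 10, 10)), spacing=(0.3, 0.3, 0.3), origin=(0, 0, 0))
    c = _straight_centerline(0.0, 50.0)
    with pytest.raises(GeometryError):
        cr.resample_sections(v, c)


def test_defect_interval_collinear():
    c = _straight_centerline(0.0, 10.0, n=101, x=0.0, y=0.0)
    lm = cr.LandmarkPair((0, 0, 2), (0, 0, 8))
    di = cr.defect_interval(c, lm)
    assert di.defect_length == pytest.approx(6.0)
    assert (di.s_start, di.s_end) == (pytest.approx(2.0), pytest.approx(8.0))


def test_defect_interval_lateral_offsets_cancel():
    c = _straight_centerline(0.0, 10.0, n=101, x=0.0, y=0.0)
    lm = cr.LandmarkPair((1.0, 0, 0), (1.0, 0, 10.0))
    di = cr.defect_interval(c, lm)
    assert di.defect_length == pytest.approx(10.0)


def test_defect_interval_degenerate_rejected():
    c = _straight_centerline(0.0, 10.0, n=11, x=0.0, y=0.0)
    lm = cr.LandmarkPair((0.1, 0, 5.0), (0, 0.1, 5.01))  # both nearest z=5 vertex
    with pytest.raises(GeometryError):
        cr.defect_interval(c, lm)


def test_chord_never_exceeds_arc_on_curved_axis():
    from canalregen.phantom import _axis_samples_raw

    ax = cr.AxisSpec("sinusoidal", amplitude_mm=1.0, period_mm=10.0)
    Ltrue = float(_axis_samples_raw((48, 48, 64), (0.3, 0.3, 0.3), ax)[1][-1])
    spec = cr.PhantomSpec(
        stations=[cr.Station(0.0, Ltrue, 360, 1000)],
        axis=ax,
        defect_span_mm=(1.5, Ltrue - 1.5),
    )
    _, truth = cr.build_phantom(spec)
    di = cr.defect_interval(truth.centerline, truth.landmarks)
    arc = di.s_end - di.s_start
    assert di.defect_length <= arc + 1e-9


def test_translation_equivariance_end_to_end():
    spec = cr.make_case_spec(0.6, 0.05, seed=2, noise_sd=0.0)
    vol, truth = cr.build_phantom(spec)
    res0 = cr.score_case(vol, truth.centerline, truth.landmarks)

    shift = np.array([3.7, -1.2, 5.0])
    vol2 = cr.Volume(vol.data, vol.spacing, vol.origin + shift)
    c2 = cr.Centerline(truth.centerline.points + shift)
    lm2 = cr.LandmarkPair(
        truth.landmarks.mesial_apex + shift, truth.landmarks.distal_apex + shift
    )
    res1 = cr.score_case(vol2, c2, lm2)
    assert res1.report.regen_pct_800 == pytest.approx(res0.report.regen_pct_800)
    assert res1.report.regen_pct_400 == pytest.approx(res0.report.regen_pct_400)
    assert res1.report.defect_length == pytest.approx(res0.report.defect_length)
    for a, b in zip(res0.verdicts, res1.verdicts):
        assert b.enclosure_deg_mature == pytest.approx(a.enclosure_deg_mature, abs=1e-6)
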