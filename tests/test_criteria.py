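"""Enclosure angle, circularity, section verdicts and continuity runs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import canalregen as cr
from canalregen.errors import GeometryError, InputError
from conftest import ARC_PARAMS, angular_histogram_oracle, arc_section, make_verdict

L = 18.9


def _synthetic_section(radius_fn, wall_hu=1000.0, background=300.0, thickness=1.0,
                       in_plane=0.1, half_mm=6.0, metal_sector=None):
    """Build a CrossSection grid directly from an analytic wall r(theta)."""
    m = int(round(2 * half_mm / in_plane)) + 1
    offs = (np.arange(m) - (m - 1) / 2.0) * in_plane
    X, Y = np.meshgrid(offs, offs, indexing="ij")
    r = np.hypot(X, Y)
    th = np.arctan2(Y, X)
    r0 = radius_fn(th)
    grid = np.full((m, m), background)
    grid[(r >= r0) & (r <= r0 + thickness)] = wall_hu
    grid[r < r0] = 40.0
    if metal_sector is not None:
        lo, hi = np.radians(metal_sector[0]), np.radians(metal_sector[1])
        grid[(th >= lo) & (th <= hi) & (r >= r0 - 0.5) & (r <= r0 + thickness)] = 3071.0
    return cr.CrossSection(
        station_s=0.0, center=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]),
        grid=grid, in_plane_spacing=in_plane,
        u=np.array([1.0, 0, 0]), v=np.array([0, 1.0, 0]),
    )


def test_full_ring_measures_360(params):
    cs = _synthetic_section(lambda th: np.full_like(th, 2.0))
    ang = cr.enclosure_angle(cs, 800.0, params)
    assert abs(ang - 360.0) <= 1.0


def test_half_ring_measures_180_and_fails(params):
    cs = _synthetic_section(
        lambda th: np.where(np.abs(th) <= np.pi / 2, 2.0, 99.0)  # wall off-patch
    )
    ang = cr.enclosure_angle(cs, 800.0, params)
    assert abs(ang - 180.0) <= 2.0
    assert ang < params.enclosure_min_deg


@pytest.mark.parametrize("arc", [90.0, 180.0, 269.0, 271.0, 275.0, 360.0])
def test_enclosure_matches_angular_histogram_oracle(arc):
    cs = arc_section(arc)
    impl = cr.enclosure_angle(cs, 800.0, ARC_PARAMS)
    orc = angular_histogram_oracle(cs, 800.0, ARC_PARAMS)
    assert abs(impl - orc) <= 2.0
    assert abs(impl - arc) <= 2.0


def test_269_271_straddle_the_pass_boundary():
    below = cr.enclosure_angle(arc_section(269.0), 800.0, ARC_PARAMS)
    above = cr.enclosure_angle(arc_section(271.0), 800.0, ARC_PARAMS)
    assert below < 270.0
    assert above >= 270.0


def test_threshold_monotonicity_per_section(params):
    spec = cr.PhantomSpec(
        stations=[cr.Station(0.0, 9.0, 300, 600), cr.Station(9.0, L, 300, 1000)],
        noise_sd=25.0,
        seed=4,
    )
    vol, truth = cr.build_phantom(spec)
    secs = cr.resample_sections(vol, truth.centerline)
    for cs in secs:
        e800 = cr.enclosure_angle(cs, params.hu_mature, params)
        e400 = cr.enclosure_angle(cs, params.hu_early, params)
        assert e400 >= e800 - 1e-9


def test_ray_count_convergence():
    cs = arc_section(275.0)
    a360 = cr.enclosure_angle(cs, 800.0, ARC_PARAMS)
    p720 = cr.ScoringParams(
        band_inner_mm=ARC_PARAMS.band_inner_mm,
        band_outer_mm=ARC_PARAMS.band_outer_mm,
        ray_count=720,
    )
    a720 = cr.enclosure_angle(cs, 800.0, p720)
    assert abs(a720 - a360) < 1.0


def test_rotation_invariance_of_enclosure(params):
    cs = _synthetic_section(
        lambda th: np.where(np.abs(th) <= np.radians(150), 2.0, 99.0)
    )
    ang0 = cr.enclosure_angle(cs, 800.0, params)
    rotated = cr.CrossSection(
        station_s=0.0, center=cs.center, normal=cs.normal,
        grid=np.rot90(cs.grid).copy(), in_plane_spacing=cs.in_plane_spacing,
        u=cs.u, v=cs.v,
    )
    ang90 = cr.enclosure_angle(rotated, 800.0, params)
    assert abs(ang90 - ang0) <= 360.0 / params.ray_count + 1e-9


def test_annulus_must_fit_in_patch():
    cs = _synthetic_section(lambda th: np.full_like(th, 2.0), half_mm=3.0)
    p = cr.ScoringParams(band_inner_mm=1.0, band_outer_mm=5.0)
    with pytest.raises(GeometryError):
        cr.enclosure_angle(cs, 800.0, p)


def test_circularity_perfect_annulus(params):
    cs = _synthetic_section(lambda th: np.full_like(th, 2.0))
    assert cr.circularity(cs, 800.0, params) >= 0.95


def test_circularity_no_wall_is_zero(params):
    cs = _synthetic_section(lambda th: np.full_like(th, 2.0), wall_hu=100.0)
    assert cr.circularity(cs, 800.0, params) == 0.0


def test_circularity_ellipse_matches_closed_form(params):
    a, b = 3.2, 1.6  # 2:1 axes

    def r_ell(th):
        return a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)

    cs = _synthetic_section(r_ell, in_plane=0.05)
    p = cr.ScoringParams(band_inner_mm=1.2, band_outer_mm=5.5)
    score = cr.circularity(cs, 800.0, p)

    # oracle: same robust-CV formula on the analytic polar radii
    th = np.linspace(0, 2 * np.pi, p.ray_count, endpoint=False)
    r = r_ell(th)
    med = np.median(r)
    rcv = 1.4826 * np.median(np.abs(r - med)) / med
    expected = 1.0 - min(max(rcv, 0.0), 1.0)
    assert score == pytest.approx(expected, abs=0.05)


def test_score_sections_mixed_thresholds(params):
    # wall at 600 HU everywhere, full ring: early passes, mature fails
    spec = cr.PhantomSpec(stations=[cr.Station(0.0, L, 360, 600)], noise_sd=0.0)
    vol, truth = cr.build_phantom(spec)
    secs = cr.resample_sections(vol, truth.centerline)
    verdicts = cr.score_sections(secs, params)
    assert all(v.pass_early for v in verdicts)
    assert not any(v.pass_mature for v in verdicts)


def test_score_sections_all_air_fails(params):
    v = cr.Volume(np.full((40, 40, 40), -1000.0), spacing=(0.3, 0.3, 0.3), origin=(0, 0, 0))
    z = np.linspace(1.0, 10.0, 31)
    c = cr.Centerline(np.stack([np.full(31, 5.85), np.full(31, 5.85), z], axis=1))
    secs = cr.resample_sections(v, c, patch_mm=9.6)
    verdicts = cr.score_sections(secs, params)
    assert not any(v.pass_mature or v.pass_early for v in verdicts)


def test_score_sections_empty_rejected(params):
    with pytest.raises(InputError):
        cr.score_sections([], params)


def test_metal_occlusion_flagged(params):
    cs = _synthetic_section(lambda th: np.full_like(th, 2.0), metal_sector=(30, 100))
    verdicts = cr.score_sections([cs], params)
    v = verdicts[0]
    assert v.occluded_fraction > 0.10
    assert v.low_confidence
    # occluded rays leave the denominator: the remaining ring still encloses fully
    assert v.enclosure_deg_mature > 300.0


# ---------------------------------------------------------------------------
# continuity runs


def _runs(pattern, max_gap=0, min_run=0.9, step=0.3):
    verdicts = [make_verdict(i * step, pass_mature=p, pass_early=p) for i, p in enumerate(pattern)]
    params = cr.ScoringParams(min_run_mm=min_run, max_gap_sections=max_gap)
    return cr.find_runs(verdicts, "mature", params)


def test_runs_basic_pattern():
    runs = _runs([True, True, True, False, True, True, True])
    assert runs == [(0.0, pytest.approx(0.6)), (pytest.approx(1.2), pytest.approx(1.8))]


def test_single_section_is_isolated_area():
    assert _runs([False, True, False, False]) == []


def test_gap_tolerance_merges_runs():
    runs = _runs([True, True, True, False, True, True, True], max_gap=1)
    assert runs == [(0.0, pytest.approx(1.8))]


def _brute_force_runs(pattern, max_gap, min_count):
    """Independent reference: merge passing blocks over small gaps, filter."""
    n = len(pattern)
    blocks = []
    i = 0
    while i < n:
        if pattern[i]:
            j = i
            while j + 1 < n and pattern[j + 1]:
                j += 1
            blocks.append((i, j))
            i = j + 1
        else:
            i += 1
    merged = []
    for b in blocks:
        if merged and b[0] - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], b[1])
        else:
            merged.append(b)
    return [
        (lo, hi)
        for lo, hi in merged
        if sum(pattern[lo : hi + 1]) >= min_count
    ]


@settings(max_examples=200, deadline=None)
@given(
    pattern=st.lists(st.booleans(), min_size=2, max_size=30),
    max_gap=st.integers(min_value=0, max_value=3),
    min_count=st.integers(min_value=1, max_value=4),
)
def test_runs_match_brute_force(pattern, max_gap, min_count):
    step = 0.3
    expected = [
        (pytest.approx(lo * step), pytest.approx(hi * step))
        for lo, hi in _brute_force_runs(pattern, max_gap, min_count)
    ]
    got = _runs(pattern, max_gap=max_gap, min_run=min_count * step)
    assert got == expected
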