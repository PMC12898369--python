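"""Per-section and per-run scoring of the four canal-identification criteria.

A cross-section passes at a density threshold when (i) its wall shows
supra-threshold bone (criterion 2, embodied in the threshold itself),
(ii) the bony enclosure around the canal centre spans >= 270 degrees
(criterion 3), and (iii) the wall has a tubular/circular morphology
(criterion 4, a radial-regularity score). Criterion 1 — continuity across
sequential sections — is applied over the section sequence by `find_runs`,
which discards isolated short passing spans.

Enclosure is measured by radial ray casting: equally spaced rays from the
section centre are classified as "walled" when they cross a minimal
contiguous span of bone-range HU inside a radial search annulus. The
enclosure angle is the total angular coverage of walled rays; the longest
contiguous walled arc is recorded alongside as a diagnostic. Rays that meet
metal (clamped-ceiling HU from implants) before bone are excluded from the
denominator; sections with many occluded rays are flagged low-confidence.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import GeometryError, InputError
from .geometry import CrossSection
from .volume_io import HU_MIN

__all__ = [
    "ScoringParams",
    "SectionVerdict",
    "enclosure_angle",
    "circularity",
    "score_sections",
    "find_runs",
]


@dataclass
class ScoringParams:
    """Tunable parameters of the scoring criteria.

    hu_mature / hu_early
        Wall-density thresholds in HU: >800 mature bone, >400 early or
        partially mineralised bone.
    hu_bone_upper
        Upper HU bound of the bone range; samples at or above it are treated
        as metal (implants saturate the 12-bit CT ceiling).
    enclosure_min_deg
        Minimal circumferential bony enclosure (degrees) for a section to
        pass; 270 by definition of the criterion.
    ray_count
        Rays cast per section.
    band_inner_mm / band_outer_mm
        Radial wall-search annulus around the section centre.
    min_wall_mm
        Minimal contiguous supra-threshold radial chord for a walled ray;
        None means one in-plane sample.
    circularity_min
        Morphology score threshold in [0, 1].
    min_run_mm
        Minimal continuous passing span; shorter spans are isolated areas,
        not canal.
    max_gap_sections
        Failing sections tolerated consecutively inside a run.
    occlusion_flag_fraction
        Occluded-ray fraction above which a section is flagged low-confidence.
    """

    hu_mature: float = 800.0
    hu_early: float = 400.0
    hu_bone_upper: float = 3071.0
    enclosure_min_deg: float = 270.0
    ray_count: int = 360
    band_inner_mm: float = 1.2
    band_outer_mm: float = 4.5
    min_wall_mm: float | None = None
    circularity_min: float = 0.6
    min_run_mm: float = 0.9
    max_gap_sections: int = 0
    occlusion_flag_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.hu_early < self.hu_mature <= self.hu_bone_upper):
            raise InputError("require 0 < hu_early < hu_mature <= hu_bone_upper")
        if not (0 < self.enclosure_min_deg <= 360):
            raise InputError("enclosure_min_deg must lie in (0, 360]")
        if not self.band_inner_mm < self.band_outer_mm:
            raise InputError("band_inner_mm must be < band_outer_mm")
        if self.ray_count < 8:
            raise InputError("ray_count too small")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SectionVerdict:
    """Criterion outcomes for one cross-section."""

    station_s: float
    enclosure_deg_mature: float
    enclosure_deg_early: float
    longest_arc_mature: float
    longest_arc_early: float
    circularity: float
    occluded_fraction: float
    low_confidence: bool
    pass_mature: bool
    pass_early: bool


@dataclass
class _RayAnalysis:
    walled: np.ndarray  # bool per ray
    occluded: np.ndarray  # bool per ray
    r_first: np.ndarray  # inner wall radius per walled ray (nan if not walled)
    enclosure_deg: float
    longest_arc_deg: float
    occluded_fraction: float


def _ray_analysis(cs: CrossSection, hu_thresh: float, p: ScoringParams) -> _RayAnalysis:
    if p.band_outer_mm > cs.half_extent_mm + 1e-9:
        raise GeometryError(
            f"wall-search annulus (outer {p.band_outer_mm} mm) exceeds the "
            f"section patch (half extent {cs.half_extent_mm:.2f} mm)"
        )
    dr = cs.in_plane_spacing / 2.0
    radii = np.arange(p.band_inner_mm, p.band_outer_mm + dr / 2, dr)
    thetas = np.linspace(0.0, 2 * math.pi, p.ray_count, endpoint=False)
    x = radii[None, :] * np.cos(thetas)[:, None]
    y = radii[None, :] * np.sin(thetas)[:, None]
    c0 = (cs.grid.shape[0] - 1) / 2.0
    ix = x / cs.in_plane_spacing + c0
    iy = y / cs.in_plane_spacing + c0
    prof = map_coordinates(
        cs.grid, [ix.ravel(), iy.ravel()], order=1, mode="constant", cval=HU_MIN
    ).reshape(p.ray_count, len(radii))

    # half-HU guard: interpolation of clamped-ceiling (metal) voxels must not
    # round just below the bound and masquerade as bone
    upper = p.hu_bone_upper - 0.5
    metal = prof >= upper
    # partial-volume samples adjacent to metal are blooming, not bone: dilate
    # the metal mask by one radial sample before classifying bone
    metal_guard = metal.copy()
    metal_guard[:, 1:] |= metal[:, :-1]
    metal_guard[:, :-1] |= metal[:, 1:]
    bone = (prof > hu_thresh) & (prof < upper) & ~metal_guard

    min_wall = p.min_wall_mm if p.min_wall_mm is not None else cs.in_plane_spacing
    n_min = max(1, int(math.ceil(min_wall / dr - 1e-9)))

    n_rays, n_r = bone.shape
    has_metal = metal.any(axis=1)
    m_first = np.where(has_metal, np.argmax(metal, axis=1), n_r)

    runlen = np.zeros(n_rays, dtype=int)
    jstar = np.full(n_rays, -1, dtype=int)
    for j in range(n_r):
        runlen = np.where(bone[:, j], runlen + 1, 0)
        newly = (jstar < 0) & (runlen >= n_min) & (j < m_first)
        jstar = np.where(newly, j, jstar)
    walled = jstar >= 0
    occluded = (~walled) & has_metal

    r_first = np.full(n_rays, np.nan)
    r_first[walled] = radii[jstar[walled] - n_min + 1]

    denom = n_rays - int(occluded.sum())
    enclosure = 360.0 * walled.sum() / denom if denom > 0 else 0.0

    longest = _longest_circular_run(walled) * 360.0 / n_rays
    return _RayAnalysis(
        walled=walled,
        occluded=occluded,
        r_first=r_first,
        enclosure_deg=float(enclosure),
        longest_arc_deg=float(longest),
        occluded_fraction=float(occluded.mean()),
    )


def _longest_circular_run(mask: np.ndarray) -> int:
    if mask.all():
        return len(mask)
    if not mask.any():
        return 0
    # rotate so the sequence starts at a failure, then scan linearly
    start = int(np.argmin(mask))
    rolled = np.roll(mask, -start)
    best = cur = 0
    for v in rolled:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def enclosure_angle(cs: CrossSection, hu_thresh: float, p: ScoringParams) -> float:
    """Total angular coverage (degrees) of bony wall around the section centre.

    Casts ``p.ray_count`` equally spaced rays; a ray is walled when it crosses
    at least ``min_wall_mm`` of contiguous bone-range HU inside the search
    annulus. Returns 360 x walled / (rays - occluded).
    """
    return _ray_analysis(cs, hu_thresh, p).enclosure_deg


def circularity(cs: CrossSection, hu_thresh: float, p: ScoringParams) -> float:
    """Radial-regularity morphology score in [0, 1].

    Uses the inner wall radius of each walled ray; the score is one minus the
    robust coefficient of variation (scaled MAD over median) of those radii,
    clipped to [0, 1]. Fewer than 3 walled rays score 0 (no tube to speak of).
    """
    ra = _ray_analysis(cs, hu_thresh, p)
    r = ra.r_first[ra.walled]
    if len(r) < 3:
        return 0.0
    med = float(np.median(r))
    if med <= 0:
        return 0.0
    mad = float(np.median(np.abs(r - med)))
    rcv = 1.4826 * mad / med
    return float(1.0 - min(max(rcv, 0.0), 1.0))


def score_sections(sections: list[CrossSection], p: ScoringParams) -> list[SectionVerdict]:
    """Score every section at both density thresholds.

    Circularity is evaluated on the inclusive bone definition (hu_early, the
    lower bound of the bone range) and shared by both pass flags, so passing
    at the mature threshold always implies at least as much passing length at
    the early threshold.
    """
    if not sections:
        raise InputError("empty section list")
    stations = [cs.station_s for cs in sections]
    if any(b <= a for a, b in zip(stations, stations[1:])):
        raise InputError("sections must be ordered by increasing station_s")
    verdicts = []
    for cs in sections:
        ra_m = _ray_analysis(cs, p.hu_mature, p)
        ra_e = _ray_analysis(cs, p.hu_early, p)
        r = ra_e.r_first[ra_e.walled]
        if len(r) < 3:
            circ = 0.0
        else:
            med = float(np.median(r))
            mad = float(np.median(np.abs(r - med)))
            circ = 1.0 - min(max(1.4826 * mad / med, 0.0), 1.0) if med > 0 else 0.0
        occl = max(ra_m.occluded_fraction, ra_e.occluded_fraction)
        verdicts.append(
            SectionVerdict(
                station_s=cs.station_s,
                enclosure_deg_mature=ra_m.enclosure_deg,
                enclosure_deg_early=ra_e.enclosure_deg,
                longest_arc_mature=ra_m.longest_arc_deg,
                longest_arc_early=ra_e.longest_arc_deg,
                circularity=circ,
                occluded_fraction=occl,
                low_confidence=occl > p.occlusion_flag_fraction,
                pass_mature=(ra_m.enclosure_deg >= p.enclosure_min_deg)
                and (circ >= p.circularity_min),
                pass_early=(ra_e.enclosure_deg >= p.enclosure_min_deg)
                and (circ >= p.circularity_min),
            )
        )
    return verdicts


def _infer_step(stations: np.ndarray) -> float:
    diffs = np.diff(stations)
    if len(diffs) == 0:
        raise InputError("need at least 2 stations to infer the section step")
    return float(np.median(diffs))


def _pass_flags(verdicts: list[SectionVerdict], threshold_kind: str) -> np.ndarray:
    if threshold_kind == "mature":
        return np.array([v.pass_mature for v in verdicts], dtype=bool)
    if threshold_kind == "early":
        return np.array([v.pass_early for v in verdicts], dtype=bool)
    raise InputError(f"unknown threshold kind: {threshold_kind!r}")


def find_runs(
    verdicts: list[SectionVerdict],
    threshold_kind: str,
    p: ScoringParams,
) -> list[tuple[float, float]]:
    """Maximal continuous passing runs (criterion 1, canal continuity).

    Consecutive passing blocks are merged when separated by at most
    ``max_gap_sections`` failing sections. A run qualifies only when its
    passing stations span at least ``min_run_mm`` (passing count x step);
    shorter spans are isolated hypodense areas, not a linear canal. Returns
    (s_start, s_end) of each qualifying run, bounded by passing sections.
    """
    if len(verdicts) < 2:
        # a single section cannot show continuity across sequential sections
        return []
    stations = np.array([v.station_s for v in verdicts])
    passes = _pass_flags(verdicts, threshold_kind)
    if not passes.any():
        return []
    step = _infer_step(stations)

    # passing blocks as (first_idx, last_idx)
    idx = np.flatnonzero(passes)
    block_breaks = np.flatnonzero(np.diff(idx) > 1)
    blocks = []
    start = 0
    for b in block_breaks:
        blocks.append((int(idx[start]), int(idx[b])))
        start = b + 1
    blocks.append((int(idx[start]), int(idx[-1])))

    # merge blocks across allowed gaps
    merged = [list(blocks[0])]
    for lo, hi in blocks[1:]:
        gap = lo - merged[-1][1] - 1
        if gap <= p.max_gap_sections:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])

    runs = []
    for lo, hi in merged:
        n_pass = int(passes[lo : hi + 1].sum())
        if n_pass * step >= p.min_run_mm - 1e-9:
            runs.append((float(stations[lo]), float(stations[hi])))
    return runs
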