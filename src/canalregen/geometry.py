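"""Perpendicular cross-section resampling along the canal axis.

A case is analysed as a sequence of 2D sections orthogonal to the centerline,
one per arc-length station (default step 0.3 mm, one native CBCT voxel, so
"sequential sections" means scanner-resolution slices). The in-plane frame is
transported along the axis with minimal rotation; enclosure angles downstream
are rotation-invariant, so only frame continuity matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import GeometryError
from .volume_io import HU_MIN, Centerline, LandmarkPair, Volume

__all__ = ["CrossSection", "DefectInterval", "resample_sections", "defect_interval"]


@dataclass
class CrossSection:
    """One resampled plane orthogonal to the canal axis.

    ``grid[i, j]`` is the HU sample at world point
    ``center + offs[i] * u + offs[j] * v`` where ``offs`` is a symmetric
    1D coordinate axis with step ``in_plane_spacing``; the section centre is
    the middle grid sample.
    """

    station_s: float
    center: np.ndarray
    normal: np.ndarray
    grid: np.ndarray
    in_plane_spacing: float
    u: np.ndarray
    v: np.ndarray
    oob_fraction: float = 0.0

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            raise GeometryError("section normal must be unit length")

    @property
    def half_extent_mm(self) -> float:
        """Distance from the section centre to the patch edge."""
        return (self.grid.shape[0] - 1) / 2.0 * self.in_plane_spacing


@dataclass
class DefectInterval:
    """Arc-length interval of the surgically disrupted canal segment."""

    s_start: float
    s_end: float
    defect_length: float

    def __post_init__(self) -> None:
        if not self.s_start < self.s_end:
            raise GeometryError("defect interval requires s_start < s_end")
        if not self.defect_length > 0:
            raise GeometryError("defect length must be positive")


def _tangents(c: Centerline, stations: np.ndarray, h: float) -> np.ndarray:
    """Central-difference unit tangents (one-sided at the endpoints)."""
    lo = np.maximum(stations - h, 0.0)
    hi = np.minimum(stations + h, c.length)
    d = c.position(hi) - c.position(lo)
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    if np.any(norms <= 1e-12):
        raise GeometryError("degenerate tangent along centerline")
    return d / norms


def _transported_frames(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimal-rotation frame (u, v) transported along the tangent sequence."""
    t0 = tangents[0]
    seed = np.eye(3)[np.argmin(np.abs(t0))]
    u = seed - np.dot(seed, t0) * t0
    u /= np.linalg.norm(u)
    us = np.empty_like(tangents)
    vs = np.empty_like(tangents)
    for k, t in enumerate(tangents):
        u = u - np.dot(u, t) * t
        n = np.linalg.norm(u)
        if n < 1e-9:  # tangent flipped by ~90°+; restart the frame
            seed = np.eye(3)[np.argmin(np.abs(t))]
            u = seed - np.dot(seed, t) * t
            n = np.linalg.norm(u)
        u = u / n
        us[k] = u
        vs[k] = np.cross(t, u)
    return us, vs


def resample_sections(
    v: Volume,
    c: Centerline,
    step_mm: float = 0.3,
    patch_mm: float = 10.8,
    in_plane_mm: float = 0.3,
) -> list[CrossSection]:
    """Resample perpendicular sections at stations 0, step, 2*step, ..., end.

    Each section grid is sampled by trilinear interpolation on the plane
    orthogonal to the local centerline tangent. Samples falling outside the
    volume are filled with -1024 HU and counted in ``oob_fraction``; a fully
    out-of-bounds section raises GeometryError.
    """
    if step_mm <= 0:
        raise GeometryError("step_mm must be positive")
    if not np.all(v.contains(c.points)):
        raise GeometryError("centerline extends outside the volume bounding box")

    n_stations = int(np.floor(c.length / step_mm + 1e-9)) + 1
    stations = np.arange(n_stations) * step_mm
    centers = c.position(stations)
    tangents = _tangents(c, stations, h=min(step_mm, 0.25))
    us, vs = _transported_frames(tangents)

    m = int(round(patch_mm / in_plane_mm)) + 1
    offs = (np.arange(m) - (m - 1) / 2.0) * in_plane_mm
    A, B = np.meshgrid(offs, offs, indexing="ij")
    ab = np.stack([A.ravel(), B.ravel()], axis=1)  # (m*m, 2)

    # all sample points for all stations in one interpolation call
    pts = (
        centers[:, None, :]
        + ab[None, :, 0:1] * us[:, None, :]
        + ab[None, :, 1:2] * vs[:, None, :]
    )  # (n_stations, m*m, 3)
    idx = v.world_to_index(pts.reshape(-1, 3))
    nvox = np.array(v.shape, dtype=float)
    oob = np.any((idx < 0) | (idx > nvox - 1), axis=1)
    vals = map_coordinates(v.data, idx.T, order=1, mode="constant", cval=HU_MIN)
    vals = vals.reshape(n_stations, m, m)
    oob = oob.reshape(n_stations, m * m)

    sections = []
    for k in range(n_stations):
        frac = float(oob[k].mean())
        if frac >= 1.0:
            raise GeometryError(
                f"section at s={stations[k]:.2f} mm lies fully outside the volume"
            )
        sections.append(
            CrossSection(
                station_s=float(stations[k]),
                center=centers[k],
                normal=tangents[k],
                grid=vals[k],
                in_plane_spacing=in_plane_mm,
                u=us[k],
                v=vs[k],
                oob_fraction=frac,
            )
        )
    return sections


def defect_interval(c: Centerline, lm: LandmarkPair) -> DefectInterval:
    """Locate the defect on the centerline from the implant apex landmarks.

    ``s_start``/``s_end`` are the arc-length stations of the centerline
    vertices nearest the mesial and distal apices (ties resolved to the
    smaller s). ``defect_length`` is the straight-line apex-to-apex distance,
    which is the denominator of the regeneration percentage.
    """
    i_m = int(np.argmin(np.linalg.norm(c.points - lm.mesial_apex, axis=1)))
    i_d = int(np.argmin(np.linalg.norm(c.points - lm.distal_apex, axis=1)))
    if i_m == i_d:
        raise GeometryError(
            "both apices are nearest the same centerline point (degenerate defect)"
        )
    s_pair = sorted((float(c.arc_length[i_m]), float(c.arc_length[i_d])))
    return DefectInterval(
        s_start=s_pair[0], s_end=s_pair[1], defect_length=lm.linear_distance
    )
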