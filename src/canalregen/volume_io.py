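"""Volume, centerline and landmark I/O, and the package's coordinate conventions.

All geometry lives in world millimetres. Voxel indices are 0-based and a voxel
value is the sample at the voxel centre, so the world/voxel mapping is the
affine ``world = origin + index * spacing`` with the in-memory grid always
ordered (x, y, z). Hounsfield values are clamped on load to the 12-bit CT range
[-1024, 3071]; the clamp count is kept on the volume so metal-saturated voxels
(implants) remain identifiable downstream.

Supported containers: NIfTI-1 (.nii/.nii.gz, via nibabel) and NRRD (.nrrd, via
SimpleITK). Centerlines and landmarks are plain-text x,y,z tables.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import FormatError, GeometryError, MetadataError

HU_MIN = -1024.0
HU_MAX = 3071.0

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "Volume",
    "Centerline",
    "LandmarkPair",
    "read_volume",
    "write_volume",
    "read_centerline",
    "write_centerline",
    "read_landmarks",
    "write_landmarks",
]


@dataclass
class Volume:
    """A 3D HU grid with axis-aligned world geometry.

    Parameters
    ----------
    data
        3D float array, axis order (x, y, z), values in HU.
    spacing
        Per-axis voxel size in mm, all strictly positive.
    origin
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    clamped_voxels
        Number of voxels clamped into [-1024, 3071] at construction.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    clamped_voxels: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.data.ndim != 3:
            raise GeometryError(f"volume grid must be 3D, got ndim={self.data.ndim}")
        if any(n < 2 for n in self.data.shape):
            raise GeometryError(f"volume needs >= 2 voxels per axis, got {self.data.shape}")
        if not np.all(self.spacing > 0):
            raise GeometryError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise GeometryError("volume contains non-finite HU values")
        low = self.data < HU_MIN
        high = self.data > HU_MAX
        n_clamped = int(low.sum() + high.sum())
        if n_clamped:
            self.data = np.clip(self.data, HU_MIN, HU_MAX)
        self.clamped_voxels += n_clamped

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def world_min(self) -> np.ndarray:
        """World coordinate of the first voxel centre."""
        return self.origin.copy()

    @property
    def world_max(self) -> np.ndarray:
        """World coordinate of the last voxel centre."""
        return self.origin + (np.array(self.shape) - 1) * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (..., 3) to continuous 0-based voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Elementwise test: does each point lie inside the voxel-centre bbox?"""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        ok = np.all((p >= self.world_min - tol) & (p <= self.world_max + tol), axis=1)
        return ok


@dataclass
class Centerline:
    """Ordered polyline of the nerve/canal axis in world mm.

    ``arc_length`` is the cumulative Euclidean distance per vertex, starting
    at 0 and strictly increasing.
    """

    points: np.ndarray
    arc_length: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise GeometryError("centerline needs >= 2 three-dimensional points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 1e-9):
            raise GeometryError("centerline has repeated consecutive points")
        computed = np.concatenate([[0.0], np.cumsum(seg)])
        if self.arc_length is None:
            self.arc_length = computed
        else:
            self.arc_length = np.asarray(self.arc_length, dtype=np.float64)
            if self.arc_length.shape != (len(self.points),) or not np.allclose(
                self.arc_length, computed, atol=1e-6
            ):
                raise GeometryError("arc_length inconsistent with point spacing")

    @property
    def length(self) -> float:
        """Total arc length in mm."""
        return float(self.arc_length[-1])

    def position(self, s: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the polyline at arc-length coordinate(s) s."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        out = np.stack(
            [np.interp(s, self.arc_length, self.points[:, k]) for k in range(3)], axis=-1
        )
        return out


@dataclass
class LandmarkPair:
    """Mesial and distal implant apex points (world mm) bounding the defect."""

    mesial_apex: np.ndarray
    distal_apex: np.ndarray

    def __post_init__(self) -> None:
        self.mesial_apex = np.asarray(self.mesial_apex, dtype=np.float64).reshape(3)
        self.distal_apex = np.asarray(self.distal_apex, dtype=np.float64).reshape(3)
        if np.linalg.norm(self.mesial_apex - self.distal_apex) <= 1e-9:
            raise GeometryError("landmark apices must be distinct points")

    @property
    def linear_distance(self) -> float:
        """Straight-line apex-to-apex distance (mm) — the defect length."""
        return float(np.linalg.norm(self.mesial_apex - self.distal_apex))


# ---------------------------------------------------------------------------
# volume I/O


def _read_nifti(path: Path, gain: float, offset: float) -> Volume:
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    aff = np.asarray(img.affine, dtype=float)
    rot = aff[:3, :3]
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0) or not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-3):
        raise MetadataError(f"{path}: affine is not axis-aligned or lacks voxel spacing")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    # NIfTI headers are float32; snap to 1e-6 mm so 0.3 mm stays exactly 0.3
    spacing = np.round(spacing, 6)
    origin = np.round(aff[:3, 3], 6)
    return Volume(data * gain + offset, spacing, origin)


def _read_nrrd(path: Path, gain: float, offset: float) -> Volume:
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as e:  # pragma: no cover - message path
        raise FormatError(f"cannot read NRRD volume {path}: {e}") from e
    direction = np.array(img.GetDirection(), dtype=float).reshape(3, 3)
    if not np.allclose(np.abs(direction), np.eye(3), atol=1e-3):
        raise MetadataError(f"{path}: only axis-aligned NRRD orientations are supported")
    data = sitk.GetArrayFromImage(img).astype(np.float64).transpose(2, 1, 0)  # -> (x,y,z)
    spacing = np.array(img.GetSpacing(), dtype=float)
    origin = np.array(img.GetOrigin(), dtype=float)
    if np.any(spacing <= 0):
        raise MetadataError(f"{path}: missing or non-positive voxel spacing")
    # fold axis flips into the data so the in-memory convention stays +x,+y,+z
    for ax in range(3):
        if direction[ax, ax] < 0:
            data = np.flip(data, axis=ax)
            origin[ax] = origin[ax] - spacing[ax] * (data.shape[ax] - 1)
    return Volume(data * gain + offset, spacing, origin)


def read_volume(path: str | Path, gain: float = 1.0, offset: float = 0.0) -> Volume:
    """Read a NIfTI or NRRD volume as HU.

    ``gain``/``offset`` apply an optional affine gray-value-to-HU rescale
    (``hu = gain * value + offset``) before clamping, for scanners whose gray
    values are not already HU-calibrated.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    name = path.name.lower()
    try:
        if name.endswith((".nii", ".nii.gz")):
            return _read_nifti(path, gain, offset)
        if name.endswith(".nrrd"):
            return _read_nrrd(path, gain, offset)
    except (MetadataError, FormatError):
        raise
    except Exception as e:
        raise FormatError(f"cannot read volume {path}: {e}") from e
    raise FormatError(f"unsupported volume format: {path} (expected .nii/.nii.gz/.nrrd)")


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a volume losslessly; the file round-trips through read_volume."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        aff = np.diag(np.append(v.spacing, 1.0))
        aff[:3, 3] = v.origin
        nib.save(nib.Nifti1Image(v.data, aff), str(path))
    elif name.endswith(".nrrd"):
        img = sitk.GetImageFromArray(v.data.transpose(2, 1, 0))
        img.SetSpacing(tuple(float(s) for s in v.spacing))
        img.SetOrigin(tuple(float(o) for o in v.origin))
        try:
            sitk.WriteImage(img, str(path))
        except RuntimeError as e:
            raise OSError(f"cannot write volume to {path}: {e}") from e
    else:
        raise FormatError(f"unsupported volume format: {path} (expected .nii/.nii.gz/.nrrd)")


# ---------------------------------------------------------------------------
# plain-text geometry tables


def _read_point_table(path: Path) -> np.ndarray:
    if not path.exists():
        raise FormatError(f"point table not found: {path}")
    text = path.read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.replace(",", " "))
    if not rows:
        raise GeometryError(f"{path}: no points found")
    try:
        arr = np.loadtxt(_io.StringIO("\n".join(rows)), ndmin=2)
    except ValueError as e:
        raise FormatError(f"{path}: cannot parse point table: {e}") from e
    if arr.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 columns (x,y,z), got {arr.shape[1]}")
    return arr


def read_centerline(path: str | Path) -> Centerline:
    """Read an ordered x,y,z polyline (world mm) from a text table.

    Comma- or whitespace-separated, one point per line, '#' comments ignored.
    """
    pts = _read_point_table(Path(path))
    if len(pts) < 2:
        raise GeometryError(f"{path}: a centerline needs at least 2 points")
    return Centerline(pts)


def write_centerline(c: Centerline, path: str | Path) -> None:
    header = "# centerline points: x_mm, y_mm, z_mm"
    body = "\n".join(f"{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}" for p in c.points)
    Path(path).write_text(header + "\n" + body + "\n")


def read_landmarks(path: str | Path) -> LandmarkPair:
    """Read mesial and distal apex points (two rows: mesial first)."""
    pts = _read_point_table(Path(path))
    if len(pts) != 2:
        raise GeometryError(f"{path}: expected exactly 2 landmark points, got {len(pts)}")
    return LandmarkPair(pts[0], pts[1])


def write_landmarks(lm: LandmarkPair, path: str | Path) -> None:
    header = "# landmarks: mesial apex then distal apex (x_mm, y_mm, z_mm)"
    body = "\n".join(
        f"{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}" for p in (lm.mesial_apex, lm.distal_apex)
    )
    Path(path).write_text(header + "\n" + body + "\n")
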