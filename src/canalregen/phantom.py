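"""Synthetic CBCT phantoms with analytically known canal-wall geometry.

A phantom emulates the imaging situation after inferior alveolar nerve
transposition: a trabecular-bone background, a low-density tubular lumen
(the nerve's soft-tissue track) along a known axis, and a partial annular
bony wall whose angular coverage and HU value vary along the axis — mature
bone (>800 HU), early mineralising bone (400-800 HU) or no wall at all.
Optional metallic implant cylinders saturate the CT ceiling, and additive
Gaussian noise stresses the thresholding.

The wall layout is a *station table*: disjoint arc-length intervals covering
the whole axis, each with a single contiguous angular arc (centred on the +x
reference direction) and one wall HU. Ground truth — which fraction of the
defect interval carries a wall of >=270 degrees at each density threshold —
is integrated analytically from this table, never from the rendered grid, so
it is exact and invariant to noise and implants.

Voxel membership is decided at the voxel centre (no anti-aliasing), which
keeps the analytic truth exact at voxel-centre resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .errors import SpecError
from .volume_io import Centerline, LandmarkPair, Volume

__all__ = [
    "AxisSpec",
    "Station",
    "Implant",
    "PhantomSpec",
    "PhantomTruth",
    "build_phantom",
    "sample_cohort",
    "make_case_spec",
    "random_phantom_spec",
]


@dataclass
class AxisSpec:
    """Canal axis shape: straight along z, or sinusoidal in x as x(z)."""

    kind: str = "straight"  # "straight" | "sinusoidal"
    amplitude_mm: float = 0.0
    period_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "sinusoidal"):
            raise SpecError(f"unknown axis kind: {self.kind!r}")
        if self.kind == "sinusoidal" and self.period_mm <= 0:
            raise SpecError("sinusoidal axis needs a positive period")


@dataclass
class Station:
    """One arc-length interval of the station table."""

    s_start: float
    s_end: float
    wall_arc_deg: float
    wall_hu: float

    def __post_init__(self) -> None:
        if not (0 <= self.wall_arc_deg <= 360):
            raise SpecError(f"wall_arc_deg must be in [0, 360], got {self.wall_arc_deg}")
        if not (-1024 <= self.wall_hu <= 3071):
            raise SpecError(f"wall_hu must be in [-1024, 3071], got {self.wall_hu}")
        if not self.s_end > self.s_start:
            raise SpecError("station interval must have positive length")


@dataclass
class Implant:
    """A dental-implant cylinder, axis along world y (crestal direction)."""

    center: tuple[float, float, float]
    radius_mm: float = 1.75
    length_mm: float = 8.0
    hu: float = 3500.0  # saturates; clamps to the 3071 ceiling on load


@dataclass
class PhantomSpec:
    """Full description of one synthetic case.

    Defaults mimic the study's imaging protocol: isotropic 0.3 mm voxels and
    a canal of radius 1.5 mm with a ~1.2 mm bony wall.
    """

    shape: tuple[int, int, int] = (48, 48, 64)
    spacing: tuple[float, float, float] = (0.3, 0.3, 0.3)
    canal_radius: float = 1.5
    wall_thickness: float = 1.2
    axis: AxisSpec = field(default_factory=AxisSpec)
    stations: list[Station] = field(default_factory=list)
    background_hu: float = 300.0
    lumen_hu: float = 40.0
    implants: list[Implant] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    defect_span_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.canal_radius <= 0:
            raise SpecError("canal_radius must be positive")
        voxel_diag = float(np.linalg.norm(self.spacing))
        if self.wall_thickness < voxel_diag - 1e-9:
            raise SpecError(
                f"wall_thickness {self.wall_thickness} mm below one voxel "
                f"diagonal ({voxel_diag:.3f} mm)"
            )
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")
        L = self.axis_length
        sts = sorted(self.stations, key=lambda st: st.s_start)
        if not sts:
            raise SpecError("station table is empty")
        if abs(sts[0].s_start) > 1e-6 or abs(sts[-1].s_end - L) > 1e-6:
            raise SpecError(
                f"stations must cover [0, {L:.3f}] mm; got "
                f"[{sts[0].s_start}, {sts[-1].s_end}]"
            )
        for a, b in zip(sts, sts[1:]):
            if abs(a.s_end - b.s_start) > 1e-6:
                raise SpecError("stations must be disjoint and contiguous")
        self.stations = sts
        if self.defect_span_mm is not None:
            s0, s1 = self.defect_span_mm
            if not (0 - 1e-9 <= s0 < s1 <= L + 1e-9):
                raise SpecError(f"defect span {self.defect_span_mm} outside [0, {L:.3f}]")

    @property
    def axis_length(self) -> float:
        """Total centerline arc length in mm."""
        _, s = _axis_samples(self, n_per_voxel=8)
        return float(s[-1])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "axis" in d and isinstance(d["axis"], dict):
            d["axis"] = AxisSpec(**d["axis"])
        if "stations" in d:
            d["stations"] = [
                Station(*st) if isinstance(st, (list, tuple)) else Station(**st)
                for st in d["stations"]
            ]
        if "implants" in d:
            d["implants"] = [
                Implant(**im) if isinstance(im, dict) else Implant(tuple(im[0:3]), *im[3:])
                for im in d["implants"]
            ]
        if d.get("defect_span_mm") is not None:
            d["defect_span_mm"] = tuple(d["defect_span_mm"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a rendered phantom."""

    centerline: Centerline
    landmarks: LandmarkPair
    per_station_truth: list[Station]
    true_regen_fraction_800: float
    true_regen_fraction_400: float
    defect_span_mm: tuple[float, float]

    def __post_init__(self) -> None:
        f8, f4 = self.true_regen_fraction_800, self.true_regen_fraction_400
        if not (0 - 1e-9 <= f8 <= f4 <= 1 + 1e-9):
            raise SpecError("truth fractions must satisfy 0 <= f800 <= f400 <= 1")

    def to_dict(self) -> dict:
        return {
            "true_regen_fraction_800": self.true_regen_fraction_800,
            "true_regen_fraction_400": self.true_regen_fraction_400,
            "defect_span_mm": list(self.defect_span_mm),
            "per_station_truth": [asdict(st) for st in self.per_station_truth],
            "landmarks": {
                "mesial_apex": self.landmarks.mesial_apex.tolist(),
                "distal_apex": self.landmarks.distal_apex.tolist(),
            },
        }


# ---------------------------------------------------------------------------
# axis geometry


def _axis_xy(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    axis: AxisSpec,
    z: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    cx = (shape[0] - 1) / 2.0 * spacing[0]
    cy = (shape[1] - 1) / 2.0 * spacing[1]
    if axis.kind == "sinusoidal":
        x = cx + axis.amplitude_mm * np.sin(2 * np.pi * z / axis.period_mm)
    else:
        x = np.full_like(z, cx)
    return x, np.full_like(z, cy)


def _axis_samples_raw(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    axis: AxisSpec,
    n_per_voxel: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Finely sampled axis points and their cumulative arc length."""
    nz, dz = shape[2], spacing[2]
    z = np.linspace(0.0, (nz - 1) * dz, (nz - 1) * n_per_voxel + 1)
    x, y = _axis_xy(shape, spacing, axis, z)
    pts = np.stack([x, y, z], axis=1)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, s


def _axis_samples(spec: "PhantomSpec", n_per_voxel: int = 8) -> tuple[np.ndarray, np.ndarray]:
    return _axis_samples_raw(spec.shape, spec.spacing, spec.axis, n_per_voxel)


def _station_lookup(stations: list[Station], s: float) -> Station:
    for st in stations:
        if st.s_start - 1e-9 <= s <= st.s_end + 1e-9:
            return st
    return stations[-1]


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def _truth_fraction(stations: list[Station], span: tuple[float, float], hu_cut: float) -> float:
    s0, s1 = span
    total = s1 - s0
    covered = sum(
        _overlap(st.s_start, st.s_end, s0, s1)
        for st in stations
        if st.wall_arc_deg >= 270.0 and st.wall_hu > hu_cut
    )
    return covered / total


# ---------------------------------------------------------------------------
# rendering


def build_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Render a phantom volume and its analytic ground truth.

    The wall of each axial slice follows the station whose arc-length interval
    contains that slice; the angular arc is centred on the +x direction.
    Implants overwrite bone/background (a spec whose implant intersects the
    lumen is rejected); seeded Gaussian noise is added last and the result is
    HU-clamped by the Volume constructor.
    """
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing
    fine_pts, fine_s = _axis_samples(spec)

    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dy
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    vol = np.full(spec.shape, spec.background_hu, dtype=np.float64)
    lumen_mask = np.zeros(spec.shape, dtype=bool)

    z_slices = np.arange(nz) * dz
    ax_all, ay_all = _axis_xy(spec.shape, spec.spacing, spec.axis, z_slices)
    s_of_z = np.interp(z_slices, fine_pts[:, 2], fine_s)

    r_out = spec.canal_radius + spec.wall_thickness
    for k in range(nz):
        ddx = X - ax_all[k]
        ddy = Y - ay_all[k]
        r = np.hypot(ddx, ddy)
        lum = r <= spec.canal_radius
        st = _station_lookup(spec.stations, float(s_of_z[k]))
        sl = vol[:, :, k]
        if st.wall_arc_deg > 0:
            ring = (r > spec.canal_radius) & (r <= r_out)
            if st.wall_arc_deg < 360:
                theta = np.degrees(np.arctan2(ddy, ddx))
                ring &= np.abs(theta) <= st.wall_arc_deg / 2.0
            sl[ring] = st.wall_hu
        sl[lum] = spec.lumen_hu
        lumen_mask[:, :, k] = lum

    if spec.implants:
        zs = np.arange(nz) * dz
        X3 = X[:, :, None]
        Z3 = zs[None, None, :]
        Y3 = ys[None, :, None]
        for im in spec.implants:
            cx0, cy0, cz0 = im.center
            cyl = ((X3 - cx0) ** 2 + (Z3 - cz0) ** 2 <= im.radius_mm**2) & (
                np.abs(Y3 - cy0) <= im.length_mm / 2.0
            )
            if (cyl & lumen_mask).any():
                raise SpecError("implant cylinder overlaps the canal lumen")
            vol[np.broadcast_to(cyl, vol.shape)] = im.hu

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)

    volume = Volume(vol, spec.spacing, (0.0, 0.0, 0.0))

    # centerline at one point per slice (native resolution)
    cl_pts = np.stack([ax_all, ay_all, z_slices], axis=1)
    centerline = Centerline(cl_pts)

    span = spec.defect_span_mm if spec.defect_span_mm is not None else (0.0, float(fine_s[-1]))
    landmarks = _landmarks_for(spec, centerline, span)

    truth = PhantomTruth(
        centerline=centerline,
        landmarks=landmarks,
        per_station_truth=list(spec.stations),
        true_regen_fraction_800=_truth_fraction(spec.stations, span, 800.0),
        true_regen_fraction_400=_truth_fraction(spec.stations, span, 400.0),
        defect_span_mm=(float(span[0]), float(span[1])),
    )
    return volume, truth


def _landmarks_for(
    spec: PhantomSpec, centerline: Centerline, span: tuple[float, float]
) -> LandmarkPair:
    """Implant end-cap apices when implants exist, else on-axis span ends."""
    if spec.implants:
        ims = sorted(spec.implants, key=lambda im: im.center[2])
        mesial, distal = ims[0], ims[-1]
        canal_y = (spec.shape[1] - 1) / 2.0 * spec.spacing[1]

        def apex(im: Implant) -> np.ndarray:
            cx0, cy0, cz0 = im.center
            half = im.length_mm / 2.0
            y_apex = cy0 - half if cy0 >= canal_y else cy0 + half
            return np.array([cx0, y_apex, cz0])

        return LandmarkPair(apex(mesial), apex(distal))
    return LandmarkPair(centerline.position(span[0]), centerline.position(span[1]))


# ---------------------------------------------------------------------------
# spec builders


def make_case_spec(
    regen_frac_800: float,
    early_frac_400: float = 0.05,
    seed: int = 0,
    noise_sd: float = 30.0,
    nz: int = 64,
    axis: AxisSpec | None = None,
    margin_mm: float = 1.5,
) -> PhantomSpec:
    """Build a single-case spec with a prescribed true regeneration fraction.

    The defect interval starts ``margin_mm`` inside the axis; a contiguous
    fraction ``regen_frac_800`` of it carries a mature wall (330 deg, 1100 HU),
    a further ``early_frac_400`` carries early bone (330 deg, 600 HU), and the
    remainder has only a sub-criterion remnant (100 deg, 600 HU). Outside the
    defect the native canal is intact (360 deg, 1200 HU).
    """
    if not 0 <= regen_frac_800 <= 1:
        raise SpecError("regen_frac_800 must lie in [0, 1]")
    early_frac_400 = min(early_frac_400, 1.0 - regen_frac_800)
    dz = 0.3
    ax = axis or AxisSpec()
    L = float(_axis_samples_raw((48, 48, nz), (dz, dz, dz), ax)[1][-1])

    s0 = margin_mm
    s1 = L - margin_mm
    D = s1 - s0
    stations = [Station(0.0, s0, 360, 1200)]
    cur = s0
    for frac, arc, hu in (
        (regen_frac_800, 330, 1100),
        (early_frac_400, 330, 600),
        (1.0 - regen_frac_800 - early_frac_400, 100, 600),
    ):
        if frac > 1e-9:
            end = min(cur + frac * D, s1)
            if end - cur > 1e-9:
                stations.append(Station(cur, end, arc, hu))
                cur = end
    if s1 - cur > 1e-9:
        stations.append(Station(cur, s1, 100, 600))
    stations.append(Station(s1, L, 360, 1200))

    return PhantomSpec(
        shape=(48, 48, nz),
        spacing=(dz, dz, dz),
        axis=ax,
        stations=stations,
        noise_sd=noise_sd,
        seed=seed,
        defect_span_mm=(s0, s1),
    )


def random_phantom_spec(seed: int) -> PhantomSpec:
    """A randomized phantom (random station table, optional curved axis)."""
    rng = np.random.default_rng(seed)
    nz = 48
    dz = 0.3
    ax = AxisSpec()
    if rng.random() < 0.5:
        ax = AxisSpec("sinusoidal", amplitude_mm=float(rng.uniform(0.2, 0.8)), period_mm=15.0)
    L = float(_axis_samples_raw((48, 48, nz), (dz, dz, dz), ax)[1][-1])
    n_st = int(rng.integers(3, 7))
    cuts = np.sort(rng.uniform(0.05, 0.95, n_st - 1)) * L
    edges = np.concatenate([[0.0], cuts, [L]])
    stations = [
        Station(
            float(a),
            float(b),
            float(rng.uniform(0, 360)),
            float(rng.uniform(300, 1400)),
        )
        for a, b in zip(edges[:-1], edges[1:])
        if b - a > 1e-6
    ]
    return PhantomSpec(
        shape=(48, 48, nz),
        spacing=(dz, dz, dz),
        axis=ax,
        stations=stations,
        noise_sd=30.0,
        seed=int(rng.integers(0, 2**31 - 1)),
        defect_span_mm=(1.5, L - 1.5),
    )


def sample_cohort(
    n: int, regen_mean: float, regen_sd: float, seed: int
) -> list[PhantomSpec]:
    """Draw a cohort of case specs with truth fractions ~ truncated normal.

    Truth fractions at the mature threshold are drawn from a normal
    (regen_mean, regen_sd) truncated to [0, 1]; the early-bone surplus per
    case is uniform in [0.03, 0.08]. Deterministic given the seed.
    """
    if n < 1:
        raise SpecError("cohort size must be >= 1")
    if not 0 <= regen_mean <= 1:
        raise SpecError("regen_mean must lie in [0, 1]")
    if regen_sd < 0:
        raise SpecError("regen_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if regen_sd == 0:
        fracs = np.full(n, regen_mean)
    else:
        a = (0.0 - regen_mean) / regen_sd
        b = (1.0 - regen_mean) / regen_sd
        fracs = stats.truncnorm.rvs(
            a, b, loc=regen_mean, scale=regen_sd, size=n, random_state=rng
        )
    extras = rng.uniform(0.03, 0.08, size=n)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        make_case_spec(float(f), float(min(e, 1.0 - f)), seed=int(s))
        for f, e, s in zip(fracs, extras, seeds)
    ]
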