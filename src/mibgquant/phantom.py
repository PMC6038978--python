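"""Digital chest phantoms for myocardial MIBG quantification.

Generates the three acquisition geometries of a cardiac MIBG study with
known ground truth:

* a dynamic planar chest series (first-pass bolus through the pulmonary
  artery, 120 frames of 1 s at 128x128, 3.3 mm pixels),
* a static planar chest image (5 min at 256x256),
* a myocardial activity volume (64^3) and its parallel-beam SPECT
  projections (60 views over 360 deg, 20 s per view).

Anatomy is deliberately simple — ellipses and ellipsoids for body, lungs,
pulmonary artery, mediastinum, liver and a myocardial shell — so every
downstream measurement has a closed-form truth.  Activity units are
arbitrary but consistent across the three channels of one subject, which
is what makes dose-invariance tests of the uptake indices meaningful.

The first-pass bolus is a gamma variate ``K (t-t0)^alpha exp(-(t-t0)/beta)``
plus one delayed, scaled recirculation copy.  Counting noise is Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import stats

from .projector import ParallelProjector

__all__ = [
    "BolusParams",
    "Ellipse2D",
    "Rect2D",
    "Ellipsoid",
    "DefectSpec",
    "PhantomConfig",
    "DynamicSeries",
    "PlanarImage",
    "ActivityVolume",
    "ProjectionSet",
    "SubjectPhantom",
    "GroupDistribution",
    "gamma_variate",
    "bolus_curve",
    "make_dynamic_series",
    "make_planar_image",
    "make_myocardial_volume",
    "forward_project",
    "draw_group_concentrations",
    "make_cohort",
    "DEFAULT_GROUP_DISTRIBUTIONS",
]


# --------------------------------------------------------------------------
# geometry primitives


@dataclass(frozen=True)
class Ellipse2D:
    """Axis-aligned ellipse in pixel coordinates (row, col)."""

    center: tuple[float, float]
    semi: tuple[float, float]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        return (
            ((rr - self.center[0]) / self.semi[0]) ** 2
            + ((cc - self.center[1]) / self.semi[1]) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class Rect2D:
    """Axis-aligned rectangle [r0, r1) x [c0, c1) in pixel coordinates."""

    r0: int
    r1: int
    c0: int
    c1: int

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.r0 : self.r1, self.c0 : self.c1] = True
        return m


@dataclass(frozen=True)
class Ellipsoid:
    """Ellipsoid in voxel coordinates (z, y, x) with a tilted long axis.

    ``semi`` are the semi-axes along the local (long, short, short)
    directions; the long axis is obtained from +z by a rotation of
    ``tilt_deg`` about the y axis followed by ``spin_deg`` about the z axis.
    """

    center: tuple[float, float, float]
    semi: tuple[float, float, float]
    spin_deg: float = 0.0
    tilt_deg: float = 0.0

    def axis_vector(self) -> np.ndarray:
        """Unit long-axis direction in (z, y, x) components."""
        t = np.deg2rad(self.tilt_deg)
        s = np.deg2rad(self.spin_deg)
        # rotate +z by tilt about y (toward +x), then spin about z (x toward +y)
        v = np.array([np.cos(t), np.sin(s) * np.sin(t), np.cos(s) * np.sin(t)])
        return v

    def _local_coords(self, zz, yy, xx):
        dz = zz - self.center[0]
        dy = yy - self.center[1]
        dx = xx - self.center[2]
        t = np.deg2rad(self.tilt_deg)
        s = np.deg2rad(self.spin_deg)
        # world -> local: undo spin about z, then undo tilt about y
        dx1 = np.cos(s) * dx + np.sin(s) * dy
        dy1 = -np.sin(s) * dx + np.cos(s) * dy
        dz1 = dz
        dz2 = np.cos(t) * dz1 + np.sin(t) * dx1
        dx2 = -np.sin(t) * dz1 + np.cos(t) * dx1
        return dz2, dy1, dx2

    def inside(self, zz, yy, xx) -> np.ndarray:
        lz, ly, lx = self._local_coords(zz, yy, xx)
        return (
            (lz / self.semi[0]) ** 2
            + (ly / self.semi[1]) ** 2
            + (lx / self.semi[2]) ** 2
        ) <= 1.0


def _ellipsoid_fraction(shape, ell: Ellipsoid, supersample: int) -> np.ndarray:
    """Per-voxel inside fraction, optionally antialiased by supersampling."""
    nz, ny, nx = shape
    if supersample <= 1:
        zz, yy, xx = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        return ell.inside(zz, yy, xx).astype(float)
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    frac = np.zeros(shape)
    for oz in offs:
        for oy in offs:
            for ox in offs:
                zz, yy, xx = np.meshgrid(
                    np.arange(nz) + oz,
                    np.arange(ny) + oy,
                    np.arange(nx) + ox,
                    indexing="ij",
                )
                frac += ell.inside(zz, yy, xx)
    return frac / supersample**3


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class BolusParams:
    """First-pass bolus: gamma variate plus one recirculation copy."""

    K: float = 100.0  # amplitude, counts/pixel/s at unit dose scale
    alpha: float = 3.0  # shape, dimensionless
    beta: float = 1.5  # time scale, s
    t0: float = 8.0  # arrival time, s
    recirc_fraction: float = 0.3  # kappa, in [0, 1)
    recirc_delay: float = 12.0  # s


@dataclass(frozen=True)
class DefectSpec:
    """Angular perfusion defect: shell voxels in the sector scaled by 1-depth.

    Angles are measured in the short-axis (y, x) plane about the shell
    center, counterclockwise from +x, in degrees.
    """

    center_angle_deg: float = 0.0
    extent_deg: float = 90.0
    depth: float = 0.25


@dataclass(frozen=True)
class PhantomConfig:
    # grids
    dynamic_shape: tuple[int, int] = (128, 128)
    planar_shape: tuple[int, int] = (256, 256)
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    pixel_mm: float = 3.3
    voxel_mm: float = 6.6
    # timing
    frame_duration_s: float = 1.0
    n_frames: int = 120
    planar_duration_s: float = 300.0
    n_views: int = 60
    view_duration_s: float = 20.0
    # activity
    dose_scale: float = 1.0  # proportional to the injected 111 MBq
    bolus: BolusParams = field(default_factory=BolusParams)
    planar_count_scale: float = 300.0  # counts/pixel per conc unit over 5 min
    projection_count_scale: float = 10.0  # counts/bin per conc-unit voxel path
    # 2D organ concentrations for the static planar image (arbitrary units);
    # organs add on top of the body background, the heart adds
    # heart_planar_coeff * myocardial concentration
    body_planar: float = 0.12
    lung_planar: float = 0.10
    mediastinum_planar: float = 0.08
    liver_planar: float = 0.50
    heart_planar_coeff: float = 0.35
    # dynamic-phase tissue amplitudes relative to the bolus peak
    lung_bolus_fraction: float = 0.25
    lung_bolus_delay_s: float = 2.0
    lung_beta_factor: float = 2.0
    tissue_uptake_tau_s: float = 60.0
    myo_dynamic_coeff: float = 0.10
    mediastinum_dynamic: float = 0.02
    body_dynamic: float = 0.01
    liver_dynamic: float = 0.08
    # 3D concentrations (same units as the myocardial concentration)
    body_volume: float = 0.05
    liver_volume: float = 0.40
    supersample: int = 2
    # geometry: dynamic 128x128 view
    dyn_body: Ellipse2D = field(default_factory=lambda: Ellipse2D((72, 64), (48, 56)))
    dyn_lung_r: Ellipse2D = field(default_factory=lambda: Ellipse2D((52, 38), (24, 16)))
    dyn_lung_l: Ellipse2D = field(default_factory=lambda: Ellipse2D((52, 90), (24, 16)))
    dyn_mediastinum: Ellipse2D = field(
        default_factory=lambda: Ellipse2D((40, 64), (14, 7))
    )
    dyn_liver: Ellipse2D = field(default_factory=lambda: Ellipse2D((100, 44), (16, 22)))
    dyn_heart: Ellipse2D = field(default_factory=lambda: Ellipse2D((78, 80), (14, 13)))
    pa_center: tuple[float, float] = (48.0, 64.0)
    pa_radius: float = 2.5
    # geometry: planar 256x256 view
    pl_body: Ellipse2D = field(default_factory=lambda: Ellipse2D((150, 128), (95, 112)))
    pl_lung_r: Ellipse2D = field(default_factory=lambda: Ellipse2D((105, 75), (48, 34)))
    pl_lung_l: Ellipse2D = field(
        default_factory=lambda: Ellipse2D((105, 180), (48, 34))
    )
    pl_mediastinum: Rect2D = field(default_factory=lambda: Rect2D(45, 105, 114, 142))
    pl_liver: Ellipse2D = field(default_factory=lambda: Ellipse2D((205, 95), (30, 45)))
    pl_heart: Ellipse2D = field(default_factory=lambda: Ellipse2D((140, 155), (28, 26)))
    # geometry: 64^3 volume
    vol_body: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((32, 32, 32), (28, 26, 26))
    )
    vol_liver: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((52, 40, 40), (9, 11, 11))
    )
    myo_outer: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((30, 34, 30), (14, 10, 10))
    )
    myo_inner_semi: tuple[float, float, float] = (10.0, 6.0, 6.0)
    # noise
    noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        for nm, shape in (
            ("dynamic_shape", self.dynamic_shape),
            ("planar_shape", self.planar_shape),
            ("volume_shape", self.volume_shape),
        ):
            if any(int(s) <= 0 for s in shape):
                raise ValueError(f"{nm} must be positive, got {shape}")
        if self.n_frames <= 0 or self.frame_duration_s <= 0:
            raise ValueError("frame count and duration must be positive")
        if self.pixel_mm <= 0 or self.voxel_mm <= 0:
            raise ValueError("pixel/voxel spacing must be positive")
        if not 0.0 <= self.bolus.recirc_fraction < 1.0:
            raise ValueError("recirculation fraction must be in [0, 1)")
        for nm in (
            "dose_scale",
            "body_planar",
            "lung_planar",
            "mediastinum_planar",
            "liver_planar",
            "heart_planar_coeff",
            "body_volume",
            "liver_volume",
        ):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# containers


@dataclass
class DynamicSeries:
    """Dynamic planar count series: frames indexed (time, row, col)."""

    frames: np.ndarray
    frame_duration_s: float = 1.0
    pixel_mm: float = 3.3
    start_time_s: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, row, col)")
        if np.any(self.frames < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame midpoint times in seconds."""
        return self.start_time_s + (np.arange(self.n_frames) + 0.5) * self.frame_duration_s


@dataclass
class PlanarImage:
    """Static planar count image."""

    counts: np.ndarray
    pixel_mm: float = 3.3
    duration_s: float = 300.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class ActivityVolume:
    """Activity-concentration volume with its ground-truth myocardial mask."""

    concentration: np.ndarray
    voxel_mm: float = 6.6
    myocardial_mask: Optional[np.ndarray] = None
    mean_myocardial_concentration: float = 0.0

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.concentration.ndim != 3:
            raise ValueError("concentration must be 3D")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be nonnegative")
        if self.myocardial_mask is not None:
            self.myocardial_mask = np.asarray(self.myocardial_mask, dtype=bool)
            if self.myocardial_mask.shape != self.concentration.shape:
                raise ValueError("mask must match the grid")

    @property
    def voxel_volume_ml(self) -> float:
        return (self.voxel_mm / 10.0) ** 3

    def total_activity(self) -> float:
        return float(self.concentration.sum() * self.voxel_volume_ml)


@dataclass
class ProjectionSet:
    """SPECT projection stack: (view, axial, transverse bin)."""

    views: np.ndarray
    angles_deg: np.ndarray
    view_duration_s: float = 20.0
    voxel_mm: float = 6.6

    def __post_init__(self):
        self.views = np.asarray(self.views, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.views.ndim != 3:
            raise ValueError("views must be (view, axial, bin)")
        if len(self.angles_deg) != self.views.shape[0]:
            raise ValueError("one angle per view required")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles_deg[0] < 0 or self.angles_deg[-1] >= 360.0:
            raise ValueError("angles must span [0, 360)")
        if np.any(self.views < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class SubjectPhantom:
    """One simulated subject: images plus ground truth."""

    subject_id: str
    group: str  # "LBD" | "non-LBD"
    true_concentration: float
    dynamic: Optional[DynamicSeries] = None
    planar: Optional[PlanarImage] = None
    projections: Optional[ProjectionSet] = None
    volume: Optional[ActivityVolume] = None
    pa_center: Optional[tuple[float, float]] = None
    heart_center: Optional[tuple[float, float]] = None
    axis_angles_deg: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.group not in ("LBD", "non-LBD"):
            raise ValueError(f"invalid group label {self.group!r}")


# --------------------------------------------------------------------------
# time-activity models


def gamma_variate(t, K, alpha, beta, t0):
    """``K (t-t0)^alpha exp(-(t-t0)/beta)`` for t > t0, else 0."""
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(dt)
    pos = dt > 0
    out[pos] = K * dt[pos] ** alpha * np.exp(-dt[pos] / beta)
    return out


def bolus_curve(t, p: BolusParams):
    """First-pass gamma variate plus one delayed recirculation copy."""
    g = gamma_variate(t, p.K, p.alpha, p.beta, p.t0)
    if p.recirc_fraction > 0:
        g = g + p.recirc_fraction * gamma_variate(
            t, p.K, p.alpha, p.beta, p.t0 + p.recirc_delay
        )
    return g


def _tissue_curve(t, amplitude, tau):
    return amplitude * (1.0 - np.exp(-np.asarray(t, float) / tau))


# --------------------------------------------------------------------------
# generators


def make_dynamic_series(config: PhantomConfig, seed: Optional[int] = None) -> DynamicSeries:
    """Simulate the first-pass dynamic chest series.

    Pulmonary-artery pixels follow the bolus model exactly (they override
    any underlying organ); lungs see a delayed, broadened, scaled copy of
    the bolus plus slow retention; myocardium, mediastinum, liver and body
    follow slow mono-exponential uptake curves.  Poisson noise is applied
    iff ``config.noise``.
    """
    config.validate()
    shape = config.dynamic_shape
    t = (np.arange(config.n_frames) + 0.5) * config.frame_duration_s
    p = config.bolus
    peak = p.K * (p.alpha * p.beta) ** p.alpha * np.exp(-p.alpha)

    lung_bolus = gamma_variate(
        t,
        config.lung_bolus_fraction * p.K / (config.lung_beta_factor**p.alpha),
        p.alpha,
        p.beta * config.lung_beta_factor,
        p.t0 + config.lung_bolus_delay_s,
    )
    tau = config.tissue_uptake_tau_s
    curves = {
        "body": _tissue_curve(t, config.body_dynamic * peak, tau),
        "lung": lung_bolus + _tissue_curve(t, 0.03 * peak, tau),
        "mediastinum": _tissue_curve(t, config.mediastinum_dynamic * peak, tau),
        "liver": _tissue_curve(t, config.liver_dynamic * peak, tau),
        "heart": _tissue_curve(t, config.myo_dynamic_coeff * peak, tau),
    }
    heart_mask = config.dyn_heart.mask(shape)
    masks = {
        "body": config.dyn_body.mask(shape),
        # the cardiac silhouette displaces lung
        "lung": (config.dyn_lung_r.mask(shape) | config.dyn_lung_l.mask(shape))
        & ~heart_mask,
        "mediastinum": config.dyn_mediastinum.mask(shape),
        "liver": config.dyn_liver.mask(shape),
        "heart": heart_mask,
    }

    frames = np.zeros((config.n_frames, *shape))
    for name in ("body", "lung", "mediastinum", "liver", "heart"):
        add = curves[name][:, None] * masks[name].ravel()[None, :]
        frames += add.reshape(config.n_frames, *shape)
    # pulmonary artery overrides whatever lies beneath it so that its pixel
    # trace is the bolus model exactly
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    pa_mask = (rr - config.pa_center[0]) ** 2 + (cc - config.pa_center[1]) ** 2 <= (
        config.pa_radius**2
    )
    pa = bolus_curve(t, p)
    frames[:, pa_mask] = pa[:, None]

    frames *= config.dose_scale * config.frame_duration_s
    if config.noise:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        frames = rng.poisson(frames).astype(float)
    return DynamicSeries(
        frames, frame_duration_s=config.frame_duration_s, pixel_mm=config.pixel_mm
    )


def make_planar_image(
    config: PhantomConfig,
    myocardial_concentration: float,
    seed: Optional[int] = None,
) -> PlanarImage:
    """Simulate the 5-min static chest image.

    Organs add fixed concentration increments on top of the body
    background; the heart adds ``heart_planar_coeff x concentration``.
    """
    config.validate()
    if myocardial_concentration < 0:
        raise ValueError("myocardial concentration must be nonnegative")
    shape = config.planar_shape
    img = np.zeros(shape)
    heart_mask = config.pl_heart.mask(shape)
    img[config.pl_body.mask(shape)] += config.body_planar
    # the cardiac silhouette displaces lung
    img[config.pl_lung_r.mask(shape) & ~heart_mask] += config.lung_planar
    img[config.pl_lung_l.mask(shape) & ~heart_mask] += config.lung_planar
    img[config.pl_mediastinum.mask(shape)] += config.mediastinum_planar
    img[config.pl_liver.mask(shape)] += config.liver_planar
    img[heart_mask] += config.heart_planar_coeff * myocardial_concentration
    img *= config.planar_count_scale * config.dose_scale
    if config.noise:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        img = rng.poisson(img).astype(float)
    return PlanarImage(img, pixel_mm=config.pixel_mm, duration_s=config.planar_duration_s)


def make_myocardial_volume(
    config: PhantomConfig,
    myocardial_concentration: float,
    defect: Optional[DefectSpec] = None,
) -> ActivityVolume:
    """Build the ground-truth activity volume: an ellipsoidal myocardial
    shell at the given concentration over body and liver background.

    The ground-truth mask contains the voxels fully inside the shell (so
    with background 0 every mask voxel equals the shell concentration even
    when edge antialiasing is on).  An optional angular defect scales shell
    voxels in its sector by ``1 - depth``.
    """
    config.validate()
    if myocardial_concentration < 0:
        raise ValueError("myocardial concentration must be nonnegative")
    if defect is not None:
        if not 0.0 <= defect.depth <= 1.0:
            raise ValueError("defect depth must be in [0, 1]")
        if not 0.0 <= defect.extent_deg <= 360.0:
            raise ValueError("defect angular extent must be within [0, 360] deg")
    shape = config.volume_shape
    ss = config.supersample

    outer = config.myo_outer
    inner = Ellipsoid(outer.center, config.myo_inner_semi, outer.spin_deg, outer.tilt_deg)
    f_outer = _ellipsoid_fraction(shape, outer, ss)
    f_inner = _ellipsoid_fraction(shape, inner, ss)
    shell = np.clip(f_outer - f_inner, 0.0, 1.0)

    if defect is not None and defect.depth > 0 and defect.extent_deg > 0:
        zz, yy, xx = np.meshgrid(
            np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
        )
        ang = np.rad2deg(np.arctan2(yy - outer.center[1], xx - outer.center[2]))
        d = (ang - defect.center_angle_deg + 180.0) % 360.0 - 180.0
        in_sector = np.abs(d) <= defect.extent_deg / 2.0
        shell = np.where(in_sector, shell * (1.0 - defect.depth), shell)

    grid = shell * myocardial_concentration
    grid += _ellipsoid_fraction(shape, config.vol_body, 1) * config.body_volume
    grid += _ellipsoid_fraction(shape, config.vol_liver, 1) * config.liver_volume
    # tissue activity is proportional to the injected dose, like the
    # dynamic and planar channels of the same subject
    grid *= config.dose_scale

    mask = (f_outer - f_inner) >= 0.999
    mean_conc = float(grid[mask].mean()) if mask.any() else 0.0
    return ActivityVolume(
        grid,
        voxel_mm=config.voxel_mm,
        myocardial_mask=mask,
        mean_myocardial_concentration=mean_conc,
    )


def forward_project(
    volume: ActivityVolume,
    n_views: int = 60,
    seed: Optional[int] = None,
    view_duration_s: float = 20.0,
    count_scale: float = 10.0,
) -> ProjectionSet:
    """Parallel-beam projections of the volume, uniformly over 360 deg.

    Each view is the line integral of the in-plane-rotated volume (no
    attenuation, scatter or detector blur).  Poisson noise is applied iff a
    seed is given.
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    angles = np.arange(n_views) * 360.0 / n_views
    proj = ParallelProjector.cached(volume.concentration.shape[1], angles)
    views = proj.forward(volume.concentration) * count_scale
    if seed is not None:
        rng = np.random.default_rng(seed)
        views = rng.poisson(views).astype(float)
    return ProjectionSet(
        views, angles, view_duration_s=view_duration_s, voxel_mm=volume.voxel_mm
    )


# --------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class GroupDistribution:
    """Log-normal true-uptake law matched by median and interquartile range."""

    median: float
    q1: float
    q3: float

    def lognormal_params(self) -> tuple[float, float]:
        if self.median <= 0 or self.q1 <= 0 or self.q3 <= self.q1:
            raise ValueError("distribution scale must be positive with q3 > q1")
        mu = np.log(self.median)
        z75 = stats.norm.ppf(0.75)
        sigma = np.log(self.q3 / self.q1) / (2.0 * z75)
        return mu, sigma


# Group laws mirror the reported LBD / non-LBD uptake-index distributions
# (median and IQR) of the clinical comparison this package emulates.
DEFAULT_GROUP_DISTRIBUTIONS = {
    "LBD": GroupDistribution(median=0.63, q1=0.52, q3=0.82),
    "non-LBD": GroupDistribution(median=1.70, q1=1.53, q3=2.03),
}


def draw_group_concentrations(
    n: int, dist: GroupDistribution, rng: np.random.Generator
) -> np.ndarray:
    mu, sigma = dist.lognormal_params()
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def make_cohort(
    n_lbd: int,
    n_nonlbd: int,
    group_params: Optional[dict] = None,
    seed: int = 0,
    config: Optional[PhantomConfig] = None,
    images: bool = True,
) -> list[SubjectPhantom]:
    """Generate a two-group cohort of subject phantoms.

    Per-subject true myocardial concentration is drawn from the group's
    log-normal law; with ``images=True`` (default) the full dynamic,
    planar and projection sets are generated per subject, all from the
    same injected-dose scale.  ``images=False`` draws truth only, for
    cheap distributional checks.
    """
    if n_lbd < 0 or n_nonlbd < 0:
        raise ValueError("group sizes must be nonnegative")
    dists = dict(DEFAULT_GROUP_DISTRIBUTIONS)
    if group_params:
        dists.update(group_params)
    config = config or PhantomConfig()
    config.validate()

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    concs = {
        "LBD": draw_group_concentrations(n_lbd, dists["LBD"], rng),
        "non-LBD": draw_group_concentrations(n_nonlbd, dists["non-LBD"], rng),
    }
    subjects: list[SubjectPhantom] = []
    child_seeds = ss.spawn(n_lbd + n_nonlbd)
    i = 0
    for group, cs in (("LBD", concs["LBD"]), ("non-LBD", concs["non-LBD"])):
        for c in cs:
            sid = f"{'L' if group == 'LBD' else 'N'}{i:03d}"
            subj = SubjectPhantom(
                subject_id=sid,
                group=group,
                true_concentration=float(c),
                pa_center=config.pa_center,
                heart_center=config.pl_heart.center,
                axis_angles_deg=(config.myo_outer.spin_deg, config.myo_outer.tilt_deg),
            )
            if images:
                sub_rng = np.random.default_rng(child_seeds[i])
                s_dyn, s_pl, s_pr = sub_rng.integers(0, 2**31 - 1, size=3)
                subj.dynamic = make_dynamic_series(config, seed=int(s_dyn))
                subj.planar = make_planar_image(config, float(c), seed=int(s_pl))
                vol = make_myocardial_volume(config, float(c))
                subj.volume = vol
                subj.projections = forward_project(
                    vol,
                    n_views=config.n_views,
                    seed=int(s_pr) if config.noise else None,
                    view_duration_s=config.view_duration_s,
                    count_scale=config.projection_count_scale,
                )
            subjects.append(subj)
            i += 1
    return subjects
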