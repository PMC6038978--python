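"""SPECT-side quantification: OSEM reconstruction, short-axis reorientation,
the myocardial polar map (bull's eye), the 2D-3D count-conversion factor,
and the SPECT uptake index.

The output function is the polar-map count measure ``Cmyo``; each sector's
value is the maximum over radius of the running mean of three consecutive
radial samples, and the map-level measure is the arithmetic mean of all
ring x sector values (the total is exposed as an option).  The uptake
index is

    index = scale * Cmyo / (CF * AUC)

where CF is the 2D-3D count-conversion factor calibrated by regressing
SPECT polar-map counts on planar heart counts through the origin, and AUC
is the first-pass input function.  Scatter and attenuation corrections are
deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import (
    AxisUndetermined,
    DegenerateX,
    EmptySlice,
    IndivisibleSubsets,
    InvalidCalibration,
    TooFewPairs,
    ZeroAuc,
)
from .phantom import ProjectionSet
from .projector import ParallelProjector

__all__ = [
    "ReconVolume",
    "ShortAxisGeometry",
    "PolarMap",
    "CalibrationModel",
    "SpectQuantResult",
    "osem_reconstruct",
    "reorient_short_axis",
    "build_polar_map",
    "calibrate_cf",
    "spect_uptake_index",
]

_EPS = 1e-12  # zero-sensitivity / zero-projection guard


@dataclass
class ReconVolume:
    """Reconstructed count volume with its iteration record."""

    counts: np.ndarray
    voxel_mm: float = 6.6
    subsets: int = 4
    iterations: int = 30

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be 3D")
        if np.any(self.counts < 0):
            raise ValueError("reconstruction must be nonnegative")


@dataclass(frozen=True)
class ShortAxisGeometry:
    """Myocardial center, long-axis angles, and apex-to-base slice range.

    ``spin_deg`` is the transaxial rotation about the volume z axis and
    ``tilt_deg`` the vertical tilt away from z; both in (-90, 90) degrees.
    The slice range is inclusive, apex first.
    """

    center: tuple[float, float, float]
    spin_deg: float = 0.0
    tilt_deg: float = 0.0
    slice_range: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if not (-90.0 < self.spin_deg < 90.0 and -90.0 < self.tilt_deg < 90.0):
            raise ValueError("angles must lie in (-90, 90) degrees")
        if self.slice_range[1] < self.slice_range[0]:
            raise ValueError("slice range must be non-empty")


@dataclass
class PolarMap:
    """Ring x sector polar map; ring 0 is the apex."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (rings, sectors)")
        if np.any(self.values < 0):
            raise ValueError("sector values must be nonnegative")

    @property
    def rings(self) -> int:
        return self.values.shape[0]

    @property
    def sectors(self) -> int:
        return self.values.shape[1]

    @property
    def mean_counts(self) -> float:
        """The output function Cmyo: mean over all ring x sector values."""
        return float(self.values.mean())

    @property
    def total_counts(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class CalibrationModel:
    """2D-3D count-conversion factor CF and its supporting regression."""

    cf: float
    r: float
    n: int

    def __post_init__(self):
        if self.cf <= 0:
            raise InvalidCalibration("conversion factor must be positive")
        if self.n < 3:
            raise TooFewPairs("calibration needs at least 3 pairs")


@dataclass(frozen=True)
class SpectQuantResult:
    mean_counts: float
    cf: float
    auc: float
    index: float
    virtual: bool = False


# --------------------------------------------------------------------------
# OSEM


def osem_reconstruct(
    projections: ProjectionSet,
    subsets: int = 4,
    iterations: int = 30,
    projector: Optional[ParallelProjector] = None,
    callback=None,
) -> ReconVolume:
    """Ordered-subsets EM reconstruction with the matched parallel pair.

    Views are interleaved into subsets (view v in subset v mod ``subsets``),
    the estimate starts uniform at one, voxels with zero sensitivity are
    held at zero, and the multiplicative update preserves nonnegativity by
    construction.  No scatter or attenuation correction is applied.
    """
    n_views = projections.views.shape[0]
    if n_views % subsets != 0:
        raise IndivisibleSubsets(f"{n_views} views not divisible by {subsets} subsets")
    n = projections.views.shape[2]
    nz = projections.views.shape[1]
    proj = projector or ParallelProjector.cached(n, projections.angles_deg)

    subset_views = [[v for v in range(n_views) if v % subsets == s] for s in range(subsets)]
    ones = np.ones((1, nz, n))
    sens = [
        proj.back(np.repeat(ones, len(vs), axis=0), view_idx=vs) for vs in subset_views
    ]

    x = np.ones((nz, n, n))
    for s in range(subsets):
        x[sens[s] <= _EPS] = 0.0
    measured = projections.views
    for it in range(iterations):
        for s in range(subsets):
            vs = subset_views[s]
            y = proj.forward(x, view_idx=vs)
            ratio = np.where(y > _EPS, measured[vs] / np.maximum(y, _EPS), 0.0)
            update = proj.back(ratio, view_idx=vs)
            pos = sens[s] > _EPS
            x[pos] *= update[pos] / sens[s][pos]
        if callback is not None:
            callback(it + 1, x)  # after each full iteration over all subsets
    return ReconVolume(x, voxel_mm=projections.voxel_mm, subsets=subsets, iterations=iterations)


# --------------------------------------------------------------------------
# short-axis reorientation


def _rotation_zyx(spin_deg: float, tilt_deg: float) -> np.ndarray:
    """Rotation taking the local long-axis frame to world, in (z, y, x)."""
    t = np.deg2rad(tilt_deg)
    s = np.deg2rad(spin_deg)
    ry = np.array([[np.cos(t), 0.0, -np.sin(t)], [0.0, 1.0, 0.0], [np.sin(t), 0.0, np.cos(t)]])
    rz = np.array([[1.0, 0.0, 0.0], [0.0, np.cos(s), np.sin(s)], [0.0, -np.sin(s), np.cos(s)]])
    return rz @ ry


def _estimate_axis(
    vol: np.ndarray,
    threshold_frac: float,
    search_halfwidth: Optional[int],
    search_center: Optional[tuple],
) -> tuple:
    """Intensity-weighted principal axis of the thresholded myocardium."""
    work = vol
    if search_center is not None and search_halfwidth is not None:
        lo = [max(0, int(round(c)) - search_halfwidth) for c in search_center]
        hi = [
            min(s, int(round(c)) + search_halfwidth + 1)
            for c, s in zip(search_center, vol.shape)
        ]
        box = np.zeros_like(vol)
        box[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = vol[
            lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]
        ]
        work = box
    if work.max() <= 0:
        raise AxisUndetermined("volume is empty")
    # robust maximum: hot noise voxels must not collapse the mask
    vmax = float(np.percentile(work[work > 0], 99.0))
    if vmax <= 0:
        vmax = float(work.max())
    mask = work >= threshold_frac * vmax
    labels, n_lab = ndimage.label(mask)
    if n_lab == 0:
        raise AxisUndetermined("thresholded myocardial mask is empty")
    sizes = ndimage.sum(mask, labels, range(1, n_lab + 1))
    mask = labels == (1 + int(np.argmax(sizes)))

    w = work[mask]
    coords = np.asarray(np.nonzero(mask), dtype=float)
    center = (coords * w).sum(axis=1) / w.sum()
    d = coords - center[:, None]
    cov = (d * w) @ d.T / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[-1] / max(evals[-2], 1e-12) < 1.1:
        raise AxisUndetermined("mask is isotropic; no long axis")
    u = evecs[:, -1]
    if u[0] < 0:
        u = -u
    tilt = float(np.rad2deg(np.arccos(np.clip(u[0], -1.0, 1.0))))
    spin = float(np.rad2deg(np.arctan2(u[1], u[2]))) if tilt > 1e-6 else 0.0
    # fold the axis sign so both angles sit in (-90, 90)
    if spin > 90.0:
        spin -= 180.0
        tilt = -tilt
    elif spin < -90.0:
        spin += 180.0
        tilt = -tilt
    return tuple(center), spin, tilt, mask


def reorient_short_axis(
    volume: ReconVolume,
    geometry: Optional[ShortAxisGeometry] = None,
    threshold_frac: float = 0.5,
    search_center: Optional[tuple] = None,
    search_halfwidth: Optional[int] = 18,
    template: Optional[ShortAxisGeometry] = None,
    min_slices: int = 10,
) -> tuple[np.ndarray, ShortAxisGeometry, bool]:
    """Resample the volume so short-axis slices are perpendicular to the
    myocardial long axis.

    If no geometry is given it is estimated as the principal axis of
    voxels above ``threshold_frac`` of the myocardial maximum (within a
    search box around the expected cardiac position).  If estimation fails
    and a ``template`` geometry is supplied, the template is used and the
    virtual flag is returned true; with no template,
    :class:`AxisUndetermined` propagates.

    Returns ``(short_axis_volume, geometry, virtual)``; interpolation is
    trilinear on an isotropic grid at the original voxel size.
    """
    vol = volume.counts
    virtual = False
    myo_mask = None
    if geometry is None:
        if search_center is None:
            search_center = tuple((s - 1) / 2.0 for s in vol.shape)
        try:
            center, spin, tilt, myo_mask = _estimate_axis(
                vol, threshold_frac, search_halfwidth, search_center
            )
        except AxisUndetermined:
            if template is None:
                raise
            geometry = template
            virtual = True
        else:
            geometry = ShortAxisGeometry(center=center, spin_deg=spin, tilt_deg=tilt)

    rot = _rotation_zyx(geometry.spin_deg, geometry.tilt_deg)
    c = np.asarray(geometry.center)
    sa = ndimage.affine_transform(
        vol, rot, offset=c - rot @ c, order=1, mode="constant", cval=0.0
    )
    sa = np.clip(sa, 0.0, None)

    if geometry.slice_range == (0, 0):
        if myo_mask is not None:
            # apex-to-base extent of the estimated myocardium itself, so
            # bright extra-cardiac structures cannot stretch the range
            prof = ndimage.affine_transform(
                myo_mask.astype(float), rot, offset=c - rot @ c, order=1,
                mode="constant", cval=0.0,
            ).max(axis=(1, 2))
        else:
            prof = sa.max(axis=(1, 2))
        above = np.nonzero(prof >= 0.5 * prof.max())[0] if prof.max() > 0 else []
        if len(above):
            z0, z1 = int(above[0]), int(above[-1])
            # polar-map construction needs at least min_slices slices
            while z1 - z0 + 1 < min_slices and (z0 > 0 or z1 < vol.shape[0] - 1):
                if z0 > 0:
                    z0 -= 1
                if z1 < vol.shape[0] - 1 and z1 - z0 + 1 < min_slices:
                    z1 += 1
            geometry = ShortAxisGeometry(
                center=geometry.center,
                spin_deg=geometry.spin_deg,
                tilt_deg=geometry.tilt_deg,
                slice_range=(z0, z1),
            )
    return sa, geometry, virtual


# --------------------------------------------------------------------------
# polar map


def build_polar_map(
    sa_volume: np.ndarray,
    geometry: ShortAxisGeometry,
    rings: int = 10,
    sectors: int = 36,
) -> PolarMap:
    """Ring x sector bull's-eye map of a short-axis volume.

    Apex-to-base slices of the slice range are split into ``rings``
    contiguous groups (slice-averaged).  For each ring and angular sector,
    counts are sampled along the radial ray at 1-voxel steps from the
    myocardial center; the sector value is the maximum over radius of the
    running mean of three consecutive samples.
    """
    sa_volume = np.asarray(sa_volume, dtype=float)
    z0, z1 = geometry.slice_range
    n_slices = z1 - z0 + 1
    if n_slices < rings:
        raise ValueError(f"slice range covers {n_slices} slices < {rings} rings")
    groups = np.array_split(np.arange(z0, z1 + 1), rings)

    ny, nx = sa_volume.shape[1:]
    cy, cx = geometry.center[1], geometry.center[2]
    r_max = int(max(ny, nx) // 2)
    radii = np.arange(0, r_max + 1, 1.0)
    theta = (np.arange(sectors) + 0.5) * 2.0 * np.pi / sectors

    values = np.zeros((rings, sectors))
    for ri, grp in enumerate(groups):
        sl = sa_volume[grp].mean(axis=0)
        for si, th in enumerate(theta):
            ys = cy + radii * np.sin(th)
            xs = cx + radii * np.cos(th)
            ok = (ys >= 0) & (ys <= ny - 1) & (xs >= 0) & (xs <= nx - 1)
            if not ok.any():
                raise EmptySlice(f"ring {ri} sector {si}: all samples off-grid")
            samples = ndimage.map_coordinates(
                sl, np.vstack([ys[ok], xs[ok]]), order=1, mode="constant", cval=0.0
            )
            if len(samples) >= 3:
                run = np.convolve(samples, np.ones(3) / 3.0, mode="valid")
            else:
                run = np.array([samples.mean()])
            values[ri, si] = run.max()
    return PolarMap(values)


# --------------------------------------------------------------------------
# calibration and index


def calibrate_cf(planar_counts, spect_counts, through_origin: bool = True) -> CalibrationModel:
    """Estimate the 2D-3D conversion factor CF by least squares.

    CF is the slope of SPECT polar-map counts on planar heart counts,
    through the origin by default (proportionality is the model's
    premise); ``r`` is the Pearson correlation of the pairs.
    """
    x = np.asarray(planar_counts, dtype=float)
    y = np.asarray(spect_counts, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("count lists must be 1D and of equal length")
    if len(x) < 3:
        raise TooFewPairs(f"need at least 3 pairs, got {len(x)}")
    if np.all(x == 0):
        raise DegenerateX("all planar counts are zero")
    if through_origin:
        cf = float((x * y).sum() / (x * x).sum())
    else:
        cf = float(np.polyfit(x, y, 1)[0])
    r = float(np.corrcoef(x, y)[0, 1]) if np.std(x) > 0 and np.std(y) > 0 else 1.0
    return CalibrationModel(cf=cf, r=r, n=len(x))


def spect_uptake_index(
    polar_map: PolarMap,
    calibration: CalibrationModel,
    input_auc: float,
    scale: float = 1.0,
    mode: str = "mean",
    virtual: bool = False,
) -> SpectQuantResult:
    """SPECT uptake index: Cmyo / (CF * AUC), scaled.

    Dividing the polar-map counts by CF brings them onto the planar count
    scale before normalization by the input function, which makes the
    index invariant under a global rescaling of one subject's activity.
    """
    if input_auc <= 0:
        raise ZeroAuc("input-function AUC must be positive")
    if calibration.cf <= 0:
        raise InvalidCalibration("conversion factor must be positive")
    cmyo = polar_map.mean_counts if mode == "mean" else polar_map.total_counts
    index = scale * cmyo / (calibration.cf * input_auc)
    return SpectQuantResult(
        mean_counts=cmyo, cf=calibration.cf, auc=float(input_auc),
        index=float(index), virtual=virtual,
    )
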