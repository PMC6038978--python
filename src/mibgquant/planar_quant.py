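"""Conventional planar quantification: heart-to-mediastinum ratio and the
planar uptake index from the 5-min static chest image.

Both metrics share one heart ROI.  The heart ROI is detected as the
smoothed cardiac uptake blob in the left-mid chest; when the heart
contrast over body background falls below a gate (the low-uptake
situation), a fixed-size template ROI is placed at the default anatomical
position instead and the result is flagged *virtual*.  The mediastinal
reference is a fixed upper-midline rectangle.

    H/M   = heart mean counts/pixel / mediastinum mean counts/pixel
    index = scale * heart mean counts/pixel / AUC

with AUC the first-pass input function of the same subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import RoiOutOfBounds, ZeroAuc, ZeroMediastinum
from .phantom import PlanarImage, Rect2D

__all__ = [
    "HeartRoi",
    "PlanarRoiSet",
    "PlanarQuantResult",
    "place_heart_roi",
    "hm_ratio",
    "planar_uptake_index",
]


@dataclass(frozen=True)
class HeartRoi:
    """Circular heart ROI in pixel coordinates."""

    center: tuple[float, float]
    radius: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        r0, c0 = self.center
        if (
            r0 - self.radius < -0.5
            or c0 - self.radius < -0.5
            or r0 + self.radius > shape[0] - 0.5
            or c0 + self.radius > shape[1] - 0.5
        ):
            raise RoiOutOfBounds("heart ROI exceeds the image")
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius**2


@dataclass(frozen=True)
class PlanarRoiSet:
    """Heart and mediastinum ROIs; ``virtual`` marks a template-placed heart."""

    heart: HeartRoi
    mediastinum: Rect2D
    virtual: bool = False

    def validate(self, shape: tuple[int, int]) -> None:
        hm = self.heart.mask(shape)
        mm = self.mediastinum.mask(shape)
        if self.mediastinum.r0 < 0 or self.mediastinum.r1 > shape[0] or \
           self.mediastinum.c0 < 0 or self.mediastinum.c1 > shape[1]:
            raise RoiOutOfBounds("mediastinum ROI exceeds the image")
        if (hm & mm).any():
            raise ValueError("heart and mediastinum ROIs overlap")


@dataclass(frozen=True)
class PlanarQuantResult:
    heart_mean: float
    mediastinum_mean: float
    hm: float
    index: Optional[float] = None
    virtual: bool = False


# default anatomical template for a 256x256 chest image
_DEFAULT_HEART = HeartRoi(center=(140.0, 155.0), radius=20.0)
_DEFAULT_MEDIASTINUM = Rect2D(50, 76, 120, 136)


def _scale_roi(shape, heart: HeartRoi, med: Rect2D) -> tuple[HeartRoi, Rect2D]:
    fr, fc = shape[0] / 256.0, shape[1] / 256.0
    f = min(fr, fc)
    return (
        HeartRoi((heart.center[0] * fr, heart.center[1] * fc), heart.radius * f),
        Rect2D(
            int(round(med.r0 * fr)), int(round(med.r1 * fr)),
            int(round(med.c0 * fc)), int(round(med.c1 * fc)),
        ),
    )


def place_heart_roi(
    image: PlanarImage,
    template: Optional[PlanarRoiSet] = None,
    contrast_gate: float = 1.5,
    search_window: tuple[float, float, float, float] = (0.40, 0.68, 0.45, 0.85),
    smooth_sigma: float = 3.0,
) -> PlanarRoiSet:
    """Place heart and mediastinum ROIs on the static planar image.

    The cardiac blob is the intensity-weighted centroid of pixels above
    50% of the smoothed local maximum inside the left-mid-chest search
    window (fractions of image height/width).  If the candidate ROI's mean
    is below ``contrast_gate`` times the local background (median of
    positive pixels in the surrounding annulus), the template ROI at the
    default anatomical position is used and the virtual flag set — the
    low-uptake situation.  The fallback always succeeds.
    """
    img = image.counts
    h, w = img.shape
    if template is None:
        heart_t, med_t = _scale_roi(img.shape, _DEFAULT_HEART, _DEFAULT_MEDIASTINUM)
        template = PlanarRoiSet(heart=heart_t, mediastinum=med_t, virtual=True)

    sm = ndimage.gaussian_filter(img, smooth_sigma)
    r0, r1 = int(search_window[0] * h), int(search_window[1] * h)
    c0, c1 = int(search_window[2] * w), int(search_window[3] * w)
    win = sm[r0:r1, c0:c1]

    virtual = True
    heart = template.heart
    if win.size and win.max() > 0:
        blob = win >= 0.5 * win.max()
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        wgt = np.where(blob, win, 0.0)
        center = (
            float((rr * wgt).sum() / wgt.sum()),
            float((cc * wgt).sum() / wgt.sum()),
        )
        cand = HeartRoi(center=center, radius=template.heart.radius)
        try:
            m = cand.mask(img.shape)
        except RoiOutOfBounds:
            m = None
        if m is not None:
            inside = float(img[m].mean())
            rr2, cc2 = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
            d2 = (rr2 - center[0]) ** 2 + (cc2 - center[1]) ** 2
            annulus = (d2 > (1.2 * cand.radius) ** 2) & (d2 <= (2.0 * cand.radius) ** 2)
            ring = img[annulus]
            ring = ring[ring > 0]
            background = float(np.median(ring)) if ring.size else 0.0
            if background > 0 and inside >= contrast_gate * background:
                heart = cand
                virtual = False
    return PlanarRoiSet(heart=heart, mediastinum=template.mediastinum, virtual=virtual)


def hm_ratio(image: PlanarImage, rois: PlanarRoiSet) -> float:
    """Heart-to-mediastinum ratio of mean counts per pixel."""
    heart_mean = float(image.counts[rois.heart.mask(image.counts.shape)].mean())
    med_mean = float(image.counts[rois.mediastinum.mask(image.counts.shape)].mean())
    if med_mean == 0:
        raise ZeroMediastinum("mediastinal mean counts are zero")
    return heart_mean / med_mean


def planar_uptake_index(
    image: PlanarImage,
    rois: PlanarRoiSet,
    input_auc: float,
    scale: float = 1000.0,
) -> PlanarQuantResult:
    """Planar uptake index: heart mean counts/pixel over the input AUC.

    The scale is a fixed convention (unit conversion constants cancel in
    any within-study comparison); the default 1000 puts phantom indices in
    the low single digits.
    """
    if input_auc <= 0:
        raise ZeroAuc("input-function AUC must be positive")
    shape = image.counts.shape
    heart_mean = float(image.counts[rois.heart.mask(shape)].mean())
    med_mask = rois.mediastinum.mask(shape)
    med_mean = float(image.counts[med_mask].mean()) if med_mask.any() else 0.0
    return PlanarQuantResult(
        heart_mean=heart_mean,
        mediastinum_mean=med_mean,
        hm=heart_mean / med_mean if med_mean > 0 else float("nan"),
        index=scale * heart_mean / input_auc,
        virtual=rois.virtual,
    )
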