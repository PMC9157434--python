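"""Automated footpad-dermatitis (FPD) scoring of single poultry-foot images.

The pipeline mirrors an industrial camera system: the foot is segmented by
contrasting it against a blue background, the metatarsal footpad is located
as the largest inscribed circle of the (morphologically opened) foot mask,
dark lesions are detected inside the footpad, and the lesion/footpad area
ratio is mapped onto the 5-level Hocking severity scale.

Two detection variants are provided: ``AUT1`` (single darkness threshold)
and ``AUT2`` (two intensity strata plus shape-based pseudo-lesion
rejection).

Conventions: row-major 0-based coordinates, origin top-left. Masks are
boolean ``H x W`` numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .errors import (
    DegenerateFootpad,
    FootpadNotFound,
    FpdError,
    InvalidThresholds,
    NoFootDetected,
)

Algorithm = Literal["AUT1", "AUT2"]

#: reference image width at which ``min_lesion_px`` is calibrated
REFERENCE_WIDTH = 512


@dataclass(frozen=True)
class RgbImage:
    """An 8-bit RGB raster of a single foot.

    Parameters
    ----------
    pixels : ndarray
        ``H x W x 3`` uint8 array, ``H, W >= 64``.
    id : str
        Opaque identifier carried through to output records.
    laterality : {"left", "right", "unknown"}
    """

    pixels: np.ndarray
    id: str = ""
    laterality: str = "unknown"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] < 3:
            raise ValueError("pixels must be H x W x 3")
        if px.shape[2] > 3:  # drop alpha with a warning
            import warnings

            warnings.warn("alpha channel ignored", stacklevel=2)
            px = px[:, :, :3]
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("image must be at least 64 x 64")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.laterality not in ("left", "right", "unknown"):
            raise ValueError(f"bad laterality {self.laterality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class FootpadRegion:
    """Largest inscribed circle of the opened foot mask.

    ``mask`` is the filled circle intersected with the foot mask;
    ``area_px`` is its true-pixel count.
    """

    center: tuple[int, int]
    radius: float
    mask: np.ndarray
    area_px: int


@dataclass(frozen=True)
class LesionComponent:
    mask: np.ndarray
    stratum: str  # "dark" or "intermediate"; AUT1 uses "dark" only
    area_px: int
    elongation: float
    boundary_contact: float


@dataclass(frozen=True)
class LesionSegmentation:
    mask: np.ndarray
    components: tuple[LesionComponent, ...]
    total_area_px: int


@dataclass(frozen=True)
class ScoreThresholds:
    """Area-ratio class boundaries of the 5-level severity scale.

    Classes are half-open: ``[0, t1) -> 1``, ``[t1, t2) -> 2``,
    ``[t2, t3) -> 3``, ``[t3, 1] -> 4``; level 0 is reserved for feet
    without any surviving lesion component.
    """

    t1: float = 0.10
    t2: float = 0.25
    t3: float = 0.50
    min_lesion_px: int = 9

    def validate(self) -> None:
        if not (0.0 < self.t1 < self.t2 < self.t3 < 1.0):
            raise InvalidThresholds(
                f"need 0 < t1 < t2 < t3 < 1, got {self.t1}, {self.t2}, {self.t3}"
            )


@dataclass(frozen=True)
class FpdScore:
    level: int
    ratio: float
    algorithm: str = "AUT1"


@dataclass(frozen=True)
class ColorConfig:
    """Color-model parameters for segmentation and lesion detection.

    ``background_hue_window`` is in degrees on the 0-360 hue circle;
    the darkness factors are fractions of a reference luminance, taken as
    the ``reference_quantile`` quantile of footpad luminance.  A median
    reference (q = 0.5) cannot detect lesions covering the majority of the
    pad, so the default is the upper quartile.
    """

    background_hue_window: tuple[float, float] = (180.0, 300.0)
    min_saturation: float = 0.25
    reference_quantile: float = 0.75
    k: float = 0.60
    k_dark: float = 0.45
    k_intermediate: float = 0.65
    max_elongation: float = 6.0
    max_boundary_contact: float = 0.5
    boundary_annulus_px: int = 3

    def validate(self) -> None:
        if not (0.0 < self.k_dark < self.k_intermediate < 1.0):
            raise ValueError("need 0 < k_dark < k_intermediate < 1")


@dataclass(frozen=True)
class FootRecord:
    """One scored (or unscorable) foot; QC errors are flags, not exceptions."""

    foot_id: str
    laterality: str
    algorithm: str
    level: Optional[int]
    ratio: Optional[float]
    footpad_area_px: Optional[int]
    lesion_area_px: Optional[int]
    qc_flag: str = "OK"
    footpad: Optional[FootpadRegion] = field(default=None, repr=False, compare=False)
    lesions: Optional[LesionSegmentation] = field(default=None, repr=False, compare=False)

    @property
    def scorable(self) -> bool:
        return self.qc_flag == "OK"


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def background_mask(image: RgbImage, color: ColorConfig) -> np.ndarray:
    """Pixels that belong to the blue backdrop (hue window + saturation)."""
    hsv = skcolor.rgb2hsv(image.pixels)
    hue_deg = hsv[:, :, 0] * 360.0
    lo, hi = color.background_hue_window
    if lo <= hi:
        in_window = (hue_deg >= lo) & (hue_deg <= hi)
    else:  # window wrapping through 0 degrees
        in_window = (hue_deg >= lo) | (hue_deg <= hi)
    return in_window & (hsv[:, :, 1] >= color.min_saturation)


def segment_foot(image: RgbImage, color: ColorConfig = ColorConfig()) -> np.ndarray:
    """Segment the foot as the largest hole-filled non-background component.

    Raises
    ------
    NoFootDetected
        If no connected component reaches 1% of the image area.
    """
    fg = ~background_mask(image, color)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise NoFootDetected("no non-background pixels")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < 0.01 * fg.size:
        raise NoFootDetected(
            f"largest component {int(sizes[best - 1])} px < 1% of image area"
        )
    return ndimage.binary_fill_holes(labels == best)


def locate_footpad(
    foot: np.ndarray, opening_radius_frac: float = 0.02
) -> FootpadRegion:
    """Locate the metatarsal footpad as the largest inscribed circle.

    A morphological opening (disc of radius ``opening_radius_frac * W``,
    minimum 1 px) suppresses toe strips; the circle is centred at the
    argmax of the Euclidean distance transform of the opened mask (ties
    broken row-major), with radius equal to the maximum distance.

    Raises
    ------
    FootpadNotFound
        If the opened mask is empty.
    """
    foot = np.asarray(foot, bool)
    if not foot.any():
        raise FootpadNotFound("foot mask is empty")
    w = foot.shape[1]
    r_open = max(1, round(opening_radius_frac * w))
    opened = skmorph.opening(foot, skmorph.disk(r_open))
    if not opened.any():
        raise FootpadNotFound("opened mask is empty")
    dist = ndimage.distance_transform_edt(opened)
    flat_idx = int(np.argmax(dist))  # first maximum in row-major order
    center = np.unravel_index(flat_idx, dist.shape)
    radius = float(dist[center])
    circle = circle_mask(foot.shape, center, radius)
    mask = circle & foot
    return FootpadRegion(
        center=(int(center[0]), int(center[1])),
        radius=radius,
        mask=mask,
        area_px=int(mask.sum()),
    )


def circle_mask(
    shape: tuple[int, int], center: Sequence[int], radius: float
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _luminance(image: RgbImage) -> np.ndarray:
    return skcolor.rgb2gray(image.pixels)


def scaled_min_lesion_px(width: int, min_lesion_px: int) -> int:
    """Minimum component area, scaled quadratically from the 512-px reference."""
    return max(1, round(min_lesion_px * (width / REFERENCE_WIDTH) ** 2))


def _components(
    mask: np.ndarray, stratum: str, footpad: FootpadRegion, annulus_px: int
) -> list[LesionComponent]:
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    # inner annulus of the footpad circle, used for boundary-contact
    rr, cc = np.ogrid[: mask.shape[0], : mask.shape[1]]
    d2 = (rr - footpad.center[0]) ** 2 + (cc - footpad.center[1]) ** 2
    annulus = footpad.mask & (d2 >= (footpad.radius - annulus_px) ** 2)
    out = []
    for region in skmeasure.regionprops(labels):
        comp = labels == region.label
        area = int(region.area)
        minor = region.axis_minor_length
        major = region.axis_major_length
        elong = float("inf") if minor < 1e-9 else float(major / minor)
        contact = float((comp & annulus).sum() / area)
        out.append(LesionComponent(comp, stratum, area, elong, contact))
    return out


def detect_lesions(
    image: RgbImage,
    footpad: FootpadRegion,
    color: ColorConfig = ColorConfig(),
    algorithm: Algorithm = "AUT1",
    min_lesion_px: int = 9,
) -> LesionSegmentation:
    """Detect dark lesion regions inside the footpad.

    ``AUT1`` keeps every component darker than ``k x median`` footpad
    luminance (subject to the minimum-area floor). ``AUT2`` splits
    candidates into a dark and an intermediate stratum; intermediate
    components are additionally rejected when too elongated or hugging
    the footpad boundary (pseudo-lesion filters).
    """
    color.validate()
    lum = _luminance(image)
    pad = footpad.mask
    if not pad.any():
        return LesionSegmentation(np.zeros_like(pad), (), 0)
    ref = float(np.quantile(lum[pad], color.reference_quantile))
    min_px = scaled_min_lesion_px(image.shape[1], min_lesion_px)

    comps: list[LesionComponent] = []
    if algorithm == "AUT1":
        cand = pad & (lum < color.k * ref)
        comps = [
            c
            for c in _components(cand, "dark", footpad, color.boundary_annulus_px)
            if c.area_px >= min_px
        ]
    elif algorithm == "AUT2":
        dark = pad & (lum < color.k_dark * ref)
        inter = pad & (lum >= color.k_dark * ref) & (lum < color.k_intermediate * ref)
        comps = [
            c
            for c in _components(dark, "dark", footpad, color.boundary_annulus_px)
            if c.area_px >= min_px
        ]
        for c in _components(inter, "intermediate", footpad, color.boundary_annulus_px):
            if c.area_px < min_px:
                continue
            if c.elongation > color.max_elongation:
                continue
            if c.boundary_contact > color.max_boundary_contact:
                continue
            comps.append(c)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    if comps:
        mask = np.logical_or.reduce([c.mask for c in comps])
    else:
        mask = np.zeros_like(pad)
    return LesionSegmentation(mask, tuple(comps), int(sum(c.area_px for c in comps)))


def compute_area_ratio(lesions: LesionSegmentation, footpad: FootpadRegion) -> float:
    """Lesion area divided by footpad area, clamped to [0, 1]."""
    if footpad.area_px == 0:
        raise DegenerateFootpad("footpad has zero area")
    return float(min(1.0, max(0.0, lesions.total_area_px / footpad.area_px)))


def classify_score(
    ratio: float,
    has_lesion: bool,
    thresholds: ScoreThresholds = ScoreThresholds(),
    algorithm: str = "AUT1",
) -> FpdScore:
    """Map an area ratio onto the 5-level severity scale (half-open classes)."""
    thresholds.validate()
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio {ratio} outside [0, 1]")
    if not has_lesion:
        level = 0
    elif ratio < thresholds.t1:
        level = 1
    elif ratio < thresholds.t2:
        level = 2
    elif ratio < thresholds.t3:
        level = 3
    else:
        level = 4
    return FpdScore(level=level, ratio=ratio, algorithm=algorithm)


@dataclass(frozen=True)
class PipelineConfig:
    color: ColorConfig = ColorConfig()
    thresholds: ScoreThresholds = ScoreThresholds()
    algorithm: Algorithm = "AUT1"
    opening_radius_frac: float = 0.02


def score_image(image: RgbImage, config: PipelineConfig = PipelineConfig()) -> FootRecord:
    """Run the full pipeline on one image; never raises.

    Stage failures (no foot, no footpad, ...) are embedded as the QC flag
    of an unscorable record so exclusion counts remain auditable.
    """
    try:
        foot = segment_foot(image, config.color)
        footpad = locate_footpad(foot, config.opening_radius_frac)
        lesions = detect_lesions(
            image,
            footpad,
            config.color,
            config.algorithm,
            config.thresholds.min_lesion_px,
        )
        ratio = compute_area_ratio(lesions, footpad)
        score = classify_score(
            ratio, lesions.total_area_px > 0, config.thresholds, config.algorithm
        )
    except FpdError as exc:
        return FootRecord(
            foot_id=image.id,
            laterality=image.laterality,
            algorithm=config.algorithm,
            level=None,
            ratio=None,
            footpad_area_px=None,
            lesion_area_px=None,
            qc_flag=type(exc).__name__,
        )
    return FootRecord(
        foot_id=image.id,
        laterality=image.laterality,
        algorithm=config.algorithm,
        level=score.level,
        ratio=score.ratio,
        footpad_area_px=footpad.area_px,
        lesion_area_px=lesions.total_area_px,
        qc_flag="OK",
        footpad=footpad,
        lesions=lesions,
    )


def select_foot(
    pair: tuple[Optional[FootRecord], Optional[FootRecord]],
    policy: Literal["left_default", "both"] = "left_default",
) -> FootRecord | tuple[FootRecord, ...]:
    """Choose which foot of a pair is reported.

    The default slaughter-line policy scores the left foot, switching to
    the right when the left is unscorable; ``"both"`` returns every
    present record (the experimental design).
    """
    left, right = pair
    if left is None and right is None:
        raise ValueError("at least one record must be present")
    if policy == "both":
        return tuple(r for r in (left, right) if r is not None)
    if left is not None and left.scorable:
        return left
    if right is not None and right.scorable:
        return right
    # neither scorable: report the pair as unscorable (prefer the left slot)
    fallback = left if left is not None else right
    assert fallback is not None
    return replace(fallback, qc_flag=fallback.qc_flag or "UnscorablePair")
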