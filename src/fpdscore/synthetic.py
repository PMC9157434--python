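"""Seeded synthetic foot-image generator with full ground truth.

Renders a stylised poultry foot on a blue backdrop: a circular metatarsal
pad, three tapering toe strips built from phalange segments, and an
irregular dark lesion grown to a requested area fraction of the pad.
Presentation skew is modelled as a horizontal compression by ``cos(angle)``
and laterality as a horizontal mirror, so masks stay analytically exact
(no interpolation).  Everything is deterministic under a fixed seed, and
per-foot seeds in a flock are derived by counter-based splitting so
generation is order-independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleSpec
from .imaging import RgbImage, ScoreThresholds, classify_score

#: degree ranges sampled for each presentation-angle class; kept clear of
#: the 10 / 25 degree audit bin edges so class labels are unambiguous
ANGLE_CLASS_RANGES = ((0.0, 8.0), (12.0, 23.0), (28.0, 50.0))

#: per-level target-ratio sampling windows, inset from the 10/25/50%
#: class boundaries so rendering error cannot flip the class
LEVEL_RATIO_WINDOWS = {
    1: (0.015, 0.085),
    2: (0.120, 0.230),
    3: (0.280, 0.460),
    4: (0.530, 0.660),
}

#: level marginals of the human scoring of the post-modification dataset
DEFAULT_LEVEL_MARGINALS = (0.0167, 0.1096, 0.6602, 0.1932, 0.0203)

#: probability that a foot presents straight, by laterality
DEFAULT_STRAIGHT_PROB = {"left": 0.424, "right": 0.772}

#: of the skewed feet, fraction falling in the strongly-skewed class
DEFAULT_STRONG_SKEW_FRAC = 0.12


@dataclass(frozen=True)
class FootColors:
    """RGB palette; luminances are tuned against the detector defaults."""

    background: tuple[int, int, int] = (40, 80, 180)
    skin: tuple[int, int, int] = (205, 170, 150)
    lesion: tuple[int, int, int] = (75, 62, 55)
    penumbra: tuple[int, int, int] = (125, 106, 95)
    artifact: tuple[int, int, int] = (105, 89, 80)


@dataclass(frozen=True)
class SyntheticFootSpec:
    """Recipe for one synthetic foot.

    Exactly one of ``target_level`` / ``target_ratio`` drives the lesion
    size (``target_level=0`` or ``target_ratio=0`` means no lesion); the
    skew is given either as a class (degrees drawn from the class range)
    or explicitly in degrees.
    """

    target_level: Optional[int] = None
    target_ratio: Optional[float] = None
    angle_class: Optional[int] = None
    skew_deg: Optional[float] = None
    laterality: str = "left"
    size: tuple[int, int] = (256, 256)
    noise_sigma: float = 0.0
    penumbra_px: int = 0
    boundary_artifact: bool = False
    n_lesion_blobs: Optional[int] = None
    colors: FootColors = field(default_factory=FootColors)
    seed: int = 0

    def validate(self) -> None:
        if self.target_ratio is not None and not 0.0 <= self.target_ratio <= 1.0:
            raise InfeasibleSpec(f"target_ratio {self.target_ratio} outside [0, 1]")
        if self.target_level is not None and self.target_level not in range(5):
            raise InfeasibleSpec(f"target_level {self.target_level} outside 0..4")
        if self.skew_deg is not None and not 0.0 <= self.skew_deg <= 60.0:
            raise InfeasibleSpec("skew angle must lie in [0, 60] degrees")
        if self.angle_class is not None and self.angle_class not in (0, 1, 2):
            raise InfeasibleSpec("angle_class must be 0, 1 or 2")
        if self.laterality not in ("left", "right"):
            raise InfeasibleSpec(f"bad laterality {self.laterality!r}")
        if min(self.size) < 64:
            raise InfeasibleSpec("canvas must be at least 64 x 64")


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth for one rendered foot."""

    foot_mask: np.ndarray
    footpad_mask: np.ndarray
    toe_segment_masks: tuple[np.ndarray, ...]
    lesion_mask: np.ndarray
    true_ratio: float
    true_level: int
    skew_deg: float
    laterality: str


def angle_class_of(skew_deg: float, bins: tuple[float, float] = (10.0, 25.0)) -> int:
    if skew_deg < bins[0]:
        return 0
    if skew_deg <= bins[1]:
        return 1
    return 2


# ---------------------------------------------------------------------------
# geometry helpers (all evaluated in canonical, pre-skew coordinates)
# ---------------------------------------------------------------------------


def _canonical_grid(
    size: tuple[int, int], skew_deg: float, laterality: str
) -> tuple[np.ndarray, np.ndarray]:
    """Map rendered pixel centres back to canonical coordinates.

    Skew compresses columns toward the pad axis by cos(angle); a right
    foot is the mirror image of the canonical (left) foot.
    """
    h, w = size
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    if laterality == "right":
        cols = (w - 1) - cols
    cx = (w - 1) / 2.0
    cos_t = math.cos(math.radians(skew_deg))
    return rows, cx + (cols - cx) / cos_t


def _ellipse(
    y: np.ndarray,
    x: np.ndarray,
    center: tuple[float, float],
    axis_deg: float,
    semi_major: float,
    semi_minor: float,
) -> np.ndarray:
    dy = y - center[0]
    dx = x - center[1]
    a = math.radians(axis_deg)
    u = dx * math.sin(a) - dy * math.cos(a)  # along the toe axis
    v = dx * math.cos(a) + dy * math.sin(a)
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def _disc(y, x, center, radius):
    return (y - center[0]) ** 2 + (x - center[1]) ** 2 <= radius**2


def generate_foot(spec: SyntheticFootSpec) -> tuple[RgbImage, GroundTruth]:
    """Render one foot and its ground truth (deterministic under the seed)."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    h, w = spec.size

    # resolve skew
    if spec.skew_deg is not None:
        skew = float(spec.skew_deg)
    elif spec.angle_class is not None:
        lo, hi = ANGLE_CLASS_RANGES[spec.angle_class]
        skew = float(rng.uniform(lo, hi))
    else:
        skew = 0.0

    # resolve target lesion area fraction
    if spec.target_ratio is not None:
        target = float(spec.target_ratio)
    elif spec.target_level is not None:
        if spec.target_level == 0:
            target = 0.0
        else:
            lo, hi = LEVEL_RATIO_WINDOWS[spec.target_level]
            target = float(rng.uniform(lo, hi))
    else:
        target = 0.0

    # canonical layout
    pad_r = 0.17 * min(h, w)
    pad_c = (0.60 * (h - 1), (w - 1) / 2.0)
    y, x = _canonical_grid(spec.size, skew, spec.laterality)

    pad = _disc(y, x, pad_c, pad_r)

    # three tapering toes fanning upward; deliberately asymmetric so
    # laterality is visible in the rendered geometry
    toe_angles = (-38.0, -4.0, 30.0)
    seg_lens = (0.42 * pad_r, 0.40 * pad_r, 0.36 * pad_r)
    seg_half_w = (0.13 * pad_r, 0.11 * pad_r, 0.085 * pad_r)
    toe_segments: list[np.ndarray] = []
    for ang in toe_angles:
        a = math.radians(ang)
        d = (-math.cos(a), math.sin(a))  # unit direction, pointing up-ish
        back = pad_r * 0.85  # chain start, safely inside the pad
        for j in range(3):
            semi = seg_lens[j] * 0.62
            pos = back + semi
            center = (pad_c[0] + d[0] * pos, pad_c[1] + d[1] * pos)
            seg = _ellipse(y, x, center, ang, semi, seg_half_w[j])
            toe_segments.append(seg)
            back = pos + semi - 3.0  # 3-px overlap keeps the chain connected

    toes = np.logical_or.reduce(toe_segments) if toe_segments else np.zeros_like(pad)
    foot = pad | toes

    lesion_core = np.zeros_like(pad)
    if target > 0.0:
        lesion_core = _grow_lesion(rng, y, x, pad, pad_c, pad_r, target, spec)

    lesion = lesion_core
    penumbra = np.zeros_like(pad)
    if spec.penumbra_px > 0 and lesion_core.any():
        from scipy import ndimage

        grown = ndimage.binary_dilation(
            lesion_core, structure=_disk_structure(spec.penumbra_px)
        )
        penumbra = grown & pad & ~lesion_core
        lesion = lesion_core | penumbra

    artifact = np.zeros_like(pad)
    if spec.boundary_artifact:
        d2 = (y - pad_c[0]) ** 2 + (x - pad_c[1]) ** 2
        band = (d2 <= (pad_r - 1.0) ** 2) & (d2 >= (pad_r - 3.2) ** 2)
        theta = np.arctan2(y - pad_c[0], x - pad_c[1])
        artifact = band & (theta > math.radians(20)) & (theta < math.radians(160))
        artifact &= ~lesion

    # paint
    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.colors.background
    img[foot] = spec.colors.skin
    img[penumbra] = spec.colors.penumbra
    img[lesion_core] = spec.colors.lesion
    img[artifact] = spec.colors.artifact
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma * 255.0, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    pad_px = int(pad.sum())
    if pad_px == 0:
        raise InfeasibleSpec("footpad does not fit on the canvas")
    true_ratio = float(lesion.sum() / pad_px)
    if target > 0 and abs(true_ratio - target) > 0.02:
        raise InfeasibleSpec(
            f"could not reach target ratio {target:.3f} (achieved {true_ratio:.3f})"
        )
    true_level = classify_score(
        true_ratio, bool(lesion.any()), ScoreThresholds()
    ).level

    image = RgbImage(
        pixels=pixels,
        id=f"synth-{spec.seed}-{spec.laterality}",
        laterality=spec.laterality,
    )
    truth = GroundTruth(
        foot_mask=foot,
        footpad_mask=pad,
        toe_segment_masks=tuple(toe_segments),
        lesion_mask=lesion,
        true_ratio=true_ratio,
        true_level=true_level,
        skew_deg=skew,
        laterality=spec.laterality,
    )
    return image, truth


def _disk_structure(r: int) -> np.ndarray:
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return yy**2 + xx**2 <= r**2


def _grow_lesion(
    rng: np.random.Generator,
    y: np.ndarray,
    x: np.ndarray,
    pad: np.ndarray,
    pad_c: tuple[float, float],
    pad_r: float,
    target: float,
    spec: SyntheticFootSpec,
) -> np.ndarray:
    """Union of discs inside the pad, scaled to hit the target area fraction.

    Small punctual blobs at low fractions, a single blob at high fractions;
    the common scale factor is found by bisection on the rendered area.
    """
    if spec.n_lesion_blobs is not None:
        n_blobs = spec.n_lesion_blobs
    else:
        n_blobs = 1 if target >= 0.2 else int(rng.integers(1, 5))
    offs_r = rng.uniform(0.0, 0.55 * pad_r, n_blobs)
    offs_t = rng.uniform(0.0, 2 * math.pi, n_blobs)
    centers = [
        (pad_c[0] + r_ * math.sin(t_), pad_c[1] + r_ * math.cos(t_))
        for r_, t_ in zip(offs_r, offs_t)
    ]
    base = rng.uniform(0.5, 1.0, n_blobs)
    pad_area = pad.sum()

    def area_frac(scale: float) -> tuple[float, np.ndarray]:
        m = np.zeros_like(pad)
        for c, b in zip(centers, base):
            m |= _disc(y, x, c, b * scale)
        m &= pad
        return float(m.sum() / pad_area), m

    lo, hi = 0.0, 3.0 * pad_r
    mask = np.zeros_like(pad)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        frac, mask = area_frac(mid)
        if abs(frac - target) < 0.003:
            return mask
        if frac < target:
            lo = mid
        else:
            hi = mid
    frac, mask = area_frac(0.5 * (lo + hi))
    return mask


# ---------------------------------------------------------------------------
# flock generation
# ---------------------------------------------------------------------------


def draw_flock_specs(
    n: int,
    level_marginals: Sequence[float] = DEFAULT_LEVEL_MARGINALS,
    straight_prob: dict[str, float] | None = None,
    strong_skew_frac: float = DEFAULT_STRONG_SKEW_FRAC,
    laterality_mix: float = 0.5,
    seed: int = 0,
    size: tuple[int, int] = (256, 256),
    noise_sigma: float = 0.0,
) -> list[SyntheticFootSpec]:
    """Draw per-foot specs i.i.d. from the stated marginals.

    ``laterality_mix`` is the probability of a right foot.  Per-foot
    randomness is split from the flock seed with per-index spawn keys,
    so spec ``i`` does not depend on how many feet precede it.
    """
    marg = np.asarray(level_marginals, float)
    if marg.shape != (5,) or (marg < 0).any() or abs(marg.sum() - 1.0) > 1e-6:
        raise ValueError("level_marginals must be 5 non-negative values summing to 1")
    if straight_prob is None:
        straight_prob = dict(DEFAULT_STRAIGHT_PROB)
    specs = []
    for i in range(n):
        r = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        lat = "right" if r.random() < laterality_mix else "left"
        level = int(r.choice(5, p=marg))
        if r.random() < straight_prob[lat]:
            ac = 0
        else:
            ac = 2 if r.random() < strong_skew_frac else 1
        specs.append(
            SyntheticFootSpec(
                target_level=level,
                angle_class=ac,
                laterality=lat,
                size=size,
                noise_sigma=noise_sigma,
                seed=int(r.integers(0, 2**62)),
            )
        )
    return specs


def generate_flock(
    n: int,
    level_marginals: Sequence[float] = DEFAULT_LEVEL_MARGINALS,
    straight_prob: dict[str, float] | None = None,
    strong_skew_frac: float = DEFAULT_STRONG_SKEW_FRAC,
    laterality_mix: float = 0.5,
    seed: int = 0,
    size: tuple[int, int] = (256, 256),
    noise_sigma: float = 0.0,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[RgbImage, GroundTruth]], pd.DataFrame]:
    """Generate a flock of feet plus a manifest.

    When ``out_dir`` is given, images are written as PNG, truth masks as
    bilevel PNGs, and the manifest as ``manifest.csv`` alongside them.
    """
    specs = draw_flock_specs(
        n,
        level_marginals,
        straight_prob,
        strong_skew_frac,
        laterality_mix,
        seed,
        size,
        noise_sigma,
    )
    feet = [generate_foot(s) for s in specs]
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, (img, truth) in enumerate(feet):
        path = ""
        if out is not None:
            from PIL import Image

            path = f"foot_{i:05d}.png"
            Image.fromarray(img.pixels).save(out / path)
            for name, mask in (
                ("foot", truth.foot_mask),
                ("footpad", truth.footpad_mask),
                ("lesion", truth.lesion_mask),
            ):
                Image.fromarray(mask.astype(np.uint8) * 255).convert("1").save(
                    out / f"foot_{i:05d}_{name}.png"
                )
        rows.append(
            {
                "foot_id": img.id,
                "image_path": path,
                "laterality": truth.laterality,
                "angle_class": angle_class_of(truth.skew_deg),
                "skew_deg": truth.skew_deg,
                "true_level": truth.true_level,
                "true_ratio": truth.true_ratio,
            }
        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "foot_id",
            "image_path",
            "laterality",
            "angle_class",
            "skew_deg",
            "true_level",
            "true_ratio",
        ],
    )
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    if n == 0:
        warnings.warn("empty flock requested", stacklevel=2)
    return feet, manifest
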