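"""Ground-truth-based audit of detection quality.

Grades, per foot, how well the footpad was localised (0-3), how well the
alteration area was estimated (0/1/3 - the alteration scale deliberately
has no level 2), and the presentation-angle class (0-2), and summarises
audit distributions per stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import MissingTruth
from .imaging import FootpadRegion, FootRecord
from .synthetic import GroundTruth, angle_class_of


@dataclass(frozen=True)
class AuditScores:
    footpad_score: int
    alteration_score: int
    angle_score: int

    def __post_init__(self) -> None:
        if self.footpad_score not in (0, 1, 2, 3):
            raise ValueError("footpad_score must be 0..3")
        if self.alteration_score not in (0, 1, 3):
            raise ValueError("alteration scale has levels 0, 1 and 3 only")
        if self.angle_score not in (0, 1, 2):
            raise ValueError("angle_score must be 0..2")


def _disk(r: int) -> np.ndarray:
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return yy**2 + xx**2 <= r**2


def audit_footpad(
    detected: FootpadRegion | np.ndarray,
    truth: GroundTruth,
    deficit_tol: float = 0.05,
    slack_px: int = 2,
) -> int:
    """Grade footpad localisation against the true pad mask.

    Excess is the detected area outside the (slack-dilated) true pad, in
    units of the mean toe-segment area; a detection with no meaningful
    excess but a relative area deficit beyond ``deficit_tol`` is graded 3
    (too small).
    """
    if truth.footpad_mask is None or not truth.toe_segment_masks:
        raise MissingTruth("audit needs the true footpad and toe-segment masks")
    mask = detected.mask if isinstance(detected, FootpadRegion) else np.asarray(detected, bool)
    true_pad = truth.footpad_mask
    dilated = ndimage.binary_dilation(true_pad, structure=_disk(slack_px))
    seg_area = float(np.mean([m.sum() for m in truth.toe_segment_masks]))
    excess = float((mask & ~dilated).sum()) / seg_area
    deficit = float((true_pad & ~mask).sum()) / max(1, int(true_pad.sum()))
    if excess >= 0.5:
        return 2
    if excess >= 0.1:
        return 1
    if deficit > deficit_tol:
        return 3
    return 0


def audit_alteration(
    detected_area: float, true_area: float, rel_tol: float = 0.15
) -> int:
    """Grade alteration-area estimation: 0 correct, 1 too big, 3 too small."""
    tol = rel_tol * max(true_area, 1.0)
    if abs(detected_area - true_area) <= tol:
        return 0
    return 1 if detected_area > true_area else 3


def audit_angle(skew_deg: float, bins: tuple[float, float] = (10.0, 25.0)) -> int:
    """Grade the presentation angle into straight / slightly skew / skew."""
    if skew_deg < 0:
        raise ValueError("skew angle must be non-negative")
    return angle_class_of(skew_deg, bins)


def audit_record(
    record: FootRecord,
    truth: GroundTruth,
    deficit_tol: float = 0.05,
    alteration_rel_tol: float = 0.15,
) -> Optional[AuditScores]:
    """Audit one scored foot; returns None for unscorable records."""
    if not record.scorable or record.footpad is None:
        return None
    return AuditScores(
        footpad_score=audit_footpad(record.footpad, truth, deficit_tol),
        alteration_score=audit_alteration(
            float(record.lesion_area_px or 0),
            float(truth.lesion_mask.sum()),
            alteration_rel_tol,
        ),
        angle_score=audit_angle(truth.skew_deg),
    )


def summarize_audit(
    records: Iterable[dict], stratify_by: str = "algorithm"
) -> pd.DataFrame:
    """Percentage of feet at each audit level, per stratum.

    ``records`` are dicts with ``footpad_score``, ``alteration_score``,
    ``angle_score`` and the stratifier columns (``algorithm``, ``angle``,
    ``laterality``, ...).  Empty strata are omitted with a warning.
    """
    df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("no audit records")
    if stratify_by not in df.columns:
        raise KeyError(f"no stratifier column {stratify_by!r}")
    out_rows = []
    for stratum, grp in df.groupby(stratify_by):
        if grp.empty:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"empty stratum {stratum!r} omitted", stacklevel=2)
            continue
        for param, levels in (
            ("footpad_score", (0, 1, 2, 3)),
            ("alteration_score", (0, 1, 3)),
            ("angle_score", (0, 1, 2)),
        ):
            counts = grp[param].value_counts()
            n = len(grp)
            for lev in levels:
                out_rows.append(
                    {
                        stratify_by: stratum,
                        "parameter": param,
                        "level": lev,
                        "pct": 100.0 * counts.get(lev, 0) / n,
                    }
                )
    return pd.DataFrame(out_rows)
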