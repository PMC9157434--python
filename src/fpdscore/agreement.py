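"""Agreement and performance statistics for ordinal severity ratings.

Implements Krippendorff's alpha (nominal / ordinal / interval difference
functions) from a coincidence matrix, with unit-resampling bootstrap
confidence intervals; one-vs-rest performance measures (sensitivity,
specificity, PPV, NPV, accuracy) with binomial standard errors; per-level
deviation summaries; and Landis-Koch verbal banding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import LevelOutOfRange

Metric = str  # "nominal" | "ordinal" | "interval"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, matching printed-table style."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K cross-tabulation of paired ratings (rows = axis_a)."""

    counts: np.ndarray
    axis_a: str = "A"
    axis_b: str = "B"
    levels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be square")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))
        if not self.levels:
            object.__setattr__(self, "levels", tuple(range(c.shape[0])))

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_margin(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_margin(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def percentages(self) -> np.ndarray:
        """Cell percentages of the grand total."""
        return 100.0 * self.counts / self.total

    def transposed(self) -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.counts.T, axis_a=self.axis_b, axis_b=self.axis_a, levels=self.levels
        )

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{self.axis_a} {v}" for v in self.levels]
        cols = [f"{self.axis_b} {v}" for v in self.levels]
        return pd.DataFrame(self.counts, index=idx, columns=cols)


def build_confusion(
    pairs: Iterable[tuple[int, int]],
    levels: Sequence[int] = (0, 1, 2, 3, 4),
    axis_a: str = "A",
    axis_b: str = "B",
) -> ConfusionMatrix:
    """Cross-tabulate equal-length paired scores onto the given level set."""
    index = {v: i for i, v in enumerate(levels)}
    counts = np.zeros((len(levels), len(levels)), dtype=np.int64)
    for a, b in pairs:
        if a not in index or b not in index:
            raise LevelOutOfRange(f"rating pair ({a}, {b}) outside levels {levels}")
        counts[index[a], index[b]] += 1
    return ConfusionMatrix(counts, axis_a=axis_a, axis_b=axis_b, levels=tuple(levels))


@dataclass(frozen=True)
class RatingsTable:
    """unit x rater ordinal ratings; missing values are None.

    Units with fewer than two non-missing values are not pairable and do
    not contribute to agreement.
    """

    units: tuple[str, ...]
    raters: tuple[str, ...]
    values: dict[tuple[str, str], int] = field(repr=False)

    @classmethod
    def from_long(cls, rows: Iterable[tuple[str, str, int]]) -> "RatingsTable":
        units: list[str] = []
        raters: list[str] = []
        values: dict[tuple[str, str], int] = {}
        for unit, rater, level in rows:
            if unit not in units:
                units.append(unit)
            if rater not in raters:
                raters.append(rater)
            values[(str(unit), str(rater))] = int(level)
        if len(raters) < 2:
            raise ValueError("need at least 2 raters")
        return cls(tuple(units), tuple(raters), values)

    @classmethod
    def from_csv(cls, path) -> "RatingsTable":
        df = pd.read_csv(path)
        required = {"unit_id", "rater_id", "level"}
        if not required.issubset(df.columns):
            raise ValueError(f"ratings CSV must have columns {sorted(required)}")
        return cls.from_long(
            (str(r.unit_id), str(r.rater_id), int(r.level)) for r in df.itertuples()
        )

    def unit_values(self) -> list[list[int]]:
        """Non-missing values per unit, keeping only pairable units."""
        out = []
        for u in self.units:
            vals = [
                self.values[(u, r)] for r in self.raters if (u, r) in self.values
            ]
            if len(vals) >= 2:
                out.append(vals)
        return out


@dataclass(frozen=True)
class AlphaResult:
    alpha: float
    metric: str
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_boot: int = 0
    seed: Optional[int] = None

    @property
    def landis_koch_label(self) -> str:
        return landis_koch_label(self.alpha) if math.isfinite(self.alpha) else "undefined"


# ---------------------------------------------------------------------------
# Krippendorff's alpha
# ---------------------------------------------------------------------------


def coincidence_from_confusion(confusion: ConfusionMatrix) -> np.ndarray:
    """Two-rater coincidence matrix: counts + counts-transposed."""
    c = confusion.counts.astype(float)
    return c + c.T


def coincidence_from_units(
    unit_values: list[list[int]], levels: Sequence[int]
) -> np.ndarray:
    index = {v: i for i, v in enumerate(levels)}
    k = len(levels)
    o = np.zeros((k, k))
    for vals in unit_values:
        m = len(vals)
        for i_, a in enumerate(vals):
            for j_, b in enumerate(vals):
                if i_ == j_:
                    continue
                o[index[a], index[b]] += 1.0 / (m - 1)
    return o


def delta_squared(metric: Metric, n_c: np.ndarray, levels: Sequence[int]) -> np.ndarray:
    """Pairwise squared difference function on the level set.

    The ordinal metric uses cumulative coincidence marginals:
    ``delta(c, k)^2 = (sum_{g=c..k} n_g - (n_c + n_k) / 2)^2``.
    """
    k = len(n_c)
    d2 = np.zeros((k, k))
    vals = np.asarray(levels, float)
    for c in range(k):
        for j in range(k):
            if c == j:
                continue
            if metric == "nominal":
                d2[c, j] = 1.0
            elif metric == "interval":
                d2[c, j] = (vals[c] - vals[j]) ** 2
            elif metric == "ordinal":
                lo, hi = min(c, j), max(c, j)
                d2[c, j] = (n_c[lo : hi + 1].sum() - (n_c[c] + n_c[j]) / 2.0) ** 2
            else:
                raise ValueError(f"unknown metric {metric!r}")
    return d2


def _alpha_from_coincidence(
    o: np.ndarray, metric: Metric, levels: Sequence[int]
) -> float:
    n_c = o.sum(axis=1)
    n = n_c.sum()
    d2 = delta_squared(metric, n_c, levels)
    iu = np.triu_indices(len(n_c), k=1)
    d_obs = (o[iu] * d2[iu]).sum()
    d_exp = (np.outer(n_c, n_c)[iu] * d2[iu]).sum()
    if d_exp == 0:
        return math.nan
    return float(1.0 - (n - 1.0) * d_obs / d_exp)


def krippendorff_alpha(
    data: ConfusionMatrix | RatingsTable,
    metric: Metric = "ordinal",
    n_boot: int = 0,
    seed: Optional[int] = None,
    ci: float = 0.95,
) -> AlphaResult:
    """Krippendorff's alpha with optional unit-resampling bootstrap CI.

    Accepts either a two-rater confusion matrix or a general ratings
    table.  If every pairable value is identical the expected
    disagreement is zero and alpha is undefined: a NaN result is returned
    with a warning.
    """
    if isinstance(data, ConfusionMatrix):
        levels = data.levels
        o = coincidence_from_confusion(data)
    else:
        unit_values = data.unit_values()
        observed = sorted({v for vals in unit_values for v in vals})
        levels = tuple(observed)
        o = coincidence_from_units(unit_values, levels)

    point = _alpha_from_coincidence(o, metric, levels)
    if math.isnan(point):
        warnings.warn(
            "DegenerateRatings: all pairable values identical, alpha undefined",
            stacklevel=2,
        )
        return AlphaResult(math.nan, metric, n_boot=n_boot, seed=seed)

    lo = hi = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        if isinstance(data, ConfusionMatrix):
            # units are (a, b) pairs: resampling with replacement is a
            # multinomial draw over the cells
            total = data.total
            p = data.counts.ravel() / total
            for b in range(n_boot):
                cb = rng.multinomial(total, p).reshape(data.counts.shape)
                boots[b] = _alpha_from_coincidence(
                    cb.astype(float) + cb.T, metric, levels
                )
        else:
            n_units = len(unit_values)
            for b in range(n_boot):
                pick = rng.integers(0, n_units, n_units)
                ob = coincidence_from_units(
                    [unit_values[i] for i in pick], levels
                )
                boots[b] = _alpha_from_coincidence(ob, metric, levels)
        boots = boots[np.isfinite(boots)]
        if boots.size:
            tail = (1.0 - ci) / 2.0
            lo = float(np.quantile(boots, tail))
            hi = float(np.quantile(boots, 1.0 - tail))
    return AlphaResult(point, metric, ci_low=lo, ci_high=hi, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# one-vs-rest performance measures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LevelPerformance:
    level: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    se: dict[str, Optional[float]] = field(default_factory=dict)


@dataclass(frozen=True)
class PerformanceReport:
    orientation: str  # which axis is the gold standard: "rows" or "cols"
    per_level: tuple[LevelPerformance, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.per_level:
            rows.append(
                {
                    "level": p.level,
                    "sensitivity": p.sensitivity,
                    "specificity": p.specificity,
                    "ppv": p.ppv,
                    "npv": p.npv,
                    "accuracy": p.accuracy,
                }
            )
        return pd.DataFrame(rows).set_index("level")


def _measure(num: int, den: int) -> tuple[Optional[float], Optional[float]]:
    """Proportion and its binomial SE; missing when the denominator is 0."""
    if den == 0:
        return None, None
    p = num / den
    return p, math.sqrt(p * (1.0 - p) / den)


def performance_measures(
    confusion: ConfusionMatrix, orientation: str = "rows"
) -> PerformanceReport:
    """One-vs-rest sensitivity / specificity / PPV / NPV / accuracy per level.

    ``orientation`` names the gold-standard axis.  With ``"rows"`` the row
    variable is the condition; with ``"cols"`` the column variable is.
    Published agreement tables mix both conventions, so both are
    first-class.
    """
    if confusion.k < 2:
        raise ValueError("need at least 2 levels")
    c = confusion.counts
    total = confusion.total
    gold = confusion.row_margin() if orientation == "rows" else confusion.col_margin()
    pred = confusion.col_margin() if orientation == "rows" else confusion.row_margin()
    if orientation not in ("rows", "cols"):
        raise ValueError("orientation must be 'rows' or 'cols'")
    out = []
    for i, level in enumerate(confusion.levels):
        tp = int(c[i, i])
        fn = int(gold[i]) - tp
        fp = int(pred[i]) - tp
        tn = total - tp - fn - fp
        sens, se_sens = _measure(tp, tp + fn)
        spec, se_spec = _measure(tn, tn + fp)
        ppv, se_ppv = _measure(tp, tp + fp)
        npv, se_npv = _measure(tn, tn + fn)
        acc, se_acc = _measure(tp + tn, total)
        out.append(
            LevelPerformance(
                level=level,
                tp=tp,
                fp=fp,
                tn=tn,
                fn=fn,
                sensitivity=sens,
                specificity=spec,
                ppv=ppv,
                npv=npv,
                accuracy=acc,
                se={
                    "sensitivity": se_sens,
                    "specificity": se_spec,
                    "ppv": se_ppv,
                    "npv": se_npv,
                    "accuracy": se_acc,
                },
            )
        )
    return PerformanceReport(orientation=orientation, per_level=tuple(out))


def deviation_summary(
    confusion: ConfusionMatrix, margin: str = "cols"
) -> pd.DataFrame:
    """Per-level disagreement percentages along one margin.

    For each level on the chosen margin: the percentage of all units in
    that margin line that fall off the diagonal, and the percentage whose
    partner score differs by more than one level.
    """
    c = confusion.counts
    total = confusion.total
    rows = []
    for i, level in enumerate(confusion.levels):
        line = c[:, i] if margin == "cols" else c[i, :]
        differing = int(line.sum()) - int(c[i, i])
        gt1 = int(sum(v for j, v in enumerate(line) if abs(j - i) > 1))
        rows.append(
            {
                "level": level,
                "pct_differing": 100.0 * differing / total,
                "pct_differing_gt1": 100.0 * gt1 / total,
            }
        )
    return pd.DataFrame(rows).set_index("level")


LANDIS_KOCH_BANDS = (
    (0.00, "poor"),  # below 0.00
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def landis_koch_label(alpha: float) -> str:
    """Verbal agreement band; upper bounds inclusive."""
    if alpha > 1.0:
        raise ValueError("alpha cannot exceed 1")
    if alpha < 0.0:
        return "poor"
    for upper, label in LANDIS_KOCH_BANDS[1:]:
        if alpha <= upper:
            return label
    return "almost perfect"
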