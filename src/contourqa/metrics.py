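"""Mask overlap and quality-prediction evaluation statistics.

The central quantity is the Dice similarity coefficient

    Dice(A, B) = 2 |A ∩ B| / (|A| + |B|)

between two binary voxel arrays, 1 for identical masks and 0 for disjoint
ones.  A quality predictor emits an estimate ŷ of the true Dice y for each
(image, contour) pair; this module scores lists of such (ŷ, y) pairs with
the mean absolute error, the mean absolute percentage error, the Spearman
rank correlation, and a *qualitative* accuracy based on a two-clause
failure rule: a prediction is misleading when it is confidently good on a
bad contour (ŷ > 0.8 while y < 0.75) or confidently bad on a good one
(ŷ < 0.75 while y > 0.8).

Degenerate rank correlations (either side constant) are reported as the
typed :data:`UNDEFINED` sentinel, never silently as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence, Union

import numpy as np
from scipy import stats

from contourqa.core import as_mask, check_same_shape


class _Undefined:
    """Sentinel for statistics that are mathematically undefined.

    Singleton; serializes to JSON ``null``.  Falsy so that
    ``report.spearman or fallback`` reads naturally.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


#: Returned where a correlation has no defined value (constant input).
UNDEFINED = _Undefined()

MaybeFloat = Union[float, _Undefined]


class QualityPair(NamedTuple):
    """One scored contour: predicted Dice ŷ and target (true) Dice y."""

    predicted: float
    target: float


@dataclass(frozen=True)
class FailureRuleConfig:
    """Thresholds of the two-clause qualitative failure rule.

    A prediction fails when (ŷ < low_pred and y > high_target) — missed good
    contour — or (ŷ > high_pred and y < low_target) — trusted bad contour.
    All comparisons are strict, so values inside the [0.75, 0.8] gap on
    either axis never trigger the rule.
    """

    low_pred: float = 0.75
    high_pred: float = 0.8
    low_target: float = 0.75
    high_target: float = 0.8

    def __post_init__(self) -> None:
        if self.low_pred > self.high_pred:
            raise ValueError("low_pred must be <= high_pred")
        if self.low_target > self.high_target:
            raise ValueError("low_target must be <= high_target")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary masks.

    Raises on shape mismatch and on two empty masks (0/0 undefined).
    """
    a = as_mask(a, "a")
    b = as_mask(b, "b")
    check_same_shape(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise ValueError("Dice undefined: both masks are empty")
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / denom


def _split(pairs: Sequence[QualityPair]) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) == 0:
        raise ValueError("empty list of quality pairs")
    arr = np.asarray(pairs, dtype=float)
    return arr[:, 0], arr[:, 1]


def mae(pairs: Sequence[QualityPair], ddof: int = 1) -> tuple[float, float]:
    """Mean absolute error |ŷ − y| and its spread.

    The spread is the sample standard deviation (n−1 denominator) by
    default, matching "mean ± SD" reporting; set ``ddof=0`` for the
    population SD.  With a single pair the SD is reported as 0.
    """
    pred, target = _split(pairs)
    err = np.abs(pred - target)
    sd = 0.0 if err.size <= ddof else float(np.std(err, ddof=ddof))
    return float(err.mean()), sd


def mape_percent(pairs: Sequence[QualityPair]) -> float:
    """Mean absolute percentage error, 100·mean(|ŷ − y| / y).

    Undefined (raises) when any target is 0.
    """
    pred, target = _split(pairs)
    if np.any(target == 0):
        raise ValueError("mape undefined: at least one target Dice is 0")
    return float(np.mean(100.0 * np.abs(pred - target) / target))


def spearman(pairs: Sequence[QualityPair]) -> MaybeFloat:
    """Spearman rank correlation of predictions vs targets.

    Ties receive average ranks.  When either side is constant the rank
    correlation has no defined value and :data:`UNDEFINED` is returned.
    Requires at least two pairs.
    """
    pred, target = _split(pairs)
    if pred.size < 2:
        raise ValueError("spearman needs at least 2 pairs")
    if np.all(pred == pred[0]) or np.all(target == target[0]):
        return UNDEFINED
    rho = stats.spearmanr(pred, target).statistic
    if math.isnan(rho):  # pragma: no cover - guarded above
        return UNDEFINED
    return float(rho)


def is_failed_prediction(
    pair: QualityPair, cfg: FailureRuleConfig = FailureRuleConfig()
) -> bool:
    """Whether a prediction is qualitatively misleading.

    True iff (ŷ < low_pred and y > high_target) or
    (ŷ > high_pred and y < low_target); strict inequalities.
    """
    p, t = float(pair[0]), float(pair[1])
    missed_good = p < cfg.low_pred and t > cfg.high_target
    trusted_bad = p > cfg.high_pred and t < cfg.low_target
    return missed_good or trusted_bad


def qualitative_accuracy(
    pairs: Sequence[QualityPair], cfg: FailureRuleConfig = FailureRuleConfig()
) -> float:
    """Fraction of pairs not flagged by the failure rule."""
    if len(pairs) == 0:
        raise ValueError("empty list of quality pairs")
    failed = sum(is_failed_prediction(p, cfg) for p in pairs)
    return 1.0 - failed / len(pairs)


@dataclass
class MetricReport:
    """All evaluation statistics for one set of scored contours.

    ``spearman`` is :data:`UNDEFINED` for constant inputs; ``mape_percent``
    is NaN when any target is 0 (percentage error undefined there).  Both
    serialize to JSON ``null``.
    """

    mae: float
    mae_sd: float
    mape_percent: float
    max_abs_error: float
    spearman: MaybeFloat
    qualitative_accuracy: float
    n: int

    def to_dict(self) -> dict:
        out = {
            "mae": self.mae,
            "mae_sd": self.mae_sd,
            "mape_percent": self.mape_percent,
            "max_abs_error": self.max_abs_error,
            "spearman": None if isinstance(self.spearman, _Undefined) else self.spearman,
            "qualitative_accuracy": self.qualitative_accuracy,
            "n": self.n,
        }
        if out["mape_percent"] is not None and math.isnan(out["mape_percent"]):
            out["mape_percent"] = None
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "MetricReport":
        return cls(
            mae=d["mae"],
            mae_sd=d["mae_sd"],
            mape_percent=math.nan if d["mape_percent"] is None else d["mape_percent"],
            max_abs_error=d["max_abs_error"],
            spearman=UNDEFINED if d["spearman"] is None else d["spearman"],
            qualitative_accuracy=d["qualitative_accuracy"],
            n=d["n"],
        )

    @classmethod
    def from_json(cls, s: str) -> "MetricReport":
        return cls.from_dict(json.loads(s))


def metric_report(
    pairs: Sequence[QualityPair], cfg: FailureRuleConfig = FailureRuleConfig()
) -> MetricReport:
    """Bundle every statistic above into one :class:`MetricReport`."""
    pred, target = _split(pairs)
    m, sd = mae(pairs)
    mape = mape_percent(pairs) if np.all(target > 0) else math.nan
    rho = spearman(pairs) if pred.size >= 2 else UNDEFINED
    return MetricReport(
        mae=m,
        mae_sd=sd,
        mape_percent=mape,
        max_abs_error=float(np.max(np.abs(pred - target))),
        spearman=rho,
        qualitative_accuracy=qualitative_accuracy(pairs, cfg),
        n=len(pairs),
    )
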