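"""Constructed failure modes and the failure-case study harness.

A deployed quality predictor must stay sensible far outside the narrow
quality band it was trained on.  Four constructed failure modes probe this:

* ``empty``      — all-zero contour; the target Dice is exactly 0,
* ``noise``      — i.i.d. Bernoulli(p) voxels; for a ground truth of g
                   voxels in an N-voxel grid the expected Dice is
                   approximately 2pg / (g + pN),
* ``ones``       — all-one contour; target Dice is exactly 2g / (g + N),
* ``shifted_gt`` — the ground truth rigidly shifted in-plane by up to
                   ±50% of the (cropped) array extent, in integer voxels.

A fifth ``gt`` mode feeds the ground truth itself (target exactly 1),
probing the opposite end of the scale.  Every target is recomputed with
the Dice function from the generated mask — the closed forms above are
verification oracles, never the stored values.

The study harness builds each mode from each fold's held-out cases (one
sample per held-out contour slot), scores it with that fold's predictor
only, and pools per-mode metrics across folds; for a study-shaped cohort
of 60 cases / 80 contours / 5 folds this yields 80 samples per mode (400
stress cases), which together with the 80 standard held-out predictions
of the cross-validation form a 480-case global-accuracy pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from contourqa.core import as_mask
from contourqa.datapipe import QaSample, center_crop, default_crop_shape, \
    normalize_intensity, stack_channels
from contourqa.metrics import (
    FailureRuleConfig,
    MetricReport,
    QualityPair,
    dice,
    metric_report,
)
from contourqa.phantom import PhantomCase, _integer_shift_2d

MODES = ("empty", "noise", "ones", "shifted_gt", "gt")


def empty_contour(shape: tuple[int, int, int]) -> np.ndarray:
    """All-zero mask: no tissue identified."""
    return np.zeros(shape, dtype=bool)


def ones_contour(shape: tuple[int, int, int]) -> np.ndarray:
    """All-one mask: the whole field identified as organ."""
    return np.ones(shape, dtype=bool)


def noise_contour(
    shape: tuple[int, int, int], p: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """I.i.d. Bernoulli(p) voxel mask."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    rng = rng if rng is not None else np.random.default_rng()
    return rng.random(shape) < p


def shifted_gt(
    gt: np.ndarray,
    max_frac: float = 0.5,
    rng: Optional[np.random.Generator] = None,
    frame: str = "extent",
) -> np.ndarray:
    """Ground truth translated in-plane by a random integer shift.

    ``frame='extent'`` draws the x/y shifts uniformly within ±max_frac of
    the full in-plane array extent; ``frame='bbox'`` uses the mask's
    bounding-box extent instead.  Zero fill, no wraparound, z untouched.
    An empty result is allowed — it is a legitimate hard case.
    """
    gt = as_mask(gt, "gt")
    if not gt.any():
        raise ValueError("gt mask is empty")
    rng = rng if rng is not None else np.random.default_rng()
    if frame == "extent":
        ex, ey = gt.shape[0], gt.shape[1]
    elif frame == "bbox":
        xs, ys = np.nonzero(gt.any(axis=2))
        ex = int(xs.max() - xs.min() + 1)
        ey = int(ys.max() - ys.min() + 1)
    else:
        raise ValueError(f"unknown frame {frame!r}")
    dx = int(round(rng.uniform(-max_frac, max_frac) * ex))
    dy = int(round(rng.uniform(-max_frac, max_frac) * ey))
    return _integer_shift_2d(gt, dx, dy)


@dataclass
class FailureCaseSet:
    """All stress samples of one mode, with their pooled metrics."""

    mode: str
    pairs: list[QualityPair]
    report: MetricReport
    samples: list[QaSample] = field(default_factory=list, repr=False)


def _make_mode_mask(mode: str, gt: np.ndarray, rng: np.random.Generator,
                    noise_p: float, shift_frac: float, shift_frame: str) -> np.ndarray:
    if mode == "empty":
        return empty_contour(gt.shape)
    if mode == "noise":
        return noise_contour(gt.shape, noise_p, rng)
    if mode == "ones":
        return ones_contour(gt.shape)
    if mode == "shifted_gt":
        return shifted_gt(gt, shift_frac, rng, shift_frame)
    if mode == "gt":
        return gt.copy()
    raise ValueError(f"unknown failure mode {mode!r}")


def run_failure_study(
    cohort: Sequence[PhantomCase],
    folds: Sequence[tuple[list[str], list[str]]],
    predictors: Sequence[object],
    crop_shape: Optional[tuple[int, int, int]] = None,
    failure_cfg: FailureRuleConfig = FailureRuleConfig(),
    noise_p: float = 0.5,
    shift_frac: float = 0.5,
    shift_frame: str = "extent",
    seed: int = 0,
    keep_samples: bool = False,
) -> dict[str, FailureCaseSet]:
    """Score every failure mode on every fold's held-out cases.

    ``predictors[k]`` must be the predictor fit on fold k's training side;
    a length mismatch with ``folds`` raises.  Failure masks are built in
    the cropped evaluation frame, one sample per held-out contour slot,
    and each target is recomputed by the Dice function (exactly 0 for
    empty mode and exactly 1 for gt mode by construction).
    """
    if len(predictors) != len(folds):
        raise ValueError(
            f"need one predictor per fold: {len(predictors)} vs {len(folds)}"
        )
    crop_shape = crop_shape or default_crop_shape(cohort[0].image.shape)
    by_id = {c.case_id: c for c in cohort}
    rng = np.random.default_rng(seed)
    mode_pairs: dict[str, list[QualityPair]] = {m: [] for m in MODES}
    mode_samples: dict[str, list[QaSample]] = {m: [] for m in MODES}

    for (train_ids, test_ids), predictor in zip(folds, predictors):
        del train_ids
        fold_samples: dict[str, list[QaSample]] = {m: [] for m in MODES}
        for cid in test_ids:
            case = by_id[cid]
            img = normalize_intensity(center_crop(case.image, crop_shape))
            gt = center_crop(case.gt, crop_shape)
            for _slot in range(len(case.auto_contours)):
                for mode in MODES:
                    mask = _make_mode_mask(mode, gt, rng, noise_p,
                                           shift_frac, shift_frame)
                    if mask.any() or gt.any():
                        target = dice(mask, gt)
                    else:  # pragma: no cover - empty cropped gt
                        target = 1.0
                    fold_samples[mode].append(QaSample(
                        tensor=stack_channels(img, mask), target=target,
                        case_id=cid,
                    ))
        for mode in MODES:
            samples = fold_samples[mode]
            preds = np.asarray(predictor.predict_samples(samples), dtype=float)
            mode_pairs[mode].extend(
                QualityPair(float(p), float(s.target))
                for p, s in zip(preds, samples)
            )
            if keep_samples:
                mode_samples[mode].extend(samples)

    return {
        mode: FailureCaseSet(
            mode=mode, pairs=mode_pairs[mode],
            report=metric_report(mode_pairs[mode], failure_cfg),
            samples=mode_samples[mode],
        )
        for mode in MODES
    }


def total_scored_cases(study: dict[str, FailureCaseSet]) -> int:
    """Number of scored stress cases across all modes (incl. gt mode)."""
    return sum(len(s.pairs) for s in study.values())
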