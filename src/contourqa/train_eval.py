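"""Training loop and patient-level cross-validation harness.

The training protocol mirrors a small-data regime: batches are built on the
fly by the augmentation engine (one real and one fake image-contour pair
per batch of 2, generalized to any even batch size at a 1:1 ratio), the
loss is MSE on (predicted, target) Dice, optimization is Adam with a step
learning-rate schedule (0.002 dropping to 0.0002 at epoch 120 by default),
and validation is a random k-fold cross-validation split at patient level:
all contours of a case stay on one side of every split, so no image or
ground truth of a held-out patient is ever touched during that fold's
training or augmentation.

The harness takes any *predictor* exposing
``predict_samples(list[QaSample]) -> array``; besides the trained network
wrapper this includes oracle and constant predictors used for harness
self-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from contourqa.datapipe import (
    AugmentConfig,
    QaSample,
    default_crop_shape,
    make_training_batch,
    preprocess_pair,
)
from contourqa.metrics import (
    FailureRuleConfig,
    MetricReport,
    QualityPair,
    metric_report,
)
from contourqa.nn import autograd as ag
from contourqa.nn.optim import Adam
from contourqa.phantom import PhantomCase
from contourqa.qa_net import NetConfig, QaNet


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol parameters."""

    epochs: int = 200
    batch_size: int = 2
    lr_initial: float = 0.002
    lr_reduced: float = 0.0002
    lr_switch_epoch: int = 120
    loss: str = "mse"
    n_folds: int = 5
    seed: int = 0
    #: Batches per epoch.  None (default) = one shuffled pass anchoring each
    #: training case once; an integer draws that many batches with random
    #: anchors (fresh augmented samples every epoch either way).
    steps_per_epoch: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lr_switch_epoch >= self.epochs:
            raise ValueError("lr_switch_epoch must be < epochs")
        if self.batch_size < 2 or self.batch_size % 2:
            raise ValueError("batch_size must be even (1:1 real:fake ratio)")
        if self.loss != "mse":
            raise ValueError(f"unsupported loss {self.loss!r}")


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Step schedule: the reduced rate first applies AT ``lr_switch_epoch``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr_initial if epoch < cfg.lr_switch_epoch else cfg.lr_reduced


def make_folds(
    cohort: Sequence[PhantomCase], n_folds: int, seed: int
) -> list[tuple[list[str], list[str]]]:
    """Random patient-level partition into (train_ids, test_ids) per fold.

    All contours of a case stay on one side of every split, and the split
    is stratified by contour count: cases with more contours are dealt
    round-robin first, so both case counts and contour counts stay
    balanced within ±1 across folds (e.g. 60 cases / 80 contours / 5 folds
    → 12 cases and 16 contours per test fold).
    """
    ids = [c.case_id for c in cohort]
    if n_folds > len(ids):
        raise ValueError(f"n_folds={n_folds} exceeds {len(ids)} cases")
    if len(set(ids)) != len(ids):
        raise ValueError("case ids must be unique")
    rng = np.random.default_rng(seed)
    strata: dict[int, list[str]] = {}
    for c in cohort:
        strata.setdefault(len(c.auto_contours), []).append(c.case_id)
    fold_ids: list[list[str]] = [[] for _ in range(n_folds)]
    counts = np.zeros(n_folds, dtype=int)
    for n_contours in sorted(strata, reverse=True):
        members = list(strata[n_contours])
        rng.shuffle(members)
        for cid in members:
            # fill the currently smallest fold; random tie-break
            minima = np.flatnonzero(counts == counts.min())
            k = int(minima[rng.integers(len(minima))])
            fold_ids[k].append(cid)
            counts[k] += 1
    out = []
    for k in range(n_folds):
        test = sorted(fold_ids[k])
        train = sorted(set(ids) - set(test))
        out.append((train, test))
    return out


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------


class NetPredictor:
    """Adapts a trained QaNet to the harness predictor protocol."""

    def __init__(self, model: QaNet):
        self.model = model

    def predict_samples(self, samples: Sequence[QaSample]) -> np.ndarray:
        return self.model.predict([s.tensor for s in samples])


class OraclePredictor:
    """Returns the true targets — a self-test upper bound for the harness."""

    def predict_samples(self, samples: Sequence[QaSample]) -> np.ndarray:
        return np.array([s.target for s in samples], dtype=np.float64)


class ConstantPredictor:
    """Predicts one constant value for every sample."""

    def __init__(self, value: float):
        self.value = float(value)

    def predict_samples(self, samples: Sequence[QaSample]) -> np.ndarray:
        return np.full(len(samples), self.value)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_fold(
    train_cases: Sequence[PhantomCase],
    cfg: TrainConfig,
    net_cfg: NetConfig,
    aug_cfg: AugmentConfig,
    seed: int,
    crop_shape: Optional[tuple[int, int, int]] = None,
    val_cases: Optional[Sequence[PhantomCase]] = None,
) -> tuple[QaNet, list[dict]]:
    """Train one model on one fold's training cases.

    Each epoch anchors every training case once (shuffled) as the batch's
    real sample; fake samples are drawn from the same training pool only.
    Returns the model and a per-epoch curve of mean train loss (plus
    monitoring loss on ``val_cases`` when given).  Aborts on non-finite
    loss rather than continuing silently.
    """
    if len(train_cases) < 2:
        raise ValueError("training needs >= 2 cases (contour swap needs a donor)")
    rng = np.random.default_rng(seed)
    model = QaNet(net_cfg)
    opt = Adam(model.parameters(), lr=cfg.lr_initial)
    n_pairs = cfg.batch_size // 2
    curve: list[dict] = []
    val_samples = None
    if val_cases:
        val_samples = evaluation_samples(val_cases, crop_shape)

    for epoch in range(cfg.epochs):
        opt.lr = lr_schedule(epoch, cfg)
        model.train()
        if cfg.steps_per_epoch is None:
            order = rng.permutation(len(train_cases))
            batches = [order[s:s + n_pairs] for s in range(0, len(order), n_pairs)]
        else:
            batches = [rng.integers(len(train_cases), size=n_pairs)
                       for _ in range(cfg.steps_per_epoch)]
        losses = []
        for batch_idx in batches:
            anchors = [train_cases[i] for i in batch_idx]
            samples: list[QaSample] = []
            for anchor in anchors:
                samples.extend(
                    make_training_batch(anchor, list(train_cases), aug_cfg, rng,
                                        crop_shape=crop_shape, n_pairs=1)
                )
            X = np.stack([s.tensor for s in samples])
            y = np.array([s.target for s in samples], dtype=np.float32)
            opt.zero_grad()
            loss = ag.mse_loss(model.forward(X), y)
            if not math.isfinite(float(loss.data)):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "lr": opt.lr, "val_loss": None}
        if val_samples:
            preds = NetPredictor(model).predict_samples(val_samples)
            targets = np.array([s.target for s in val_samples])
            entry["val_loss"] = float(np.mean((preds - targets) ** 2))
        curve.append(entry)
    return model, curve


def evaluation_samples(
    cases: Sequence[PhantomCase], crop_shape: Optional[tuple[int, int, int]] = None
) -> list[QaSample]:
    """Augmentation-free preprocessed samples, one per auto contour."""
    samples = []
    for case in cases:
        for mask, _ in case.auto_contours:
            samples.append(preprocess_pair(case, mask, crop_shape))
    return samples


@dataclass
class FoldResult:
    """Held-out predictions and metrics of one cross-validation fold."""

    fold_index: int
    test_case_ids: list[str]
    pairs: list[QualityPair]
    report: MetricReport
    training_curve: list[dict]
    predictor: object = field(repr=False, default=None)


@dataclass
class CrossValResult:
    folds: list[FoldResult]
    pooled_pairs: list[QualityPair]
    pooled_report: MetricReport


PredictorFactory = Callable[[Sequence[PhantomCase], int], object]


def cross_validate(
    cohort: Sequence[PhantomCase],
    train_cfg: TrainConfig,
    net_cfg: Optional[NetConfig] = None,
    aug_cfg: Optional[AugmentConfig] = None,
    crop_shape: Optional[tuple[int, int, int]] = None,
    predictor_factory: Optional[PredictorFactory] = None,
    failure_cfg: FailureRuleConfig = FailureRuleConfig(),
) -> CrossValResult:
    """k-fold cross-validation with pooled headline metrics.

    One predictor is fit per fold (by default a network trained with
    :func:`train_fold`) and applied to that fold's held-out contours; the
    (ŷ, y) pairs of all folds are pooled for the headline report, and
    per-fold reports are retained.  ``predictor_factory(train_cases, k)``
    may inject any predictor, e.g. an oracle for harness self-tests.
    """
    crop_shape = crop_shape or default_crop_shape(cohort[0].image.shape)
    by_id = {c.case_id: c for c in cohort}
    folds = make_folds(cohort, train_cfg.n_folds, train_cfg.seed)
    results: list[FoldResult] = []
    pooled: list[QualityPair] = []
    for k, (train_ids, test_ids) in enumerate(folds):
        train_cases = [by_id[i] for i in train_ids]
        test_cases = [by_id[i] for i in test_ids]
        curve: list[dict] = []
        if predictor_factory is not None:
            predictor = predictor_factory(train_cases, k)
        else:
            model, curve = train_fold(
                train_cases, train_cfg, net_cfg, aug_cfg,
                seed=train_cfg.seed + 1000 * (k + 1), crop_shape=crop_shape,
            )
            predictor = NetPredictor(model)
        samples = evaluation_samples(test_cases, crop_shape)
        preds = np.asarray(predictor.predict_samples(samples), dtype=float)
        pairs = [QualityPair(float(p), float(s.target)) for p, s in zip(preds, samples)]
        results.append(FoldResult(
            fold_index=k, test_case_ids=list(test_ids), pairs=pairs,
            report=metric_report(pairs, failure_cfg), training_curve=curve,
            predictor=predictor,
        ))
        pooled.extend(pairs)
    return CrossValResult(
        folds=results, pooled_pairs=pooled,
        pooled_report=metric_report(pooled, failure_cfg),
    )
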